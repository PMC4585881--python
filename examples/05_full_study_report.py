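"""Simulate a full nine-site study and print the complete analysis summary.

Equivalent to:  stomascale analyze --simulate --seed 1 --out report/
"""

from stomascale import StudyConfig, simulate_study
from stomascale.report import render_summary, run_full_analysis

bundle = simulate_study(StudyConfig(seed=1))
results = run_full_analysis(bundle)
print(render_summary(results))
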