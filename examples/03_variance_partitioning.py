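"""Where does stomatal trait variance live: within or among sites?

Runs the nested random-effects ANOVA (species within sites) and a
random-intercept mixed model with AIC selection over environmental
covariates screened for collinearity.
"""

import dataclasses

import numpy as np
import pandas as pd

from stomascale import (
    MixedModelSpec, StudyConfig, aic_select, collinearity_screen,
    nested_variance_components, simulate_study, variance_explained,
)
from stomascale.trait_tables import five_pft_label

bundle = simulate_study(StudyConfig(seed=1))
log_sd = np.log10([r.sd_l for r in bundle.species_traits])

vc = nested_variance_components(
    log_sd, [r.site_id for r in bundle.species_traits],
    [r.species_id for r in bundle.species_traits])
print(f"log10 SD_L: {vc.among_site_pct:.1f}% of variance among sites, "
      f"{vc.within_site_pct:.1f}% within sites "
      f"({vc.n_obs} records, {vc.n_sites} sites)")

env = pd.DataFrame([dataclasses.asdict(e) for e in bundle.environment])
kept, _ = collinearity_screen(env[["mat", "map", "soil_n", "soil_p",
                                   "swc", "insolation"]])
print(f"covariates surviving the collinearity screen: {kept}")

data = pd.DataFrame({
    "log_sd": log_sd,
    "pft": [five_pft_label(r) for r in bundle.species_traits],
    "site_id": [r.site_id for r in bundle.species_traits],
}).merge(env[["site_id"] + kept], on="site_id")

candidates = [MixedModelSpec("log_sd", ("pft",))]
for cov in kept[:2]:
    candidates += [MixedModelSpec("log_sd", ("pft", cov)),
                   MixedModelSpec("log_sd", ("pft", cov, f"pft:{cov}"))]
best, ranking = aic_select(candidates, data)
print(f"\nbest model by ML-AIC: log_sd ~ {' + '.join(best.spec.fixed_terms)} "
      f"+ (1|site);  AIC {best.aic_ml:.1f}")
ledger = variance_explained(best.spec, data, best)
for row in ledger.itertuples(index=False):
    print(f"  {row.component:12s} {row.pct:5.1f}% of variance")
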