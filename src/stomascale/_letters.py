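"""Compact letter display for pairwise multiple comparisons.

Groups that share at least one letter are not significantly different at the
chosen alpha; groups sharing no letter differ.  Letters are assigned by greedy
grouping of maximal runs on the mean-sorted group order, the convention used
for Tukey-style box-plot annotations.
"""

from __future__ import annotations

import string

import numpy as np


def letter_display(group_names, group_means, reject) -> dict[str, str]:
    """Assign compact letters from a pairwise rejection matrix.

    Parameters
    ----------
    group_names : sequence of str
    group_means : sequence of float
        Used only to order the groups (descending mean gets 'a' first).
    reject : (g, g) boolean array
        ``reject[i, j]`` True when groups i and j differ significantly.
        Must be symmetric with a False diagonal.

    Returns
    -------
    dict mapping group name -> letter string (e.g. "a", "ab").
    """
    names = list(group_names)
    g = len(names)
    reject = np.asarray(reject, dtype=bool)
    if reject.shape != (g, g):
        raise ValueError("reject matrix shape does not match group count")
    order = np.argsort(-np.asarray(group_means, dtype=float), kind="stable")

    # maximal runs of mutually non-different groups in mean-sorted order
    runs: list[tuple[int, ...]] = []
    for start in range(g):
        end = start
        while end + 1 < g and not any(
            reject[order[k], order[end + 1]] for k in range(start, end + 1)
        ):
            end += 1
        runs.append(tuple(order[start : end + 1]))
    # drop runs contained in an earlier, longer run
    kept: list[tuple[int, ...]] = []
    for run in runs:
        if not any(set(run) <= set(other) for other in kept):
            kept.append(run)

    alphabet = string.ascii_lowercase
    letters = {name: "" for name in names}
    for li, run in enumerate(kept):
        letter = alphabet[li % 26] * (1 + li // 26)
        for idx in run:
            letters[names[idx]] += letter
    return letters
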