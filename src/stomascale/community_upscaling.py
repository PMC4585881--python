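"""Community-level stomatal traits by LAI weighting.

A plot's community stomatal density is the total stomata count per unit
ground area, obtained by summing each species' leaf-level density weighted
by its leaf area index:

    SD_C = Σ_i SD_Li · LAI_i          (stomata mm⁻² ground)
    SL_C = Σ_i SD_Li · SL_Li · LAI_i  (μm of stomatal length mm⁻² ground)

LAI is dimensionless (m² leaf per m² ground), so the leaf-level units carry
through.  The ratio SL_C / SD_C is an SD·LAI-weighted mean stomatal length
and must lie within the range of the contributing species' SL values — the
package's central algebraic consistency check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, InsufficientDataError
from .lai_allometry import SpeciesLAI

__all__ = [
    "CommunityTraits", "SiteCommunityTraits",
    "community_sd", "community_sl", "upscale",
]


@dataclass
class CommunityTraits:
    """Per-plot community stomatal traits with the per-species decomposition."""

    plot_id: str
    site_id: str
    sd_c: float  # stomata per mm^2 ground
    sl_c: float  # um stomatal length per mm^2 ground
    lai_total: float  # m^2 m^-2
    contributions: pd.DataFrame = field(repr=False, default=None)
    # columns: species_id, lai_i, sd_l, sl_l, sd_share, sl_share


@dataclass
class SiteCommunityTraits:
    """Unweighted mean ± SE of plot-level community traits within a site."""

    site_id: str
    sd_c_mean: float
    sd_c_se: float
    sl_c_mean: float
    sl_c_se: float
    lai_mean: float
    n_plots: int


def community_sd(per_species: Sequence[tuple[float, float]]) -> float:
    """Σ SD_Li × LAI_i over the community's species.

    ``per_species``: pairs (SD_Li in stomata mm⁻², LAI_i dimensionless).
    """
    if len(per_species) == 0:
        raise InsufficientDataError("empty community: no (SD, LAI) pairs")
    total = 0.0
    for sd, lai in per_species:
        if not (sd > 0) or lai < 0:
            raise ValueError(f"need SD > 0 and LAI >= 0, got ({sd}, {lai})")
        total += sd * lai
    return total


def community_sl(per_species: Sequence[tuple[float, float, float]]) -> float:
    """Σ SD_Li × SL_Li × LAI_i over the community's species.

    ``per_species``: triples (SD_Li, SL_Li in μm, LAI_i).
    """
    if len(per_species) == 0:
        raise InsufficientDataError("empty community: no (SD, SL, LAI) triples")
    total = 0.0
    for sd, sl, lai in per_species:
        if not (sd > 0) or not (sl > 0) or lai < 0:
            raise ValueError(f"need SD, SL > 0 and LAI >= 0, got ({sd}, {sl}, {lai})")
        total += sd * sl * lai
    return total


def upscale(
    species_lai: Iterable[SpeciesLAI],
    traits,
    coverage_threshold: float = 1.0,
    site_of_plot=None,
    pool_plots: bool = False,
) -> tuple[list[CommunityTraits], list[SiteCommunityTraits]]:
    """Community traits per plot and their site-level aggregation.

    Parameters
    ----------
    species_lai : SpeciesLAI records (any number of plots).
    traits : mapping species_id -> (sd_l, sl_l), or a DataFrame with columns
        species_id, sd_l, sl_l, or trait records with those attributes.
    coverage_threshold : minimum fraction of each plot's total LAI that must
        be carried by species with trait values; below it a
        :class:`CoverageError` reports the uncovered species and LAI share.
    site_of_plot : mapping plot_id -> site_id.  Defaults to everything in one
        site labelled "site".
    pool_plots : if True, site values pool all plots' species lists into one
        pseudo-community (LAI averaged over plots) instead of averaging
        plot-level trait values; the default is the mean over plots.
    """
    lookup = _trait_pairs(traits)
    site_of_plot = dict(site_of_plot or {})
    plots: dict[str, list[SpeciesLAI]] = {}
    for rec in species_lai:
        plots.setdefault(rec.plot_id, []).append(rec)
    if not plots:
        raise InsufficientDataError("no species LAI records supplied")

    plot_results: list[CommunityTraits] = []
    for plot_id in sorted(plots):
        recs = plots[plot_id]
        lai_total = sum(r.lai_i for r in recs)
        uncovered = [r for r in recs if r.species_id not in lookup]
        uncovered_share = (
            sum(r.lai_i for r in uncovered) / lai_total if lai_total > 0 else 0.0
        )
        if uncovered and uncovered_share > (1.0 - coverage_threshold) + 1e-12:
            names = ", ".join(
                f"{r.species_id} (LAI {r.lai_i:.3g})" for r in uncovered
            )
            raise CoverageError(
                f"plot {plot_id}: species without traits carry "
                f"{100 * uncovered_share:.1f}% of LAI (> allowed "
                f"{100 * (1 - coverage_threshold):.1f}%): {names}"
            )
        covered = [r for r in recs if r.species_id in lookup]
        if not covered:
            raise CoverageError(f"plot {plot_id}: no trait coverage at all")
        sd_c = community_sd([(lookup[r.species_id][0], r.lai_i) for r in covered])
        sl_c = community_sl(
            [(lookup[r.species_id][0], lookup[r.species_id][1], r.lai_i) for r in covered]
        )
        contrib = pd.DataFrame(
            {
                "species_id": [r.species_id for r in covered],
                "lai_i": [r.lai_i for r in covered],
                "sd_l": [lookup[r.species_id][0] for r in covered],
                "sl_l": [lookup[r.species_id][1] for r in covered],
            }
        )
        contrib["sd_share"] = contrib.sd_l * contrib.lai_i / sd_c if sd_c > 0 else 0.0
        contrib["sl_share"] = (
            contrib.sd_l * contrib.sl_l * contrib.lai_i / sl_c if sl_c > 0 else 0.0
        )
        plot_results.append(
            CommunityTraits(
                plot_id=plot_id,
                site_id=site_of_plot.get(plot_id, "site"),
                sd_c=sd_c,
                sl_c=sl_c,
                lai_total=lai_total,
                contributions=contrib,
            )
        )

    site_results: list[SiteCommunityTraits] = []
    by_site: dict[str, list[CommunityTraits]] = {}
    for ct in plot_results:
        by_site.setdefault(ct.site_id, []).append(ct)
    for site_id in sorted(by_site):
        group = by_site[site_id]
        if pool_plots:
            n = len(group)
            pooled = pd.concat([ct.contributions for ct in group], ignore_index=True)
            sd_c = community_sd(list(zip(pooled.sd_l, pooled.lai_i / n)))
            sl_c = community_sl(list(zip(pooled.sd_l, pooled.sl_l, pooled.lai_i / n)))
            site_results.append(
                SiteCommunityTraits(site_id, sd_c, float("nan"), sl_c, float("nan"),
                                    sum(ct.lai_total for ct in group) / n, n)
            )
        else:
            sd = np.array([ct.sd_c for ct in group])
            sl = np.array([ct.sl_c for ct in group])
            lai = np.array([ct.lai_total for ct in group])
            n = len(group)
            se = lambda v: float(np.std(v, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
            site_results.append(
                SiteCommunityTraits(
                    site_id=site_id,
                    sd_c_mean=float(sd.mean()), sd_c_se=se(sd),
                    sl_c_mean=float(sl.mean()), sl_c_se=se(sl),
                    lai_mean=float(lai.mean()), n_plots=n,
                )
            )
    return plot_results, site_results


def community_frame(plot_results: Iterable[CommunityTraits]) -> pd.DataFrame:
    """Plot-level output table: plot_id, site_id, sd_c, sl_c, lai_total."""
    return pd.DataFrame(
        [
            {"plot_id": ct.plot_id, "site_id": ct.site_id, "sd_c": ct.sd_c,
             "sl_c": ct.sl_c, "lai_total": ct.lai_total}
            for ct in plot_results
        ]
    )


def site_frame(site_results: Iterable[SiteCommunityTraits]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"site_id": s.site_id, "sd_c_mean": s.sd_c_mean, "sd_c_se": s.sd_c_se,
             "sl_c_mean": s.sl_c_mean, "sl_c_se": s.sl_c_se,
             "lai_mean": s.lai_mean, "n_plots": s.n_plots}
            for s in site_results
        ]
    )


def _trait_pairs(traits) -> dict[str, tuple[float, float]]:
    if isinstance(traits, dict):
        return {k: (float(v[0]), float(v[1])) for k, v in traits.items()}
    if isinstance(traits, pd.DataFrame):
        return {
            str(r.species_id): (float(r.sd_l), float(r.sl_l))
            for r in traits.itertuples(index=False)
        }
    return {t.species_id: (float(t.sd_l), float(t.sl_l)) for t in traits}
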