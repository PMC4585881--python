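"""Assemble the full analysis of a study bundle into a structured report.

The report mirrors the narrative of a trait-upscaling study: species-level
trait statistics and PFT contrasts, the SD–SL trade-off and its multi-group
SMA tests, community upscaling, mixed-model selection with the
variance-explained ledger, within/among-site variance partitioning,
latitudinal and environmental gradients, and the NPP linkage.
Every number in the plain-text summary is traceable to the machine-readable
results index (results.json) and the tidy tables written alongside it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import gradient_analysis as ga
from . import mixed_models as mm
from . import sma_regression as sma
from . import trait_tables as tt
from .community_upscaling import community_frame, site_frame
from .synthetic_forest import StudyBundle

log = logging.getLogger(__name__)

STAGES = ("traits", "pft_contrasts", "sma", "upscaling",
          "mixed_models", "variance_partition", "gradients_npp")


def run_full_analysis(bundle: StudyBundle, alpha: float = 0.05,
                      stages=None) -> dict:
    """Run every analysis stage on a bundle; returns a nested results dict.

    ``stages`` restricts the run to a subset of :data:`STAGES`.  A failing
    stage is recorded under ``errors`` without aborting the others.
    """
    selected = list(stages) if stages is not None else list(STAGES)
    unknown = set(selected) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    species = tt.records_to_frame(bundle.species_traits)
    species["pft"] = [tt.five_pft_label(r) for r in bundle.species_traits]
    species["log_sd"] = np.log10(species.sd_l)
    species["log_sl"] = np.log10(species.sl_l)
    env = pd.DataFrame([dataclasses.asdict(e) for e in bundle.environment])
    species = species.merge(
        env[["site_id", "latitude", "mat", "map", "soil_n", "soil_p",
             "swc", "insolation"]], on="site_id", how="left")

    site_comm = site_frame(bundle.site_community).merge(env, on="site_id")
    plot_comm = community_frame(bundle.community).merge(env, on="site_id")
    plot_comm["log_sd_c"] = np.log10(plot_comm.sd_c)
    plot_comm["log_sl_c"] = np.log10(plot_comm.sl_c)

    results: dict = {"alpha": alpha, "n_species_records": len(species),
                     "n_sites": len(site_comm), "errors": {}}

    def stage(name):
        def deco(fn):
            if name in selected:
                try:
                    results[name] = fn()
                except Exception as exc:  # noqa: BLE001 - reported, not hidden
                    log.exception("stage %s failed", name)
                    results["errors"][name] = f"{type(exc).__name__}: {exc}"
            return fn
        return deco

    @stage("traits")
    def _traits():
        out = {}
        for trait in ("sd_l", "sl_l"):
            out[trait] = dataclasses.asdict(tt.summarize_trait(species[trait]))
        for col, trait in (("sd_c_mean", "sd_c"), ("sl_c_mean", "sl_c")):
            out[trait] = dataclasses.asdict(tt.summarize_trait(site_comm[col]))
        return out

    @stage("pft_contrasts")
    def _pft():
        out = {}
        schemes = {
            "growth_form": species.growth_form,
            "leaf_type": species.apply(
                lambda r: f"{r.leaf_type} tree"
                if r.growth_form == "tree" and pd.notna(r.leaf_type) else None, axis=1),
            "leaf_habit": species.apply(
                lambda r: f"{r.leaf_habit} broadleaf"
                if r.growth_form == "tree" and r.leaf_type == "broadleaf"
                and pd.notna(r.leaf_habit) else None, axis=1),
        }
        for scheme, labels in schemes.items():
            mask = labels.notna()
            out[scheme] = {}
            for trait in ("log_sd", "log_sl"):
                contrast = tt.pft_anova(species.loc[mask, trait],
                                        labels[mask], alpha=alpha)
                out[scheme][trait] = {
                    "f_stat": contrast.f_stat, "p_value": contrast.p_value,
                    "letters": contrast.tukey_letters,
                    "group_means_log10": contrast.group_means,
                }
        return out

    @stage("sma")
    def _sma():
        groups = {
            name: (grp.log_sd.to_numpy(), grp.log_sl.to_numpy())
            for name, grp in species.groupby("growth_form")
        }
        growth = sma.slope_heterogeneity(groups, alpha=alpha)
        habit_df = species[(species.growth_form == "tree")
                           & (species.leaf_type == "broadleaf")]
        habit_groups = {
            name: (grp.log_sd.to_numpy(), grp.log_sl.to_numpy())
            for name, grp in habit_df.groupby("leaf_habit")
        }
        habit = (sma.slope_heterogeneity(habit_groups, alpha=alpha)
                 if len(habit_groups) >= 2 else None)
        overall = sma.sma_fit(species.log_sd, species.log_sl, alpha=alpha)
        community = sma.sma_fit(np.log10(site_comm.sd_c_mean),
                                np.log10(site_comm.sl_c_mean), alpha=alpha)
        return {
            "species_overall": dataclasses.asdict(overall),
            "community": dataclasses.asdict(community),
            "growth_form": _sma_group_dict(growth),
            "leaf_habit": _sma_group_dict(habit) if habit else None,
        }

    @stage("upscaling")
    def _upscale():
        return {
            "plot_table": plot_comm[["plot_id", "site_id", "sd_c", "sl_c",
                                     "lai_total"]].to_dict("records"),
            "site_table": site_comm[["site_id", "sd_c_mean", "sd_c_se",
                                     "sl_c_mean", "sl_c_se", "lai_mean",
                                     "n_plots"]].to_dict("records"),
            "equation_levels_used": pd.Series(
                [s.equation_level_used for s in bundle.species_lai]
            ).value_counts().to_dict(),
        }

    @stage("mixed_models")
    def _mixed():
        kept, corr_report = mm.collinearity_screen(
            env[["mat", "map", "soil_n", "soil_p", "swc", "insolation"]],
            alpha=alpha)
        covs = kept[:2]  # parsimonious candidate pool
        out = {"covariates_retained": kept,
               "correlation_screen": corr_report.to_dict("records"),
               "species_level": {}, "community_level": {}}
        for resp in ("log_sd", "log_sl"):
            candidates = [mm.MixedModelSpec(resp, ("pft",))]
            for c in covs:
                candidates.append(mm.MixedModelSpec(resp, ("pft", c)))
                candidates.append(mm.MixedModelSpec(resp, ("pft", c, f"pft:{c}")))
            if len(covs) >= 2:
                candidates.append(mm.MixedModelSpec(resp, ("pft", *covs)))
            best, ranking = mm.aic_select(candidates, species)
            ledger = mm.variance_explained(best.spec, species, best)
            out["species_level"][resp] = _mm_dict(best, ranking, ledger)
        for resp in ("log_sd_c", "log_sl_c"):
            candidates = [mm.MixedModelSpec(resp, (c,)) for c in covs]
            candidates.append(mm.MixedModelSpec(resp, ()))
            best, ranking = mm.aic_select(candidates, plot_comm)
            ledger = mm.variance_explained(best.spec, plot_comm, best)
            out["community_level"][resp] = _mm_dict(best, ranking, ledger)
        return out

    @stage("variance_partition")
    def _vc():
        out = {}
        for trait in ("log_sd", "log_sl"):
            vc = mm.nested_variance_components(
                species[trait], species.site_id, species.species_id)
            out[trait] = {"among_site_pct": vc.among_site_pct,
                          "within_site_pct": vc.within_site_pct,
                          "n_sites": vc.n_sites, "n_obs": vc.n_obs}
        return out

    @stage("gradients_npp")
    def _grad():
        out = {"latitude": {}, "environment": {}}
        for trait in ("log_sd", "log_sl"):
            fit = ga.latitude_trend(species[trait], species.latitude, "species")
            out["latitude"][f"species_{trait}"] = dataclasses.asdict(fit)
        for col in ("sd_c_mean", "sl_c_mean"):
            fit = ga.latitude_trend(np.log10(site_comm[col]),
                                    site_comm.latitude, "community")
            out["latitude"][f"community_{col}"] = dataclasses.asdict(fit)
        for col in ("sd_c_mean", "sl_c_mean"):
            fit = ga.trait_env_regression(np.log10(site_comm[col]), site_comm.mat)
            out["environment"][f"community_{col}_vs_mat"] = dataclasses.asdict(fit)
        npp = bundle.npp.set_index("site_id").loc[site_comm.site_id,
                                                  "npp_dry_matter"].to_numpy()
        npp_c = ga.convert_npp_to_carbon(npp)
        assoc = ga.npp_association(site_comm.sd_c_mean, site_comm.sl_c_mean, npp_c)
        out["npp"] = {
            "fit_sd": dataclasses.asdict(assoc.fit_sd),
            "fit_sl": dataclasses.asdict(assoc.fit_sl),
            "attribution": {k: [list(t) for t in v]
                            for k, v in assoc.attribution.items()},
            "predictor_r2": assoc.predictor_r2,
            "collinear": assoc.collinear,
        }
        return out

    return results


def _sma_group_dict(res: sma.SMAGroupResult) -> dict:
    out = {
        "fits": {name: dataclasses.asdict(fit) for name, fit in res.fits.items()},
        "heterogeneity_stat": res.heterogeneity_stat,
        "heterogeneity_df": res.heterogeneity_df,
        "heterogeneity_p": res.heterogeneity_p,
        "common_slope": res.common_slope,
    }
    if res.elevation is not None:
        out["elevation"] = {
            "stat": res.elevation.stat, "p_value": res.elevation.p_value,
            "elevations": res.elevation.elevations,
            "letters": res.elevation.letters,
        }
    return out


def _mm_dict(best: mm.MixedModelResult, ranking: pd.DataFrame,
             ledger: pd.DataFrame) -> dict:
    return {
        "terms": list(best.spec.fixed_terms),
        "aic_ml": best.aic_ml,
        "sigma2_site": best.sigma2_site,
        "sigma2_resid": best.sigma2_resid,
        "term_tests": [dataclasses.asdict(t) for t in best.term_tests],
        "variance_explained_pct": {
            row.component: row.pct for row in ledger.itertuples(index=False)},
        "ranking": ranking.to_dict("records"),
    }


def write_report(results: dict, bundle: StudyBundle, out_dir) -> None:
    """Write results.json, tidy tables and the plain-text summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "results.json", "w") as fh:
        json.dump(_jsonable(results), fh, indent=1)
    community_frame(bundle.community).to_csv(out / "community_traits.tsv",
                                             sep="\t", index=False)
    site_frame(bundle.site_community).to_csv(out / "site_community_traits.tsv",
                                             sep="\t", index=False)
    contrib = pd.concat(
        [ct.contributions.assign(plot_id=ct.plot_id, site_id=ct.site_id)
         for ct in bundle.community], ignore_index=True)
    contrib.to_csv(out / "species_contributions.tsv", sep="\t", index=False)
    with open(out / "summary.txt", "w") as fh:
        fh.write(render_summary(results))


def render_summary(results: dict) -> str:
    """Plain-text results narrative (2-decimal display; full precision in JSON)."""
    lines = []
    add = lines.append
    add("Community upscaling of stomatal traits: analysis summary")
    add("=" * 58)
    tr = results.get("traits")
    if tr:
        add("\n[Species- and community-level trait statistics]")
        for key, label, unit in (("sd_l", "SD_L", "stomata mm^-2"),
                                 ("sl_l", "SL_L", "um"),
                                 ("sd_c", "SD_C (site mean)", "stomata mm^-2"),
                                 ("sl_c", "SL_C (site mean)", "um mm^-2")):
            s = tr[key]
            add(f"  {label}: mean {s['mean']:.2f} {unit}, range "
                f"{s['min']:.2f}-{s['max']:.2f}, CV {s['cv']:.2f} (n={s['n']})")
    pft = results.get("pft_contrasts")
    if pft:
        add("\n[PFT contrasts (one-way ANOVA + Tukey letters, log10 traits)]")
        for scheme, traits in pft.items():
            for trait, c in traits.items():
                add(f"  {scheme} / {trait}: F = {c['f_stat']:.2f}, "
                    f"P = {c['p_value']:.3g}; letters {c['letters']}")
    sm = results.get("sma")
    if sm:
        add("\n[SD-SL bivariate relationships (SMA, log10 axes)]")
        so = sm["species_overall"]
        add(f"  species-level: slope {so['slope']:.2f}, r2 {so['r2']:.2f}, "
            f"P = {so['p_value']:.3g} (n={so['n']})")
        co = sm["community"]
        add(f"  community-level: slope {co['slope']:.2f}, r2 {co['r2']:.2f}, "
            f"P = {co['p_value']:.3g} (n={co['n']})")
        gf = sm["growth_form"]
        slopes = {k: round(v["slope"], 2) for k, v in gf["fits"].items()}
        add(f"  growth-form slopes {slopes}; heterogeneity "
            f"P = {gf['heterogeneity_p']:.3g}"
            + (f"; common slope {gf['common_slope']:.2f}"
               if gf["common_slope"] is not None else ""))
        if sm.get("leaf_habit"):
            lh = sm["leaf_habit"]
            add(f"  leaf-habit heterogeneity P = {lh['heterogeneity_p']:.3g}"
                + (f"; common slope {lh['common_slope']:.2f}, elevation "
                   f"P = {lh['elevation']['p_value']:.3g}"
                   if lh.get("common_slope") is not None else ""))
    up = results.get("upscaling")
    if up:
        add("\n[Upscaling]")
        add(f"  equation fallback levels used: {up['equation_levels_used']}")
    mmres = results.get("mixed_models")
    if mmres:
        add("\n[Mixed models (REML, site random intercept; AIC on ML refits)]")
        add(f"  covariates retained by collinearity screen: "
            f"{mmres['covariates_retained']}")
        for level in ("species_level", "community_level"):
            for resp, d in mmres[level].items():
                ve = {k: round(v, 1) for k, v in d["variance_explained_pct"].items()}
                add(f"  {level} {resp}: terms {d['terms']}, "
                    f"AIC {d['aic_ml']:.1f}, variance explained % {ve}")
    vc = results.get("variance_partition")
    if vc:
        add("\n[Within/among-site variance partition (nested ANOVA)]")
        for trait, d in vc.items():
            add(f"  {trait}: among-site {d['among_site_pct']:.1f}%, "
                f"within-site {d['within_site_pct']:.1f}%")
    gr = results.get("gradients_npp")
    if gr:
        add("\n[Latitudinal gradients]")
        for name, fit in gr["latitude"].items():
            add(f"  {name}: {fit['form']}, r2 {fit['r2']:.2f}, "
                f"P = {fit['p_value']:.3g}")
        add("\n[NPP linkage]")
        npp = gr["npp"]
        add(f"  NPP ~ SD_C: r2 {npp['fit_sd']['r2']:.2f}, "
            f"P = {npp['fit_sd']['p_value']:.3g}")
        add(f"  NPP ~ SL_C: r2 {npp['fit_sl']['r2']:.2f}, "
            f"P = {npp['fit_sl']['p_value']:.3g}")
        sd_first = npp["attribution"]["sd_c_first"]
        add(f"  sequential SS (SD_C first): "
            + ", ".join(f"{t}: {pct:.1f}%" for t, pct, _ in sd_first))
        add(f"  SD_C-SL_C self-correlation r2 {npp['predictor_r2']:.2f}"
            + (" (collinear)" if npp["collinear"] else ""))
    if results.get("errors"):
        add("\n[Stage errors]")
        for name, msg in results["errors"].items():
            add(f"  {name}: {msg}")
    return "\n".join(lines) + "\n"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj
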