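"""REML mixed models, AIC selection, variance ledgers, nested components, screen."""

import warnings

import numpy as np
import pandas as pd
import pytest

from stomascale import (
    MixedModelSpec, aic_select, collinearity_screen, fit_lmm,
    nested_variance_components, variance_explained,
)
from stomascale.errors import DegenerateFitError, InsufficientDataError


def one_way(rng, a=9, m=12, s_site=0.7, s_res=1.0):
    site = np.repeat([f"s{i}" for i in range(a)], m)
    y = np.repeat(rng.normal(0, s_site, a), m) + rng.normal(0, s_res, a * m)
    return pd.DataFrame({"y": y, "site_id": site}), a, m


class TestREML:
    def test_balanced_components_match_anova_closed_form(self, rng):
        df, a, m = one_way(rng)
        res = fit_lmm(MixedModelSpec("y"), df)
        ybar = df.groupby("site_id").y.mean()
        msb = m * ((ybar - df.y.mean()) ** 2).sum() / (a - 1)
        msw = ((df.y - np.repeat(ybar.values, m)) ** 2).sum() / (a * (m - 1))
        assert res.sigma2_site == pytest.approx((msb - msw) / m, abs=1e-8)
        assert res.sigma2_resid == pytest.approx(msw, abs=1e-8)

    def test_matches_statsmodels_loglikelihoods(self, rng):
        import statsmodels.formula.api as smf
        df, *_ = one_way(rng)
        df["x"] = rng.normal(0, 1, len(df))
        df["y"] = df.y + 0.8 * df.x
        res = fit_lmm(MixedModelSpec("y", ("x",)), df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_reml = smf.mixedlm("y ~ x", df, groups=df.site_id).fit(reml=True)
            sm_ml = smf.mixedlm("y ~ x", df, groups=df.site_id).fit(reml=False)
        assert np.isfinite(sm_reml.llf) and np.isfinite(sm_ml.llf)
        assert res.reml_loglik == pytest.approx(sm_reml.llf, abs=1e-5)
        assert res.ml_loglik == pytest.approx(sm_ml.llf, abs=1e-5)

    def test_single_site_degenerates_to_ols(self, rng):
        n = 80
        x = rng.normal(0, 1, n)
        y = 1.5 + 0.8 * x + rng.normal(0, 1, n)
        df = pd.DataFrame({"y": y, "x": x, "site_id": "only"})
        res = fit_lmm(MixedModelSpec("y", ("x",)), df)
        assert res.sigma2_site == 0.0
        b1, b0 = np.polyfit(x, y, 1)
        assert res.fixed_estimates.loc["Intercept", "estimate"] == pytest.approx(
            b0, rel=1e-8)
        assert res.fixed_estimates.loc["x", "estimate"] == pytest.approx(b1, rel=1e-8)

    def test_invariant_to_row_order_and_level_recoding(self, rng):
        df, *_ = one_way(rng)
        df["pft"] = rng.choice(list("uvw"), len(df))
        spec = MixedModelSpec("y", ("pft",))
        base = fit_lmm(spec, df)
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        again = fit_lmm(spec, shuffled)
        assert again.sigma2_site == pytest.approx(base.sigma2_site, rel=1e-6)
        assert again.reml_loglik == pytest.approx(base.reml_loglik, rel=1e-9)
        recoded = df.assign(site_id="z_" + df.site_id)
        assert fit_lmm(spec, recoded).sigma2_site == pytest.approx(
            base.sigma2_site, rel=1e-6)

    def test_rank_deficiency_reported(self, rng):
        df, *_ = one_way(rng)
        df["x1"] = rng.normal(0, 1, len(df))
        df["x2"] = 2.0 * df.x1
        with pytest.raises(DegenerateFitError):
            fit_lmm(MixedModelSpec("y", ("x1", "x2")), df)

    def test_icc_recovery_small_batch(self):
        rng = np.random.default_rng(8)
        iccs = []
        for _ in range(30):
            site = np.repeat(np.arange(9).astype(str), 100)
            y = (np.repeat(rng.normal(0, np.sqrt(0.3), 9), 100)
                 + rng.normal(0, np.sqrt(0.7), 900))
            r = fit_lmm(MixedModelSpec("y"), pd.DataFrame({"y": y, "site_id": site}))
            iccs.append(r.sigma2_site / (r.sigma2_site + r.sigma2_resid))
        assert abs(np.mean(iccs) - 0.3) < 0.04


class TestAICSelect:
    def test_pure_noise_covariate_usually_rejected(self):
        rng = np.random.default_rng(11)
        wins = 0
        for _ in range(40):
            df, *_ = one_way(rng, a=6, m=10)
            df["x"] = rng.normal(0, 1, len(df))  # no effect on y
            best, _ = aic_select(
                [MixedModelSpec("y"), MixedModelSpec("y", ("x",))], df)
            wins += best.spec.fixed_terms == ()
        assert wins > 20  # smaller model selected in the majority

    def test_tie_break_keeps_first_candidate(self, rng):
        df, *_ = one_way(rng)
        spec = MixedModelSpec("y")
        best, table = aic_select([spec, MixedModelSpec("y")], df)
        assert best.spec is not None and len(table) == 2
        assert table.delta_aic.iloc[0] == 0.0

    def test_single_candidate_returned(self, rng):
        df, *_ = one_way(rng)
        best, table = aic_select([MixedModelSpec("y")], df)
        assert len(table) == 1

    def test_differing_observation_sets_rejected(self, rng):
        df, *_ = one_way(rng)
        df["x"] = rng.normal(0, 1, len(df))
        df.loc[:5, "x"] = np.nan  # spec with x drops rows
        with pytest.raises(ValueError, match="observation sets"):
            aic_select([MixedModelSpec("y"), MixedModelSpec("y", ("x",))], df)

    def test_mismatched_responses_rejected(self, rng):
        df, *_ = one_way(rng)
        df["z"] = df.y
        with pytest.raises(ValueError, match="response"):
            aic_select([MixedModelSpec("y"), MixedModelSpec("z")], df)


class TestVarianceExplained:
    def test_intercept_only_splits_site_and_residual(self, rng):
        df, *_ = one_way(rng)
        ledger = variance_explained(MixedModelSpec("y"), df)
        assert set(ledger.component) == {"site", "residual"}
        assert ledger.pct.sum() == pytest.approx(100.0, abs=0.1)

    def test_strong_fixed_effect_dominates(self):
        rng = np.random.default_rng(4)
        n = 600
        x = rng.normal(0, 1, n)
        y = 3.0 * x + rng.normal(0, 1.0, n)  # R2 = 0.9 by construction
        df = pd.DataFrame({"y": y, "x": x,
                           "site_id": rng.choice(list("abcdef"), n)})
        ledger = variance_explained(MixedModelSpec("y", ("x",)), df)
        pct = dict(zip(ledger.component, ledger.pct))
        assert 85 <= pct["x"] <= 95

    def test_ledger_sums_to_100_on_random_models(self, rng):
        for _ in range(5):
            df, *_ = one_way(rng)
            df["x"] = rng.normal(0, 1, len(df))
            df["pft"] = rng.choice(list("pq"), len(df))
            ledger = variance_explained(MixedModelSpec("y", ("x", "pft")), df)
            assert ledger.pct.sum() == pytest.approx(100.0, abs=0.1)
            assert (ledger.pct >= 0).all()


class TestNested:
    def test_balanced_matches_method_of_moments_closed_form(self, rng):
        a, b, n = 6, 5, 4
        site = np.repeat([f"s{i}" for i in range(a)], b * n)
        sp = np.repeat([f"s{i}_p{j}" for i in range(a) for j in range(b)], n)
        y = (np.repeat(rng.normal(0, 1.0, a), b * n)
             + np.repeat(rng.normal(0, 0.8, a * b), n)
             + rng.normal(0, 0.5, a * b * n))
        vc = nested_variance_components(y, site, sp)
        # balanced closed form from the three mean squares
        df = pd.DataFrame({"y": y, "site": site, "sp": sp})
        ms_site = (b * n * ((df.groupby("site").y.mean() - y.mean()) ** 2).sum()
                   / (a - 1))
        sub = df.groupby(["site", "sp"]).y.mean()
        ms_sp = (n * ((sub - sub.groupby("site").transform("mean")) ** 2).sum()
                 / (a * (b - 1)))
        ms_err = ((df.y - df.groupby(["site", "sp"]).y.transform("mean")) ** 2
                  ).sum() / (a * b * (n - 1))
        s_err = ms_err
        s_sp = (ms_sp - ms_err) / n
        s_site = (ms_site - ms_sp) / (b * n)
        assert vc.detail["sigma2_resid"] == pytest.approx(s_err, rel=1e-10)
        assert vc.detail["sigma2_species"] == pytest.approx(s_sp, rel=1e-10)
        assert vc.detail["sigma2_site"] == pytest.approx(s_site, rel=1e-10)

    def test_identically_distributed_sites_have_small_among_share(self):
        rng = np.random.default_rng(21)
        shares = []
        for _ in range(30):
            site = np.repeat(np.arange(8), 40)
            y = rng.normal(0, 1, 320)  # no site signal at all
            sp = [f"{s}_{i}" for s, i in zip(site, range(320))]
            shares.append(nested_variance_components(y, site, sp).among_site_pct)
        assert np.mean(shares) < 3.0

    def test_single_site_undefined(self):
        with pytest.raises(InsufficientDataError):
            nested_variance_components([1.0, 2.0], ["s", "s"], ["a", "b"])

    def test_one_record_per_species_collapses_to_one_way(self, rng):
        site = np.repeat(list("abc"), 10)
        y = rng.normal(0, 1, 30)
        sp = [f"{s}{i}" for i, s in enumerate(site)]
        vc = nested_variance_components(y, site, sp)
        assert vc.detail["collapsed_one_way"]
        assert vc.among_site_pct + vc.within_site_pct == pytest.approx(100.0)


class TestCollinearityScreen:
    def test_perfectly_correlated_pair_keeps_priority(self, rng):
        mat = rng.normal(10, 5, 9)
        env = pd.DataFrame({"mat": mat, "map": 100 * mat + 3.0})
        kept, report = collinearity_screen(env)
        assert kept == ["mat"]
        assert report.loc[0, "p"] < 1e-10

    def test_single_covariate_retained(self, rng):
        env = pd.DataFrame({"mat": rng.normal(0, 1, 5)})
        kept, report = collinearity_screen(env)
        assert kept == ["mat"] and report.empty

    def test_independent_covariates_usually_all_kept(self):
        rng = np.random.default_rng(31)
        keeps = []
        for _ in range(60):
            env = pd.DataFrame(rng.normal(0, 1, (9, 3)), columns=["a", "b", "c"])
            keeps.append(len(collinearity_screen(env)[0]))
        assert np.mean(keeps) > 2.5  # alpha=0.05 pairwise: most runs keep all 3

    def test_fewer_than_three_sites_rejected(self):
        with pytest.raises(InsufficientDataError):
            collinearity_screen(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}))

    def test_priority_order_is_respected(self, rng):
        x = rng.normal(0, 1, 9)
        env = pd.DataFrame({"soil_n": x * 2, "mat": x * 3 + 0.001 * rng.normal(size=9)})
        kept, _ = collinearity_screen(env)  # default priority puts mat first
        assert kept[0] == "mat"
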