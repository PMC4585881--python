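"""The synthetic study generator: determinism, configured structure, stress cases."""

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy.stats import spearmanr

from stomascale import StudyConfig, sma_fit, simulate_study
from stomascale import nested_variance_components
from stomascale.synthetic_forest import (
    PFTS, generate_environment, generate_npp, pft_mixture,
)


def bundle_digest(bundle, tmp_path: Path) -> str:
    out = tmp_path / f"digest_{np.random.randint(1 << 30)}"
    bundle.write(out)
    h = hashlib.sha256()
    for name in sorted(p.name for p in out.iterdir()):
        h.update((out / name).read_bytes())
    return h.hexdigest()


class TestDeterminism:
    def test_same_seed_byte_identical_bundles(self, tmp_path):
        cfg = StudyConfig(seed=42, species_per_site=20)
        d1 = bundle_digest(simulate_study(cfg), tmp_path)
        d2 = bundle_digest(simulate_study(StudyConfig(seed=42, species_per_site=20)),
                           tmp_path)
        assert d1 == d2

    def test_different_seeds_differ(self):
        b1 = simulate_study(StudyConfig(seed=1, species_per_site=15))
        b2 = simulate_study(StudyConfig(seed=2, species_per_site=15))
        assert b1.species_traits[0].sd_l != b2.species_traits[0].sd_l

    def test_environment_stage_isolated_from_later_stages(self):
        cfg = StudyConfig(seed=9)
        env_alone = generate_environment(cfg)
        env_in_study = simulate_study(
            StudyConfig(seed=9, species_per_site=10)).environment
        assert [e.mat for e in env_alone] == [e.mat for e in env_in_study]


class TestEnvironment:
    def test_mat_endpoints_match_transect(self):
        env = generate_environment(StudyConfig())
        assert env[0].mat == pytest.approx(23.15)
        assert env[-1].mat == pytest.approx(-3.67)
        assert env[0].latitude == pytest.approx(18.7)
        assert env[-1].latitude == pytest.approx(51.8)

    def test_two_sites_are_exactly_the_endpoints(self):
        env = generate_environment(StudyConfig(n_sites=2))
        assert [e.latitude for e in env] == pytest.approx([18.7, 51.8])

    def test_soil_n_increases_northwards_on_average(self):
        env = generate_environment(StudyConfig())
        rho = spearmanr([e.latitude for e in env], [e.soil_n for e in env]).statistic
        assert rho > 0.5


class TestMixtureAndTraits:
    def test_pft_proportions_sum_to_one_and_turn_over(self):
        cfg = StudyConfig()
        warm = pft_mixture(cfg, 23.15)
        cold = pft_mixture(cfg, -3.67)
        assert warm.sum() == pytest.approx(1.0)
        i_eb = PFTS.index("evergreen broadleaf tree")
        i_con = PFTS.index("conifer tree")
        assert warm[i_eb] > warm[i_con]  # evergreen broadleaf dominates the south
        assert cold[i_con] > cold[i_eb]  # conifers dominate the north

    def test_noise_free_limit_recovers_configured_slopes_exactly(self):
        cfg = StudyConfig(seed=3, species_per_site=60, within_site_sd=0.3,
                          sd_sl_scatter=0.0, among_site_sd=0.0, lat_sd_slope=0.0)
        bundle = simulate_study(cfg)
        by_pft = {}
        for rec in bundle.species_traits:
            by_pft.setdefault(bundle.pft_of_species[rec.species_id], []).append(rec)
        for pft, recs in by_pft.items():
            if len(recs) < 3:
                continue
            fit = sma_fit(np.log10([r.sd_l for r in recs]),
                          np.log10([r.sl_l for r in recs]))
            assert fit.slope == pytest.approx(cfg.sd_sl_slopes[pft], abs=1e-10)
            assert fit.r == pytest.approx(-1.0, abs=1e-10)

    def test_among_site_share_recovered_over_seeds(self):
        # configured ~12-13% among-site share; average the 9-site MoM estimate
        shares = []
        for seed in range(101, 113):
            b = simulate_study(StudyConfig(seed=seed))
            shares.append(nested_variance_components(
                np.log10([r.sd_l for r in b.species_traits]),
                [r.site_id for r in b.species_traits],
                [r.species_id for r in b.species_traits]).among_site_pct)
        assert 8.0 <= np.mean(shares) <= 18.0

    def test_trait_moments_in_calibrated_regime(self, default_study):
        sd = np.array([r.sd_l for r in default_study.species_traits])
        sl = np.array([r.sl_l for r in default_study.species_traits])
        assert 180 <= sd.mean() <= 300
        assert 0.5 <= sd.std(ddof=1) / sd.mean() <= 0.9
        assert 24 <= sl.mean() <= 38


class TestCensusAndRegistry:
    def test_all_dbh_above_census_threshold(self, default_study):
        assert min(s.dbh for s in default_study.stems) >= 2.0

    def test_fallback_fraction_zero_resolves_all_at_species_level(self):
        b = simulate_study(StudyConfig(seed=6, species_per_site=20,
                                       species_eq_fraction=1.0))
        woody = {s.species_id for s in b.stems}
        levels = {s.equation_level_used for s in b.species_lai
                  if s.species_id in woody}
        assert levels == {"species"}

    def test_no_species_equations_still_completes(self):
        b = simulate_study(StudyConfig(seed=6, species_per_site=20,
                                       species_eq_fraction=0.0))
        woody = {s.species_id for s in b.stems}
        levels = {s.equation_level_used for s in b.species_lai
                  if s.species_id in woody}
        assert "species" not in levels
        assert levels <= {"genus", "pft", "site_mixed"}
        assert len(b.community) == b.config.n_sites * b.config.plots_per_site

    def test_registry_r2_range(self, default_study):
        r2s = [eq.r2 for eq in default_study.registry if eq.level == "species"]
        assert all(0.52 <= r2 <= 1.0 for r2 in r2s)

    def test_lai_gradient_south_exceeds_north(self, default_study):
        lai = {s.site_id: s.lai_mean for s in default_study.site_community}
        assert lai["S1"] > lai["S9"]
        lats = [e.latitude for e in default_study.environment]
        lai_by_site = [lai[e.site_id] for e in default_study.environment]
        assert spearmanr(lats, lai_by_site).statistic < -0.8


class TestCommunityAndNPP:
    def test_sd_c_declines_along_the_transect(self, default_study):
        sd_c = [s.sd_c_mean for s in default_study.site_community]
        lat = [e.latitude for e in default_study.environment]
        assert spearmanr(lat, sd_c).statistic < -0.9
        assert sd_c[0] == max(sd_c) and sd_c[-1] == min(sd_c)

    def test_noise_free_npp_is_exactly_linear(self):
        cfg = StudyConfig(npp_target_r2=0.999999)
        sd_c = np.linspace(400, 3000, 9)
        npp = generate_npp(cfg, sd_c, np.random.default_rng(0))
        r2 = np.corrcoef(sd_c, npp)[0, 1] ** 2
        assert r2 > 0.999

    def test_referential_integrity(self, default_study):
        trait_ids = {r.species_id for r in default_study.species_traits}
        for stem in default_study.stems[:200]:
            assert stem.species_id in trait_ids
        for herb in default_study.herbs[:200]:
            assert herb.species_id in trait_ids


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"n_sites": 1},
        {"lat_range": (50.0, 20.0)},
        {"plots_per_site": 5},
        {"within_site_sd": -0.1},
        {"npp_target_r2": 1.5},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            StudyConfig(**kw).validate()

    def test_positive_sd_sl_slope_rejected(self):
        cfg = StudyConfig()
        cfg.sd_sl_slopes["herb"] = 0.2
        with pytest.raises(ValueError, match="herb"):
            cfg.validate()
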