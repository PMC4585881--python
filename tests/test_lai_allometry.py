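"""Allometric equation resolution, foliar biomass, and species LAI."""

import numpy as np
import pytest

from stomascale import lai_allometry as la
from stomascale.errors import CoverageError, UnresolvedEquationError


def eq(key, level, a=0.1, b=2.0, form="power_dbh"):
    return la.AllometricEquation(key=key, level=level, form=form, a=a, b=b, r2=0.9)


REGISTRY = [
    eq("Quercus acuta", "species", a=0.2),
    eq("Quercus", "genus", a=0.15),
    eq("evergreen broadleaf tree", "pft", a=0.1),
    eq("S1", "site_mixed", a=0.05),
]


class TestResolve:
    def test_species_level_direct_hit(self):
        got = la.resolve_equation("Quercus acuta", "Quercus",
                                  "evergreen broadleaf tree", "S1", REGISTRY)
        assert got.level == "species" and got.a == 0.2

    def test_genus_fallback_when_species_missing(self):
        got = la.resolve_equation("Quercus glauca", "Quercus",
                                  "evergreen broadleaf tree", "S1", REGISTRY)
        assert got.level == "genus"

    def test_pft_then_site_mixed(self):
        got = la.resolve_equation("Pinus sp", "Pinus", "evergreen broadleaf tree",
                                  "S1", REGISTRY)
        assert got.level == "pft"
        got = la.resolve_equation("Pinus sp", "Pinus", "conifer tree", "S1", REGISTRY)
        assert got.level == "site_mixed"

    def test_order_invariance_under_registry_permutation(self, rng):
        queries = [("Quercus acuta", "Quercus", "evergreen broadleaf tree", "S1"),
                   ("X", "Quercus", "p", "S1"),
                   ("X", "Y", "evergreen broadleaf tree", "S1"),
                   ("X", "Y", "Z", "S1")]
        baseline = [la.resolve_equation(*q, REGISTRY) for q in queries]
        for _ in range(10):
            shuffled = list(REGISTRY)
            rng.shuffle(shuffled)
            assert [la.resolve_equation(*q, shuffled) for q in queries] == baseline

    def test_unresolved_names_species(self):
        with pytest.raises(UnresolvedEquationError, match="Fagus missing"):
            la.resolve_equation("Fagus missing", "Fagus", "ghost pft", "S9", REGISTRY)

    def test_empty_registry(self):
        with pytest.raises(UnresolvedEquationError):
            la.resolve_equation("a", "b", "c", "d", [])


class TestFoliarBiomass:
    def test_power_law_arithmetic(self):
        assert la.foliar_biomass(eq("x", "species", a=0.1, b=2.0), 10.0) == pytest.approx(10.0)

    def test_degenerate_exponent_returns_a(self):
        e = eq("x", "species", a=3.3, b=0.0)
        for dbh in (2.0, 17.5, 40.0):
            assert la.foliar_biomass(e, dbh) == pytest.approx(3.3)

    def test_d2h_form_requires_height(self):
        e = eq("x", "species", a=0.05, b=0.7, form="power_d2h")
        assert la.foliar_biomass(e, 10.0, 8.0) == pytest.approx(0.05 * (100 * 8) ** 0.7)
        with pytest.raises(ValueError, match="height"):
            la.foliar_biomass(e, 10.0)

    def test_log_linear_refit_recovers_coefficients(self, rng):
        a_true, b_true = 0.07, 1.85
        e = eq("x", "species", a=a_true, b=b_true)
        dbh = rng.uniform(2, 50, 60)
        biomass = np.array([la.foliar_biomass(e, d) for d in dbh])
        slope, intercept = np.polyfit(np.log(dbh), np.log(biomass), 1)
        assert slope == pytest.approx(b_true, abs=1e-10)
        assert np.exp(intercept) == pytest.approx(a_true, rel=1e-10)


TRAITS = {
    "oak": {"sla": 20.0, "genus": "Quercus", "pft": "evergreen broadleaf tree",
            "site_id": "S1"},
    "grass": {"sla": 25.0, "genus": "Poa", "pft": "herb", "site_id": "S1"},
}


class TestPlotSpeciesLAI:
    def test_unit_chain(self):
        # one stem whose biomass is 60 kg, SLA 20 m2/kg, plot 1200 m2 -> LAI 1
        e = [eq("oak", "species", a=60.0, b=0.0)]
        stems = [la.StemRecord("p1", "oak", 10.0, 8.0)]
        out = la.plot_species_lai(stems, [], TRAITS, e, plot_area=1200.0)
        assert len(out) == 1
        assert out[0].lai_i == pytest.approx(1.0)
        assert out[0].equation_level_used == "species"

    def test_two_identical_stems_double_lai(self):
        e = [eq("oak", "species", a=60.0, b=0.0)]
        one = la.plot_species_lai([la.StemRecord("p1", "oak", 10, 8)], [],
                                  TRAITS, e, plot_area=1200.0)
        two = la.plot_species_lai([la.StemRecord("p1", "oak", 10, 8)] * 2, [],
                                  TRAITS, e, plot_area=1200.0)
        assert two[0].lai_i == pytest.approx(2 * one[0].lai_i, rel=1e-12)

    def test_conservation_identity_random_plot(self, rng):
        registry = [eq(f"sp{i}", "species", a=float(rng.uniform(0.01, 0.2)),
                       b=float(rng.uniform(1.5, 2.5))) for i in range(6)]
        traits = {f"sp{i}": {"sla": float(rng.uniform(4, 25)), "genus": "g",
                             "pft": "p", "site_id": "S"} for i in range(6)}
        stems = [la.StemRecord("p1", f"sp{rng.integers(6)}",
                               float(rng.uniform(2, 40)), float(rng.uniform(2, 30)))
                 for _ in range(80)]
        area = 1200.0
        out = la.plot_species_lai(stems, [], traits, registry, plot_area=area)
        lhs = sum(s.foliar_biomass * traits[s.species_id]["sla"] for s in out)
        assert lhs == pytest.approx(area * la.total_lai(out), rel=1e-12)

    def test_doubling_area_halves_lai(self):
        e = [eq("oak", "species")]
        stems = [la.StemRecord("p1", "oak", 15.0, 10.0)]
        l1 = la.plot_species_lai(stems, [], TRAITS, e, plot_area=1200.0)[0].lai_i
        l2 = la.plot_species_lai(stems, [], TRAITS, e, plot_area=2400.0)[0].lai_i
        assert l1 == pytest.approx(2 * l2, rel=1e-12)

    def test_pseudo_species_split_additivity(self, rng):
        e = [eq("oak", "species"), eq("oak_a", "species"), eq("oak_b", "species")]
        traits = dict(TRAITS)
        traits["oak_a"] = traits["oak_b"] = traits["oak"]
        stems = [la.StemRecord("p1", "oak", float(d), 8.0)
                 for d in rng.uniform(3, 30, 10)]
        whole = la.plot_species_lai(stems, [], traits, e, plot_area=1200.0)
        split = [la.StemRecord("p1", "oak_a" if i < 5 else "oak_b", s.dbh, s.height)
                 for i, s in enumerate(stems)]
        parts = la.plot_species_lai(split, [], traits, e, plot_area=1200.0)
        assert la.total_lai(parts) == pytest.approx(la.total_lai(whole), rel=1e-12)

    def test_herb_uses_aboveground_biomass(self):
        herbs = [la.HerbBiomassRecord("p1", "grass", 2.4)]
        out = la.plot_species_lai([], herbs, TRAITS, [], plot_area=1200.0)
        assert out[0].lai_i == pytest.approx(2.4 * 25.0 / 1200.0)
        assert out[0].equation_level_used == "herb_biomass"

    def test_missing_sla_is_hard_error(self):
        stems = [la.StemRecord("p1", "mystery", 10.0, 8.0)]
        with pytest.raises(CoverageError, match="mystery"):
            la.plot_species_lai(stems, [], TRAITS, [eq("mystery", "species")],
                                plot_area=1200.0)

    def test_mean_stem_mode_matches_sum_for_linear_exponent(self):
        # with b = 1 the equation is linear in DBH, so mean- and sum-based agree
        e = [eq("oak", "species", a=0.5, b=1.0)]
        stems = [la.StemRecord("p1", "oak", d, 8.0) for d in (5.0, 10.0, 20.0)]
        per_stem = la.plot_species_lai(stems, [], TRAITS, e, plot_area=1200.0)
        mean_mode = la.plot_species_lai(stems, [], TRAITS, e, plot_area=1200.0,
                                        mean_stem_mode=True)
        assert mean_mode[0].lai_i == pytest.approx(per_stem[0].lai_i, rel=1e-12)


def test_registry_json_round_trip(tmp_path, small_study):
    path = tmp_path / "registry.json"
    la.write_registry(small_study.registry, path)
    back = la.read_registry(str(path))
    assert back == small_study.registry
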