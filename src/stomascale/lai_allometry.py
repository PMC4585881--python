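"""Foliar biomass allometry and species-specific leaf area index (LAI).

Woody foliar biomass comes from power-law allometric equations on DBH
(basal stem diameter for shrubs) and height.  When a species-specific
equation is unavailable the registry is searched along a strict fallback
chain — same genus, same PFT, mixed-species equation of the site's forest.
Herb foliar biomass is the measured aboveground biomass.  A species' LAI
contribution is foliar biomass × SLA / plot ground area.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import pandas as pd

from .errors import CoverageError, SchemaError, UnresolvedEquationError

log = logging.getLogger(__name__)

EQUATION_LEVELS = ("species", "genus", "pft", "site_mixed")
EQUATION_FORMS = ("power_dbh", "power_d2h")

#: R² range of the source equation registry; values outside are flagged, not refused
_R2_TYPICAL = (0.52, 1.00)


@dataclass(frozen=True)
class AllometricEquation:
    """Power-law foliar-biomass rule: kg of foliage from DBH (cm) and height (m).

    ``power_dbh``: a·DBH^b;  ``power_d2h``: a·(DBH²·H)^b.
    ``key`` is the taxon or group the equation applies to, at the given level.
    """

    key: str
    level: str  # species | genus | pft | site_mixed
    form: str  # power_dbh | power_d2h
    a: float
    b: float
    r2: float | None = None
    source: str = ""

    def __post_init__(self):
        if self.level not in EQUATION_LEVELS:
            raise ValueError(f"level must be one of {EQUATION_LEVELS}, got {self.level!r}")
        if self.form not in EQUATION_FORMS:
            raise ValueError(f"form must be one of {EQUATION_FORMS}, got {self.form!r}")
        if not (self.a > 0):
            raise ValueError(f"coefficient a must be > 0, got {self.a}")
        if self.r2 is not None and not (_R2_TYPICAL[0] <= self.r2 <= _R2_TYPICAL[1]):
            log.warning("equation %s (%s): r2=%.3f outside typical range %s",
                        self.key, self.level, self.r2, _R2_TYPICAL)


@dataclass
class StemRecord:
    """One censused stem: DBH ≥ 2 cm for trees (basal diameter for shrubs)."""

    plot_id: str
    species_id: str
    dbh: float  # cm
    height: float  # m
    growth_form: str = "tree"


@dataclass
class HerbBiomassRecord:
    """Per-plot aboveground biomass of one herb species (kg per plot)."""

    plot_id: str
    species_id: str
    aboveground_biomass: float


@dataclass
class SpeciesLAI:
    """One species' LAI contribution within one plot."""

    plot_id: str
    species_id: str
    foliar_biomass: float  # kg per plot
    lai_i: float  # m^2 leaf per m^2 ground
    equation_level_used: str  # species|genus|pft|site_mixed|herb_biomass


def resolve_equation(
    species: str,
    genus: str,
    pft: str,
    site: str,
    registry: Iterable[AllometricEquation],
) -> AllometricEquation:
    """First registry match along the fallback chain species → genus → PFT → site-mixed.

    Resolution is independent of registry order: the chain level decides, and
    within a level the lexicographically smallest source wins (stable tie-break).
    """
    registry = list(registry)
    if not registry:
        raise UnresolvedEquationError("equation registry is empty")
    wanted = {"species": species, "genus": genus, "pft": pft, "site_mixed": site}
    for level in EQUATION_LEVELS:
        matches = sorted(
            (eq for eq in registry if eq.level == level and eq.key == wanted[level]),
            key=lambda eq: (eq.source, eq.key),
        )
        if matches:
            return matches[0]
    raise UnresolvedEquationError(
        f"no allometric equation for species {species!r} "
        f"(genus {genus!r}, pft {pft!r}, site {site!r}) at any fallback level"
    )


def foliar_biomass(eq: AllometricEquation, dbh: float, height: float | None = None) -> float:
    """Foliar biomass (kg) of a single stem under the given equation."""
    if not (dbh > 0):
        raise ValueError(f"dbh must be > 0, got {dbh}")
    if eq.form == "power_dbh":
        return eq.a * dbh ** eq.b
    if height is None or not (height > 0):
        raise ValueError(f"form power_d2h requires height > 0, got {height}")
    return eq.a * (dbh ** 2 * height) ** eq.b


def plot_species_lai(
    stems: Sequence[StemRecord],
    herbs: Sequence[HerbBiomassRecord],
    traits,
    registry: Iterable[AllometricEquation],
    plot_area: float = 1200.0,
    mean_stem_mode: bool = False,
) -> list[SpeciesLAI]:
    """Species-specific LAI for one plot.

    For each woody species, stem-level foliar biomass is computed and summed
    (``mean_stem_mode`` instead applies the equation once to the mean DBH and
    mean height and multiplies by stem count, emulating field protocols that
    record only stand means); herbs contribute their aboveground biomass
    directly.  LAI_i = foliar biomass (kg) × SLA (m² kg⁻¹) / plot area (m²).

    ``traits`` maps species_id -> object with attributes ``sla``, ``genus``
    and a PFT label (``pft``), or a pandas DataFrame with those columns
    indexed by species_id; a ``site_id`` attribute/column keys mixed-forest
    equations.
    """
    if not (plot_area > 0):
        raise ValueError(f"plot_area must be > 0, got {plot_area}")
    lookup = _as_trait_lookup(traits)
    registry = list(registry)
    out: list[SpeciesLAI] = []

    by_species: dict[str, list[StemRecord]] = {}
    for stem in stems:
        by_species.setdefault(stem.species_id, []).append(stem)

    for species_id, sp_stems in by_species.items():
        tr = _require_traits(lookup, species_id)
        eq = resolve_equation(species_id, tr["genus"], tr["pft"], tr["site_id"], registry)
        if mean_stem_mode:
            mean_dbh = sum(s.dbh for s in sp_stems) / len(sp_stems)
            mean_h = sum(s.height for s in sp_stems) / len(sp_stems)
            biomass = len(sp_stems) * foliar_biomass(eq, mean_dbh, mean_h)
        else:
            biomass = sum(foliar_biomass(eq, s.dbh, s.height) for s in sp_stems)
        out.append(
            SpeciesLAI(
                plot_id=sp_stems[0].plot_id,
                species_id=species_id,
                foliar_biomass=biomass,
                lai_i=biomass * tr["sla"] / plot_area,
                equation_level_used=eq.level,
            )
        )
    for herb in herbs:
        tr = _require_traits(lookup, herb.species_id)
        out.append(
            SpeciesLAI(
                plot_id=herb.plot_id,
                species_id=herb.species_id,
                foliar_biomass=herb.aboveground_biomass,
                lai_i=herb.aboveground_biomass * tr["sla"] / plot_area,
                equation_level_used="herb_biomass",
            )
        )
    return out


def total_lai(species_lai: Iterable[SpeciesLAI]) -> float:
    """Plot LAI: sum of species contributions."""
    return sum(s.lai_i for s in species_lai)


def _as_trait_lookup(traits) -> dict:
    if isinstance(traits, pd.DataFrame):
        df = traits
        required = {"sla", "genus", "pft", "site_id"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"trait frame missing column(s): {', '.join(sorted(missing))}")
        return {
            str(sid): {c: row[c] for c in required}
            for sid, row in df.set_index(df["species_id"] if "species_id" in df else df.index)
            .iterrows()
        }
    if isinstance(traits, dict):
        return traits
    # iterable of objects with the needed attributes
    return {
        t.species_id: {
            "sla": t.sla,
            "genus": t.genus,
            "pft": getattr(t, "pft", getattr(t, "growth_form", "")),
            "site_id": t.site_id,
        }
        for t in traits
    }


def _require_traits(lookup: dict, species_id: str) -> dict:
    if species_id not in lookup:
        raise CoverageError(f"census species {species_id!r} has no trait record (SLA required)")
    tr = lookup[species_id]
    if tr.get("sla") is None or not (tr["sla"] > 0):
        raise CoverageError(f"census species {species_id!r} lacks a positive SLA")
    return tr


# ---------------------------------------------------------------------------
# registry / census I/O


def read_registry(path) -> list[AllometricEquation]:
    """Read an equation registry from JSON (list of objects) or CSV."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            raw = json.load(fh)
    else:
        raw = pd.read_csv(path, sep=None, engine="python").to_dict("records")
    return [
        AllometricEquation(
            key=str(r["key"]), level=str(r["level"]), form=str(r["form"]),
            a=float(r["a"]), b=float(r["b"]),
            r2=None if r.get("r2") in (None, "", "NA") or pd.isna(r.get("r2"))
            else float(r["r2"]),
            source=str(r.get("source", "")),
        )
        for r in raw
    ]


def write_registry(registry: Iterable[AllometricEquation], path) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(eq) for eq in registry], fh, indent=1)


def read_stems(path) -> list[StemRecord]:
    df = pd.read_csv(path, sep="\t")
    needed = {"plot_id", "species_id", "dbh", "height"}
    if not needed <= set(df.columns):
        raise SchemaError(f"{path}: stem table needs columns {sorted(needed)}")
    return [
        StemRecord(
            plot_id=str(r.plot_id), species_id=str(r.species_id),
            dbh=float(r.dbh), height=float(r.height),
            growth_form=str(getattr(r, "growth_form", "tree")),
        )
        for r in df.itertuples(index=False)
    ]


def read_herbs(path) -> list[HerbBiomassRecord]:
    df = pd.read_csv(path, sep="\t")
    needed = {"plot_id", "species_id", "aboveground_biomass"}
    if not needed <= set(df.columns):
        raise SchemaError(f"{path}: herb table needs columns {sorted(needed)}")
    return [
        HerbBiomassRecord(
            plot_id=str(r.plot_id), species_id=str(r.species_id),
            aboveground_biomass=float(r.aboveground_biomass),
        )
        for r in df.itertuples(index=False)
    ]


def write_stems(stems: Iterable[StemRecord], path) -> None:
    pd.DataFrame([asdict(s) for s in stems]).to_csv(path, sep="\t", index=False)


def write_herbs(herbs: Iterable[HerbBiomassRecord], path) -> None:
    pd.DataFrame([asdict(h) for h in herbs]).to_csv(path, sep="\t", index=False)
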