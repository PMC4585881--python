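"""Species-level stomatal trait tables: domain records, I/O, summaries, PFT contrasts.

The central record is one species-at-site observation carrying stomatal
density SD_L (stomata mm⁻²), stomatal length SL_L (μm) and specific leaf area
SLA (m² kg⁻¹).  Species are grouped into plant functional types (PFTs) under
three schemes: growth form (herb / shrub / tree), leaf type (broadleaf vs
conifer, trees only) and leaf habit (evergreen vs deciduous, broadleaved
trees only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from ._letters import letter_display
from .errors import InsufficientDataError, SchemaError, ValidationError

GROWTH_FORMS = ("herb", "shrub", "tree")
LEAF_TYPES = ("broadleaf", "conifer")
LEAF_HABITS = ("evergreen", "deciduous")
PFT_SCHEMES = ("growth_form", "leaf_type", "leaf_habit")

#: marker returned by :func:`classify_pft` when a scheme does not apply
NOT_APPLICABLE = None


@dataclass
class SpeciesTraitRecord:
    """One species-at-site trait observation."""

    species_id: str
    genus: str
    family: str
    site_id: str
    plot_id: str
    growth_form: str  # herb | shrub | tree
    leaf_type: str | None  # broadleaf | conifer | None (non-trees)
    leaf_habit: str | None  # evergreen | deciduous | None
    sd_l: float  # stomata per mm^2 leaf
    sl_l: float  # micrometres
    sla: float | None = None  # m^2 per kg; derivable from area/mass
    leaf_area: float | None = None  # m^2
    leaf_dry_mass: float | None = None  # kg

    def __post_init__(self):
        if self.sla is None and self.leaf_area is not None and self.leaf_dry_mass is not None:
            self.sla = compute_sla(self.leaf_area, self.leaf_dry_mass)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if not (self.sd_l > 0):
            problems.append(f"sd_l must be > 0, got {self.sd_l}")
        if not (self.sl_l > 0):
            problems.append(f"sl_l must be > 0, got {self.sl_l}")
        if self.sla is not None and not (self.sla > 0):
            problems.append(f"sla must be > 0 when present, got {self.sla}")
        if self.growth_form not in GROWTH_FORMS:
            problems.append(f"growth_form must be one of {GROWTH_FORMS}, got {self.growth_form!r}")
        if self.leaf_type is not None and self.leaf_type not in LEAF_TYPES:
            problems.append(f"leaf_type must be one of {LEAF_TYPES} or NA, got {self.leaf_type!r}")
        if self.leaf_habit is not None and self.leaf_habit not in LEAF_HABITS:
            problems.append(
                f"leaf_habit must be one of {LEAF_HABITS} or NA, got {self.leaf_habit!r}"
            )
        return problems


@dataclass
class TraitSummary:
    """Descriptive statistics of one trait on the raw (untransformed) scale."""

    n: int
    mean: float
    min: float
    max: float
    se: float  # sd / sqrt(n), sample sd
    cv: float  # sample sd / mean


@dataclass
class PFTContrast:
    """One-way ANOVA + Tukey HSD contrast among PFT groups."""

    groups: list[str]
    f_stat: float
    p_value: float
    tukey_letters: dict[str, str]
    alpha: float = 0.05
    group_means: dict[str, float] = field(default_factory=dict)


_COLUMNS = [f.name for f in fields(SpeciesTraitRecord)]
_MANDATORY = [c for c in _COLUMNS if c not in ("sla", "leaf_area", "leaf_dry_mass")]
_NUMERIC = ("sd_l", "sl_l", "sla", "leaf_area", "leaf_dry_mass")
_OPTIONAL_STR = ("leaf_type", "leaf_habit")


def compute_sla(leaf_area: float, leaf_dry_mass: float) -> float:
    """Specific leaf area (m² kg⁻¹) from one-sided leaf area (m²) and dry mass (kg)."""
    if not (leaf_area > 0) or not (leaf_dry_mass > 0):
        raise ValueError(
            f"leaf_area and leaf_dry_mass must be > 0 (got {leaf_area}, {leaf_dry_mass})"
        )
    return leaf_area / leaf_dry_mass


def read_species_traits(path) -> list[SpeciesTraitRecord]:
    """Read a delimited (tab-separated) species trait table.

    Missing values are written as "NA".  Raises :class:`SchemaError` on missing
    mandatory columns and :class:`ValidationError` listing offending rows when
    any record violates its invariants.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=["NA"])
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    records, bad_rows, messages = [], [], []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        kwargs = {}
        for col in _COLUMNS:
            val = getattr(row, col, None)
            if val is None or (isinstance(val, float) and math.isnan(val)):
                kwargs[col] = None
                continue
            if col in _NUMERIC:
                try:
                    kwargs[col] = float(val)
                except ValueError:
                    bad_rows.append(i)
                    messages.append(f"row {i}: non-numeric {col}={val!r}")
                    kwargs[col] = float("nan")
            else:
                kwargs[col] = str(val)
        rec = SpeciesTraitRecord(**kwargs)
        problems = rec.validate()
        if problems:
            bad_rows.append(i)
            messages.extend(f"row {i}: {p}" for p in problems)
        records.append(rec)
    if bad_rows:
        raise ValidationError(
            f"{path}: {len(set(bad_rows))} invalid row(s):\n" + "\n".join(messages),
            rows=sorted(set(bad_rows)),
        )
    return records


def write_species_traits(records: Iterable[SpeciesTraitRecord], path) -> None:
    """Write records as a tab-separated table (schema identical to the reader's)."""
    df = records_to_frame(records)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def records_to_frame(records: Iterable[SpeciesTraitRecord]) -> pd.DataFrame:
    """Trait records as a DataFrame with one column per record field."""
    return pd.DataFrame([{c: getattr(r, c) for c in _COLUMNS} for r in records])


def frame_to_records(df: pd.DataFrame) -> list[SpeciesTraitRecord]:
    records = []
    for row in df.itertuples(index=False):
        kwargs = {c: getattr(row, c, None) for c in _COLUMNS}
        for c in _OPTIONAL_STR:
            if isinstance(kwargs[c], float) and math.isnan(kwargs[c]):
                kwargs[c] = None
        records.append(SpeciesTraitRecord(**kwargs))
    return records


def species_site_means(records: Iterable[SpeciesTraitRecord], per: str = "species") -> pd.DataFrame:
    """Average trait values within species at each site (or per species overall).

    ``per="species_site"`` keeps one row per species-at-site combination,
    which is the unit of the site-aware analyses; ``per="species"`` further
    averages a species over the sites where it occurs, the unit used for
    species-level descriptive statistics.
    """
    df = records_to_frame(records)
    keys = {"species_site": ["species_id", "site_id"], "species": ["species_id"]}[per]
    grouped = df.groupby(keys, as_index=False).agg(
        sd_l=("sd_l", "mean"),
        sl_l=("sl_l", "mean"),
        sla=("sla", "mean"),
        growth_form=("growth_form", "first"),
        leaf_type=("leaf_type", "first"),
        leaf_habit=("leaf_habit", "first"),
        site_id=("site_id", "first"),
    )
    return grouped


def summarize_trait(values: Sequence[float]) -> TraitSummary:
    """Descriptive statistics (raw scale): n, mean, min, max, SE and CV.

    CV and SE use the sample (n−1) standard deviation.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"summarize_trait needs n >= 2, got n = {x.size}")
    sd = float(np.std(x, ddof=1))
    mean = float(np.mean(x))
    return TraitSummary(
        n=int(x.size),
        mean=mean,
        min=float(np.min(x)),
        max=float(np.max(x)),
        se=sd / math.sqrt(x.size),
        cv=sd / mean if mean != 0 else float("inf"),
    )


def classify_pft(record: SpeciesTraitRecord, scheme: str) -> str | None:
    """PFT label of a record under a grouping scheme, or None when not applicable.

    leaf_type and leaf_habit schemes apply to trees only (habit further to
    broadleaved trees only); records outside the scheme's domain are flagged
    not-applicable rather than silently labelled.
    """
    if scheme not in PFT_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {PFT_SCHEMES}")
    if scheme == "growth_form":
        return record.growth_form
    if record.growth_form != "tree":
        return NOT_APPLICABLE
    if scheme == "leaf_type":
        if record.leaf_type is None:
            return NOT_APPLICABLE
        return f"{record.leaf_type} tree"
    # leaf_habit: evergreen vs deciduous broadleaved trees
    if record.leaf_type != "broadleaf" or record.leaf_habit is None:
        return NOT_APPLICABLE
    return f"{record.leaf_habit} broadleaf"


def five_pft_label(record: SpeciesTraitRecord) -> str:
    """The five-way PFT partition used by the mixed models.

    herb, shrub, conifer tree, evergreen broadleaf tree, deciduous broadleaf tree.
    """
    if record.growth_form != "tree":
        return record.growth_form
    if record.leaf_type == "conifer":
        return "conifer tree"
    return f"{record.leaf_habit} broadleaf tree"


def pft_anova(
    values: Sequence[float],
    groups: Sequence[str],
    alpha: float = 0.05,
    log10_transform: bool = False,
) -> PFTContrast:
    """One-way ANOVA with Tukey's HSD post-hoc letters across PFT groups.

    Stomatal traits are conventionally log10-transformed before this test;
    pass already-transformed values (default) or set ``log10_transform``.
    """
    y = np.asarray(values, dtype=float)
    if log10_transform:
        y = np.log10(y)
    g = np.asarray(groups, dtype=object)
    if y.shape != g.shape:
        raise ValueError("values and groups must have equal length")
    names, counts = np.unique(g, return_counts=True)
    if names.size < 2:
        raise InsufficientDataError("pft_anova needs at least 2 groups")
    singletons = names[counts < 2]
    if singletons.size:
        raise InsufficientDataError(
            f"group(s) with fewer than 2 members: {', '.join(map(str, singletons))}"
        )
    samples = [y[g == name] for name in names]
    f_stat, p_value = stats.f_oneway(*samples)
    tukey = pairwise_tukeyhsd(y, g, alpha=alpha)
    gnames = list(tukey.groupsunique)
    k = len(gnames)
    reject = np.zeros((k, k), dtype=bool)
    idx = 0
    for i in range(k):
        for j in range(i + 1, k):
            reject[i, j] = reject[j, i] = bool(tukey.reject[idx])
            idx += 1
    means = {name: float(np.mean(y[g == name])) for name in gnames}
    letters = letter_display(gnames, [means[n] for n in gnames], reject)
    return PFTContrast(
        groups=list(map(str, names)),
        f_stat=float(f_stat),
        p_value=float(p_value),
        tukey_letters=letters,
        alpha=alpha,
        group_means=means,
    )
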