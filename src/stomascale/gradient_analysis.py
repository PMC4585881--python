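"""Latitudinal trends, trait–environment regressions and the NPP linkage.

Community-level stomatal traits track the latitudinal turnover of forest
types, so the community trend is expected to be much stronger than the
species-level one.  The final link regresses forest net primary productivity
(NPP, g C m⁻² yr⁻¹) on community stomatal density and length, and attributes
NPP variance to the two (highly self-correlated) predictors by sequential
sums of squares in a general linear model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, InsufficientDataError

__all__ = [
    "SiteEnvironment", "RegressionResult", "NPPAssociation",
    "latitude_trend", "trait_env_regression",
    "convert_npp_to_carbon", "npp_association",
]

#: dry matter → carbon conversion factor
DRY_MATTER_TO_CARBON = 0.5


@dataclass
class SiteEnvironment:
    """Climate, soil and radiation descriptors of one forest site."""

    site_id: str
    latitude: float  # degrees N
    longitude: float  # degrees E
    mat: float  # mean annual temperature, deg C
    map: float  # mean annual precipitation, mm / yr
    soil_n: float  # mg g^-1
    soil_p: float  # mg kg^-1
    swc: float  # soil water content, %
    insolation: float  # kWh m^-2 day^-1


@dataclass
class RegressionResult:
    """An OLS fit, linear or quadratic in the single covariate."""

    form: str  # "linear" | "quadratic"
    coefficients: tuple[float, ...]  # low order first: (b0, b1[, b2])
    r2: float
    p_value: float
    n: int
    aic: float = float("nan")

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return sum(c * x ** k for k, c in enumerate(self.coefficients))


@dataclass
class NPPAssociation:
    fit_sd: RegressionResult  # NPP ~ SD_C
    fit_sl: RegressionResult  # NPP ~ SL_C
    attribution: dict = field(default_factory=dict)
    # order -> list of (term, pct_of_total_ss, p_value); includes "residual"
    predictor_r2: float = float("nan")  # SD_C vs SL_C self-correlation
    collinear: bool = False


def _ols_poly(x, y, degree):
    n = x.size
    X = np.column_stack([x ** k for k in range(degree + 1)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    df_den = n - degree - 1
    if df_den <= 0 or rss <= 0:
        p = 0.0 if r2 > 0 else 1.0
    else:
        f = (tss - rss) / degree / (rss / df_den)
        p = float(stats.f.sf(f, degree, df_den))
    aic = n * math.log(max(rss, 1e-300) / n) + 2 * (degree + 2)
    return RegressionResult(
        form="linear" if degree == 1 else "quadratic",
        coefficients=tuple(float(b) for b in beta),
        r2=float(r2), p_value=p, n=int(n), aic=float(aic),
    )


def latitude_trend(
    trait: Sequence[float],
    latitude: Sequence[float],
    level: str = "species",
    allow_exponential: bool = False,
) -> RegressionResult:
    """Trait (log10 scale) vs latitude.

    Species level: plain OLS line (n ≥ 10).  Community level (n ≥ 3): both a
    line and a quadratic are fitted and the AIC-preferred form is returned —
    the operational reading of a "nonlinear" community decline.  With
    ``allow_exponential`` an exponential-decay form (linear fit on the log
    response) joins the AIC comparison; it requires a positive trait.
    """
    y = np.asarray(trait, dtype=float)
    x = np.asarray(latitude, dtype=float)
    if y.size != x.size:
        raise ValueError("trait and latitude must have equal length")
    n_min = {"species": 10, "community": 3}.get(level)
    if n_min is None:
        raise ValueError(f"level must be 'species' or 'community', got {level!r}")
    if y.size < n_min:
        raise InsufficientDataError(f"{level}-level trend needs n >= {n_min}, got {y.size}")
    if np.std(x) == 0:
        raise DegenerateFitError("latitude is constant; trend undefined")
    if level == "species":
        return _ols_poly(x, y, 1)
    candidates = [_ols_poly(x, y, 1), _ols_poly(x, y, 2)]
    if allow_exponential and np.all(y > 0):
        lin_on_log = _ols_poly(x, np.log(y), 1)
        # report on the original scale for comparability
        pred = np.exp(lin_on_log.predict(x))
        rss = float(((y - pred) ** 2).sum())
        tss = float(((y - y.mean()) ** 2).sum())
        candidates.append(
            RegressionResult(
                form="exponential",
                coefficients=lin_on_log.coefficients,
                r2=1 - rss / tss if tss > 0 else 0.0,
                p_value=lin_on_log.p_value, n=int(y.size),
                aic=y.size * math.log(max(rss, 1e-300) / y.size) + 2 * 3,
            )
        )
    return min(candidates, key=lambda fit: fit.aic)


def trait_env_regression(trait: Sequence[float], env: Sequence[float]) -> RegressionResult:
    """OLS of a (log10) trait on one environmental covariate."""
    y = np.asarray(trait, dtype=float)
    x = np.asarray(env, dtype=float)
    if y.size != x.size:
        raise ValueError("trait and covariate must have equal length")
    if y.size < 3:
        raise InsufficientDataError(f"regression needs n >= 3, got {y.size}")
    if np.std(x) == 0:
        raise DegenerateFitError("zero-variance covariate")
    return _ols_poly(x, y, 1)


def convert_npp_to_carbon(npp_dry_matter):
    """Dry-matter NPP (g m⁻² yr⁻¹) to carbon units (g C m⁻² yr⁻¹): × 0.5."""
    x = np.asarray(npp_dry_matter, dtype=float)
    if np.any(x < 0):
        raise ValueError("NPP must be non-negative")
    out = DRY_MATTER_TO_CARBON * x
    return float(out) if out.ndim == 0 else out


def npp_association(
    sd_c: Sequence[float],
    sl_c: Sequence[float],
    npp: Sequence[float],
    collinearity_r2_flag: float = 0.9,
) -> NPPAssociation:
    """Site-level NPP against community stomatal traits.

    Separate OLS fits NPP~SD_C and NPP~SL_C, then a two-predictor general
    linear model with sequential (type-I) sum-of-squares attribution.  SD_C
    is entered first by default because the two predictors are strongly
    self-correlated and SD_C is the mechanistically prior one; the report
    carries both entry orders.  Percent attributions over all predictors plus
    the residual sum to 100 of the total NPP sum of squares.
    """
    x1 = np.asarray(sd_c, dtype=float)
    x2 = np.asarray(sl_c, dtype=float)
    y = np.asarray(npp, dtype=float)
    if not (x1.size == x2.size == y.size):
        raise ValueError("sd_c, sl_c and npp must have equal length")
    if y.size < 4:
        raise InsufficientDataError(f"npp_association needs >= 4 sites, got {y.size}")
    if np.std(x1) == 0 or np.std(x2) == 0:
        raise DegenerateFitError("zero-variance community trait predictor")
    fit_sd = _ols_poly(x1, y, 1)
    fit_sl = _ols_poly(x2, y, 1)

    r_pred = float(np.corrcoef(x1, x2)[0, 1]) if np.std(x1) > 0 and np.std(x2) > 0 else 0.0
    predictor_r2 = r_pred ** 2

    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0:
        raise DegenerateFitError("NPP has zero variance")

    def sequential(order):
        n = y.size
        terms = {"sd_c": x1, "sl_c": x2}
        X = np.ones((n, 1))
        rss_prev = tss
        rows = []
        for name in order:
            X = np.column_stack([X, terms[name]])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ beta) ** 2).sum())
            ss_term = rss_prev - rss
            rows.append([name, ss_term])
            rss_prev = rss
        df_err = n - X.shape[1]
        ms_err = rss_prev / df_err if df_err > 0 else float("nan")
        out = []
        for name, ss_term in rows:
            f = ss_term / ms_err if ms_err and ms_err > 0 else float("inf")
            p = float(stats.f.sf(f, 1, df_err)) if df_err > 0 else 0.0
            out.append((name, 100.0 * ss_term / tss, p))
        out.append(("residual", 100.0 * rss_prev / tss, float("nan")))
        return out

    attribution = {
        "sd_c_first": sequential(["sd_c", "sl_c"]),
        "sl_c_first": sequential(["sl_c", "sd_c"]),
    }
    return NPPAssociation(
        fit_sd=fit_sd, fit_sl=fit_sl, attribution=attribution,
        predictor_r2=predictor_r2, collinear=predictor_r2 >= collinearity_r2_flag,
    )
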