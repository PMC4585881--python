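"""Random-intercept linear mixed models and variance partitioning.

The model is y = Xβ + Z u + e with a single random intercept per site,
u ~ N(0, σ²_site I), e ~ N(0, σ² I).  Estimation profiles the variance ratio
λ = σ²_site/σ² in one dimension: for each λ the GLS solve is block-wise
closed-form (Woodbury on the per-site compound-symmetric blocks), and the
restricted (REML) or full (ML) profile log-likelihood is maximized over λ
by bounded scalar optimization.  AIC is always computed from the ML fit so
models with different fixed-effect structures are comparable; REML variances
are the ones reported.

Also provided: the classical nested random-effects ANOVA (species within
sites) by method of moments, used to split trait variance into among-site
and within-site components, and the Pearson-correlation collinearity screen
applied to site-level environmental covariates before model building.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateFitError, InsufficientDataError

__all__ = [
    "MixedModelSpec", "MixedModelResult", "VarianceComponents",
    "fit_lmm", "aic_select", "variance_explained",
    "nested_variance_components", "collinearity_screen",
]

#: default candidate ordering for the collinearity screen
DEFAULT_COVARIATE_PRIORITY = ("mat", "map", "soil_n", "soil_p", "swc", "insolation")


@dataclass(frozen=True)
class MixedModelSpec:
    """Fixed-effect structure of a random-intercept model.

    ``fixed_terms`` contains column names of the data frame (categorical
    columns are expanded with treatment contrasts, reference = first
    alphabetical level) and pairwise interactions written "a:b".
    """

    response: str
    fixed_terms: tuple[str, ...] = ()
    random_term: str = "site_id"

    def __post_init__(self):
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))


@dataclass
class TermTest:
    term: str
    df_num: int
    df_den: float
    f_stat: float
    p_value: float


@dataclass
class MixedModelResult:
    spec: MixedModelSpec
    fixed_estimates: pd.DataFrame  # index: column name; est, se
    term_tests: list[TermTest]
    sigma2_site: float
    sigma2_resid: float
    reml_loglik: float
    ml_loglik: float
    aic_ml: float
    n_obs: int
    n_sites: int
    n_params_fixed: int
    variance_explained: pd.DataFrame | None = None


@dataclass
class VarianceComponents:
    """Among-site vs within-site share of trait variance."""

    within_site_pct: float
    among_site_pct: float
    n_sites: int
    n_obs: int
    detail: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# design matrices


def build_design(data: pd.DataFrame, terms: Sequence[str]):
    """Design matrix with intercept; returns (X, column names, term slices)."""
    n = len(data)
    blocks = [np.ones((n, 1))]
    names = ["Intercept"]
    term_cols: dict[str, list[int]] = {}

    def encode(term: str) -> tuple[np.ndarray, list[str]]:
        if ":" in term:
            left, right = term.split(":", 1)
            xl, nl = encode(left)
            xr, nr = encode(right)
            cols, cnames = [], []
            for i, a in enumerate(nl):
                for j, b in enumerate(nr):
                    cols.append(xl[:, i] * xr[:, j])
                    cnames.append(f"{a}:{b}")
            return np.column_stack(cols), cnames
        col = data[term]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(map(str, pd.unique(col.astype(str))))
            ref = levels[0]
            cols = [(col.astype(str) == lev).to_numpy(float) for lev in levels[1:]]
            if not cols:
                raise DegenerateFitError(f"categorical term {term!r} has a single level")
            return np.column_stack(cols), [f"{term}[{lev}]" for lev in levels[1:]]
        return col.to_numpy(float).reshape(-1, 1), [term]

    idx = 1
    for term in terms:
        xt, cnames = encode(term)
        blocks.append(xt)
        names.extend(cnames)
        term_cols[term] = list(range(idx, idx + len(cnames)))
        idx += len(cnames)
    X = np.column_stack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateFitError(
            f"design matrix is rank deficient (terms: {', '.join(terms) or 'intercept'})"
        )
    return X, names, term_cols


# ---------------------------------------------------------------------------
# profiled REML / ML core


def _gls_pieces(X, y, starts, counts, lam):
    """X'V⁻¹X, X'V⁻¹y, y'V⁻¹y and log|V| for V = I + λ·ZZ' (block closed form)."""
    p = X.shape[1]
    xtx = np.zeros((p, p))
    xty = np.zeros(p)
    yty = 0.0
    logdet = 0.0
    for s, m in zip(starts, counts):
        Xj = X[s : s + m]
        yj = y[s : s + m]
        shrink = lam / (1.0 + lam * m)
        sx = Xj.sum(axis=0)
        sy = yj.sum()
        xtx += Xj.T @ Xj - shrink * np.outer(sx, sx)
        xty += Xj.T @ yj - shrink * sx * sy
        yty += yj @ yj - shrink * sy * sy
        logdet += math.log1p(lam * m)
    return xtx, xty, yty, logdet


def _neg2ll(lam, X, y, starts, counts, reml):
    n, p = X.shape
    xtx, xty, yty, logdet = _gls_pieces(X, y, starts, counts, lam)
    beta = np.linalg.solve(xtx, xty)
    rss = yty - xty @ beta  # r'V⁻¹r at the GLS solution
    rss = max(rss, 1e-300)
    if reml:
        dof = n - p
        sigma2 = rss / dof
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        val = dof * math.log(sigma2) + logdet + logdet_xtx + dof + dof * math.log(2 * math.pi)
    else:
        sigma2 = rss / n
        val = n * math.log(sigma2) + logdet + n + n * math.log(2 * math.pi)
    return val, beta, sigma2, xtx


def _profile_opt(X, y, starts, counts, reml):
    obj = lambda theta: _neg2ll(10.0 ** theta, X, y, starts, counts, reml)[0]
    res = optimize.minimize_scalar(
        obj, bounds=(-10.0, 8.0), method="bounded",
        options={"xatol": 1e-13, "maxiter": 500},
    )
    theta = float(res.x)
    fun = float(res.fun)
    # polish the interior optimum by root-finding the profile score
    if -9.5 < theta < 7.5:
        h = 1e-6
        score = lambda t: (obj(t + h) - obj(t - h)) / (2 * h)
        try:
            s_lo, s_hi = score(theta - 0.05), score(theta + 0.05)
            if s_lo < 0 < s_hi:
                theta = float(optimize.brentq(score, theta - 0.05, theta + 0.05,
                                              xtol=1e-14))
                fun = obj(theta)
        except ValueError:
            pass
    lam = 10.0 ** theta
    val0 = _neg2ll(0.0, X, y, starts, counts, reml)[0]
    if val0 <= fun + 1e-10:  # boundary: no site variance
        lam = 0.0
    val, beta, sigma2, xtx = _neg2ll(lam, X, y, starts, counts, reml)
    return lam, val, beta, sigma2, xtx


def fit_lmm(
    spec: MixedModelSpec,
    data: pd.DataFrame,
    compute_variance_explained: bool = False,
) -> MixedModelResult:
    """Fit a random-intercept mixed model by profiled REML.

    Reports REML variance components, both REML and ML log-likelihoods, the
    ML-based AIC, and per-term Wald F tests with a containment-style
    denominator df (site-level terms tested against sites, observation-level
    terms against residual df).
    """
    cols = {spec.response, spec.random_term}
    for t in spec.fixed_terms:
        cols.update(t.split(":"))
    df = data.dropna(subset=[c for c in cols if c in data.columns]).reset_index(drop=True)
    if df.empty:
        raise InsufficientDataError("no complete observations")
    df = df.sort_values(spec.random_term, kind="stable").reset_index(drop=True)
    groups = df[spec.random_term].astype(str).to_numpy()
    uniq, starts, counts = np.unique(groups, return_index=True, return_counts=True)
    order = np.argsort(starts)
    starts, counts = starts[order], counts[order]

    y = df[spec.response].to_numpy(float)
    X, names, term_cols = build_design(df, spec.fixed_terms)
    n, p = X.shape

    lam, reml_val, beta, sigma2, xtx = _profile_opt(X, y, starts, counts, reml=True)
    _, ml_val, _, _, _ = _profile_opt(X, y, starts, counts, reml=False)
    sigma2_site = lam * sigma2
    cov_beta = sigma2 * np.linalg.inv(xtx)

    reml_loglik = -0.5 * reml_val
    ml_loglik = -0.5 * ml_val
    k = p + 2  # fixed effects + two variances
    aic_ml = -2.0 * ml_loglik + 2.0 * k

    est = pd.DataFrame(
        {"estimate": beta, "se": np.sqrt(np.diag(cov_beta))}, index=names
    )

    # term-wise Wald F tests
    n_sites = len(uniq)
    site_level_cols = _site_level_columns(X, starts, counts)
    q_site = 1 + sum(
        1 for cols_ in term_cols.values() for c in cols_ if c in site_level_cols
    )
    tests = []
    for term, cidx in term_cols.items():
        L = np.zeros((len(cidx), p))
        for row, c in enumerate(cidx):
            L[row, c] = 1.0
        lb = L @ beta
        lvl = L @ cov_beta @ L.T
        fstat = float(lb @ np.linalg.solve(lvl, lb)) / len(cidx)
        if all(c in site_level_cols for c in cidx):
            ddf = max(n_sites - q_site, 1)
        else:
            ddf = max(n - p, 1)
        tests.append(
            TermTest(term=term, df_num=len(cidx), df_den=float(ddf),
                     f_stat=fstat, p_value=float(stats.f.sf(fstat, len(cidx), ddf)))
        )

    result = MixedModelResult(
        spec=spec, fixed_estimates=est, term_tests=tests,
        sigma2_site=float(sigma2_site), sigma2_resid=float(sigma2),
        reml_loglik=float(reml_loglik), ml_loglik=float(ml_loglik),
        aic_ml=float(aic_ml), n_obs=int(n), n_sites=int(n_sites),
        n_params_fixed=int(p),
    )
    if compute_variance_explained:
        result.variance_explained = variance_explained(spec, data, result)
    return result


def _site_level_columns(X, starts, counts) -> set[int]:
    """Columns that are constant within every site (site-level covariates)."""
    out = set()
    for c in range(1, X.shape[1]):
        const = all(
            np.allclose(X[s : s + m, c], X[s, c]) for s, m in zip(starts, counts)
        )
        if const:
            out.add(c)
    return out


def aic_select(
    candidates: Sequence[MixedModelSpec], data: pd.DataFrame
) -> tuple[MixedModelResult, pd.DataFrame]:
    """Fit all candidate specs and return the lowest-ML-AIC fit plus a ranking.

    Candidates must share the response and the observation set; ties are
    broken by fewer fixed parameters, then by candidate order.
    """
    if len(candidates) == 0:
        raise InsufficientDataError("no candidate models")
    responses = {c.response for c in candidates}
    if len(responses) > 1:
        raise ValueError(f"candidates must share a response, got {sorted(responses)}")
    results = [fit_lmm(spec, data) for spec in candidates]
    ns = {r.n_obs for r in results}
    if len(ns) > 1:
        raise ValueError(
            "candidates were fitted on differing observation sets "
            f"(n = {sorted(ns)}); align missing data first"
        )
    ranked = sorted(
        range(len(results)),
        key=lambda i: (results[i].aic_ml, results[i].n_params_fixed, i),
    )
    table = pd.DataFrame(
        {
            "terms": [" + ".join(candidates[i].fixed_terms) or "(intercept)"
                      for i in ranked],
            "aic_ml": [results[i].aic_ml for i in ranked],
            "n_params_fixed": [results[i].n_params_fixed for i in ranked],
            "delta_aic": [results[i].aic_ml - results[ranked[0]].aic_ml
                          for i in ranked],
        }
    )
    return results[ranked[0]], table


def variance_explained(
    spec: MixedModelSpec, data: pd.DataFrame, result: MixedModelResult | None = None
) -> pd.DataFrame:
    """Per-term variance-explained ledger, rescaled to sum to 100%.

    Each fixed term's raw contribution is the drop in the variance of the
    model-implied fixed-effect predictor when the term is removed
    (marginal-R²-style); the site and residual rows carry the REML variance
    components.  Negative drop-term contributions are floored at zero before
    rescaling.
    """
    if result is None:
        result = fit_lmm(spec, data)
    full = result
    cols = {spec.response, spec.random_term}
    for t in spec.fixed_terms:
        cols.update(t.split(":"))
    df = data.dropna(subset=[c for c in cols if c in data.columns]).reset_index(drop=True)
    df = df.sort_values(spec.random_term, kind="stable").reset_index(drop=True)
    X, _, _ = build_design(df, spec.fixed_terms)
    beta = full.fixed_estimates["estimate"].to_numpy()
    var_fixed_full = float(np.var(X @ beta, ddof=1)) if X.shape[1] > 1 else 0.0

    raw = {}
    for term in spec.fixed_terms:
        reduced_terms = tuple(t for t in spec.fixed_terms if t != term)
        red = fit_lmm(MixedModelSpec(spec.response, reduced_terms, spec.random_term), data)
        Xr, _, _ = build_design(df, reduced_terms)
        br = red.fixed_estimates["estimate"].to_numpy()
        var_fixed_red = float(np.var(Xr @ br, ddof=1)) if Xr.shape[1] > 1 else 0.0
        raw[term] = max(0.0, var_fixed_full - var_fixed_red)
    raw["site"] = full.sigma2_site
    raw["residual"] = full.sigma2_resid
    total = sum(raw.values())
    if total <= 0:
        raise DegenerateFitError("zero total variance; nothing to partition")
    ledger = pd.DataFrame(
        {"component": list(raw), "pct": [100.0 * v / total for v in raw.values()]}
    )
    return ledger


# ---------------------------------------------------------------------------
# nested random-effects ANOVA (method of moments)


def nested_variance_components(
    values: Sequence[float], site: Sequence, species: Sequence
) -> VarianceComponents:
    """Among-site vs within-site variance by nested random-effects ANOVA.

    Species are nested within sites.  Components are estimated by equating
    observed to expected mean squares with the unbalanced-design n₀
    coefficients (method of moments); negative estimates are truncated at
    zero.  When every species-at-site has a single record the species and
    residual strata are confounded and the decomposition collapses to the
    one-way site / within-site split.
    """
    y = np.asarray(values, dtype=float)
    site = np.asarray(site, dtype=object)
    species = np.asarray(species, dtype=object)
    if not (y.size == site.size == species.size):
        raise ValueError("values, site and species must have equal length")
    sites = pd.unique(site)
    a = len(sites)
    if a < 2:
        raise InsufficientDataError("among-site variance undefined with a single site")
    N = y.size
    df_all = pd.DataFrame({"y": y, "site": site.astype(str), "sp": species.astype(str)})
    grand = y.sum()
    ss_total = float((y ** 2).sum() - grand ** 2 / N)

    site_g = df_all.groupby("site")["y"]
    t_i = site_g.sum()
    n_i = site_g.count()
    ss_sites = float((t_i ** 2 / n_i).sum() - grand ** 2 / N)

    sub_g = df_all.groupby(["site", "sp"])["y"]
    t_ij = sub_g.sum()
    n_ij = sub_g.count()
    ss_spp = float((t_ij ** 2 / n_ij).sum() - (t_i ** 2 / n_i).sum())
    ss_err = ss_total - ss_sites - ss_spp

    b_total = len(t_ij)
    df_sites = a - 1
    df_spp = b_total - a
    df_err = N - b_total

    ms_sites = ss_sites / df_sites
    sum_nij2_by_site = (n_ij ** 2).groupby(level="site").sum()
    n0_dblprime = (N - float((n_i ** 2).sum()) / N) / df_sites

    if df_err <= 0 or df_spp <= 0:
        # one record per species-at-site (or one species per site): one-way split
        ms_within = (ss_total - ss_sites) / (N - a)
        n0 = n0_dblprime
        s2_site = max(0.0, (ms_sites - ms_within) / n0)
        s2_within = ms_within
        total = s2_site + s2_within
        return VarianceComponents(
            within_site_pct=100.0 * s2_within / total,
            among_site_pct=100.0 * s2_site / total,
            n_sites=a, n_obs=N,
            detail={"sigma2_site": s2_site, "sigma2_within": s2_within,
                    "collapsed_one_way": True},
        )

    ms_spp = ss_spp / df_spp
    ms_err = ss_err / df_err
    n0 = (N - float((sum_nij2_by_site / n_i).sum())) / df_spp
    n0_prime = (float((sum_nij2_by_site / n_i).sum()) - float((n_ij ** 2).sum()) / N) / df_sites

    s2_err = ms_err
    s2_spp = max(0.0, (ms_spp - ms_err) / n0)
    s2_site = max(0.0, (ms_sites - ms_err - n0_prime * s2_spp) / n0_dblprime)
    total = s2_err + s2_spp + s2_site
    return VarianceComponents(
        within_site_pct=100.0 * (s2_spp + s2_err) / total,
        among_site_pct=100.0 * s2_site / total,
        n_sites=a, n_obs=N,
        detail={"sigma2_site": s2_site, "sigma2_species": s2_spp,
                "sigma2_resid": s2_err, "collapsed_one_way": False},
    )


# ---------------------------------------------------------------------------
# collinearity screen


def collinearity_screen(
    env_table: pd.DataFrame,
    alpha: float = 0.05,
    priority: Sequence[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Greedy covariate retention: keep a covariate only if every pairwise
    Pearson correlation with already-kept covariates has p > alpha.

    ``env_table`` holds one row per site.  Candidates are visited in
    ``priority`` order (defaults to the canonical MAT, MAP, soil N, soil P,
    SWC, insolation ranking restricted to present columns, then any others).
    Returns the retained names plus a full pairwise correlation report.
    """
    if len(env_table) < 3:
        raise InsufficientDataError("Pearson correlation needs at least 3 sites")
    numeric = [c for c in env_table.columns if env_table[c].dtype.kind in "fiu"]
    if len(numeric) < 1:
        raise ValueError("no numeric covariates in the environment table")
    if priority is None:
        priority = [c for c in DEFAULT_COVARIATE_PRIORITY if c in numeric]
        priority += [c for c in numeric if c not in priority]
    else:
        missing = [c for c in priority if c not in numeric]
        if missing:
            raise ValueError(f"priority names not in table: {missing}")
        priority = list(priority)

    report_rows = []
    for u, v in itertools.combinations(numeric, 2):
        x, yv = env_table[u].to_numpy(float), env_table[v].to_numpy(float)
        if np.std(x) == 0 or np.std(yv) == 0:
            r, p = float("nan"), 0.0  # constant covariate: treat as conflicting
        else:
            r, p = stats.pearsonr(x, yv)
        report_rows.append({"var1": u, "var2": v, "r": float(r), "p": float(p)})
    report = pd.DataFrame(report_rows)

    pmap = {(row["var1"], row["var2"]): row["p"] for row in report_rows}
    pmap.update({(b, a): p for (a, b), p in list(pmap.items())})
    kept: list[str] = []
    for cand in priority:
        if all(pmap.get((cand, k), 1.0) > alpha for k in kept):
            kept.append(cand)
    return kept, report
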