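"""REML estimation for Gaussian linear mixed models on tree-ring panels.

The models fitted here have the structure used throughout the analysis:
a trait measured yearly on each tree is explained by fixed effects
(year as a categorical factor, cumulative DBH as a covariate, optionally
a grouping factor), a single random intercept (tree or clonal group),
and residuals that may be serially correlated within a tree (first-order
autoregressive on the year lag) and heteroscedastic between the levels
of a grouping factor (per-level residual SD multipliers, reference
level fixed at 1).

Estimation maximizes the restricted likelihood.  With the marginal
covariance written as V = σR²·V0(γ, ρ, m) — γ the random-intercept to
residual variance ratio, ρ the AR(1) coefficient and m the multipliers —
the base residual variance σR² and the fixed effects are profiled out in
closed form, so the numerical optimization runs only over (γ, ρ, m) on
unconstrained scales (log γ, atanh ρ, log m).  V0 is block diagonal over
the levels of the random factor, and each block is assembled from the
within-tree year-lag matrix, so the cost is cubic only in block size.

The restricted log-likelihood convention matches nlme:
l_R = −½ [ log|V| + log|XᵀV⁻¹X| + rᵀV⁻¹r + (n−p)·log 2π ].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

logger = logging.getLogger(__name__)

#: Lower bound on the random-intercept/residual variance ratio; fits at
#: this boundary are reported as a zero variance component.
_GAMMA_FLOOR = 1e-10
_RHO_BOUND = 0.999


class LMMError(RuntimeError):
    pass


class ConvergenceError(LMMError):
    pass


@dataclass
class ModelSpec:
    """Specification of one mixed model.

    ``fixed_terms`` is an ordered list drawn from ``"year"`` (categorical),
    ``"cDBH"`` (numeric covariate) and any grouping column name
    (categorical); an intercept is always included first.  ``random_factor``
    names the random-intercept column (tree or clonal group).  ``ar1``
    switches on AR(1) within-tree serial correlation (lag in years);
    ``heteroscedastic_by`` names a factor whose levels get their own
    residual SD multiplier.
    """

    response: str
    fixed_terms: list = field(default_factory=lambda: ["year", "cDBH"])
    random_factor: str = "tree_id"
    ar1: bool = False
    heteroscedastic_by: str | None = None


@dataclass
class DesignInfo:
    """Frozen design-matrix layout so new data can be encoded identically."""

    columns: list
    term_slices: dict        # term name -> (start, stop) column range
    factor_levels: dict      # categorical term -> ordered level list
    numeric_terms: list


@dataclass
class FittedLMM:
    """A converged REML fit.

    ``sigma2_random`` is the random-intercept variance, ``sigma2_R`` the
    base residual variance (at the reference heteroscedasticity level),
    ``rho`` the AR(1) coefficient (0 when not modelled) and
    ``group_multipliers`` the per-level residual SD ratios.  ``k`` counts
    fixed-effect coefficients plus all variance parameters, and
    AICc = −2·logREML + 2k + 2k(k+1)/(n−k−1).
    """

    spec: ModelSpec
    beta: np.ndarray
    design: DesignInfo
    sigma2_random: float
    sigma2_R: float
    rho: float
    group_multipliers: dict
    logREML: float
    k: int
    n_obs: int
    aicc: float
    converged: bool
    boundary: bool = False


# ---------------------------------------------------------------------------
# design matrices

def _categorical_columns(series: pd.Series, levels: list, term: str) -> np.ndarray:
    codes = pd.Categorical(series, categories=levels).codes
    if np.any(codes < 0):
        unseen = sorted(set(series) - set(levels))
        raise LMMError(f"unseen level(s) {unseen} for factor {term!r}")
    out = np.zeros((len(series), len(levels) - 1))
    for j in range(1, len(levels)):
        out[codes == j, j - 1] = 1.0
    return out


def build_design(data: pd.DataFrame, spec: ModelSpec,
                 info: DesignInfo | None = None) -> tuple[np.ndarray, DesignInfo]:
    """Encode the fixed-effects design matrix for ``spec`` on ``data``.

    Categorical terms are dummy-coded against their first (sorted) level;
    single-level factors are dropped with a warning.  When ``info`` is
    given the stored level sets are reused, so the encoding matches the
    training data (unseen levels raise).
    """
    cols: list = ["(Intercept)"]
    blocks = [np.ones((len(data), 1))]
    term_slices = {"(Intercept)": (0, 1)}
    factor_levels: dict = {}
    numeric_terms: list = []
    pos = 1
    for term in spec.fixed_terms:
        if term == "cDBH" or pd.api.types.is_float_dtype(data[term]):
            blocks.append(data[term].to_numpy(dtype=float)[:, None])
            cols.append(term)
            term_slices[term] = (pos, pos + 1)
            numeric_terms.append(term)
            pos += 1
            continue
        if info is not None:
            levels = info.factor_levels[term]
        else:
            levels = sorted(pd.unique(data[term]), key=str)
        if len(levels) < 2:
            logger.warning("factor %r has a single level: term dropped", term)
            factor_levels[term] = levels
            term_slices[term] = (pos, pos)
            continue
        factor_levels[term] = levels
        block = _categorical_columns(data[term], levels, term)
        blocks.append(block)
        cols.extend(f"{term}[{lv}]" for lv in levels[1:])
        term_slices[term] = (pos, pos + block.shape[1])
        pos += block.shape[1]
    X = np.hstack(blocks)
    if info is None:
        info = DesignInfo(columns=cols, term_slices=term_slices,
                          factor_levels=factor_levels,
                          numeric_terms=numeric_terms)
    return X, info


def _check_full_rank(X: np.ndarray, columns: list) -> None:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [columns[j] for j in np.nonzero(diag < tol)[0]]
    if bad:
        raise LMMError(f"singular fixed-effects design; aliased columns: {bad}")


# ---------------------------------------------------------------------------
# covariance blocks

@dataclass
class _Block:
    X: np.ndarray
    y: np.ndarray
    lag: np.ndarray        # |Δyear| int matrix
    same_tree: np.ndarray  # bool matrix
    het_codes: np.ndarray  # int codes into the multiplier vector


def _prepare_blocks(data: pd.DataFrame, X: np.ndarray, y: np.ndarray,
                    spec: ModelSpec, het_levels: list) -> list:
    df = data.reset_index(drop=True)
    order = df.sort_values([spec.random_factor, "tree_id", "year"]).index.to_numpy()
    blocks = []
    level_of = {lv: i for i, lv in enumerate(het_levels)}
    for _, idx in pd.Series(order).groupby(
            df[spec.random_factor].to_numpy()[order], sort=True):
        ix = idx.to_numpy()
        years = df["year"].to_numpy()[ix].astype(np.int64)
        trees = df["tree_id"].to_numpy()[ix]
        lag = np.abs(years[:, None] - years[None, :])
        same = trees[:, None] == trees[None, :]
        if spec.heteroscedastic_by is not None:
            het = np.array([level_of[v] for v in
                            df[spec.heteroscedastic_by].to_numpy()[ix]])
        else:
            het = np.zeros(len(ix), dtype=int)
        blocks.append(_Block(X=X[ix], y=y[ix], lag=lag,
                             same_tree=same, het_codes=het))
    return blocks


def _unpack(theta: np.ndarray, spec: ModelSpec, n_het: int):
    gamma = math.exp(theta[0])
    i = 1
    rho = 0.0
    if spec.ar1:
        rho = math.tanh(theta[i]) * _RHO_BOUND
        i += 1
    mult = np.ones(n_het)
    if n_het > 1:
        mult[1:] = np.exp(theta[i:i + n_het - 1])
    return gamma, rho, mult


def _profiled_neg_remll(theta: np.ndarray, blocks: list, spec: ModelSpec,
                        n_het: int, p: int, n: int,
                        return_fit: bool = False):
    gamma, rho, mult = _unpack(theta, spec, n_het)
    logdet = 0.0
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    solves = [] if return_fit else None
    for b in blocks:
        m = mult[b.het_codes]
        if spec.ar1:
            corr = np.where(b.same_tree, np.power(rho, b.lag), 0.0)
        else:
            corr = np.eye(len(m))
        v0 = np.outer(m, m) * corr + gamma
        try:
            c, low = linalg.cho_factor(v0, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return (_PENALTY, None) if return_fit else _PENALTY
        logdet += 2.0 * float(np.sum(np.log(np.diag(c))))
        xs = linalg.cho_solve((c, low), b.X, check_finite=False)
        ys = linalg.cho_solve((c, low), b.y, check_finite=False)
        xtvx += b.X.T @ xs
        xtvy += b.X.T @ ys
        ytvy += float(b.y @ ys)
        if return_fit:
            solves.append((c, low))
    try:
        cf = linalg.cho_factor(xtvx, check_finite=False)
    except linalg.LinAlgError:
        return (_PENALTY, None) if return_fit else _PENALTY
    beta = linalg.cho_solve(cf, xtvy, check_finite=False)
    qf = max(ytvy - float(beta @ xtvy), 1e-300)
    sigma2 = qf / (n - p)
    logdet_xtvx = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    neg2 = ((n - p) * math.log(sigma2) + logdet + logdet_xtvx
            + (n - p) + (n - p) * math.log(2 * math.pi))
    if return_fit:
        return 0.5 * neg2, (beta, sigma2, gamma, rho, mult, xtvx)
    return 0.5 * neg2


#: large finite penalty for non-PD covariance proposals (keeps the
#: quasi-Newton line search and finite differences well defined)
_PENALTY = 1e12

_N_RESTARTS = 3


def fit_reml(spec: ModelSpec, data: pd.DataFrame,
             n_restarts: int = _N_RESTARTS) -> FittedLMM:
    """Fit ``spec`` to ``data`` by REML.

    ``data`` must contain the response, every fixed term, ``tree_id``,
    ``year``, and the random factor; rows with missing response are not
    allowed.  Raises :class:`ConvergenceError` when no optimizer start
    converges, and :class:`LMMError` on a singular design.

    ``n_restarts`` controls how many optimizer starts are tried (the
    deterministic moment start plus seeded jitters); large simulation
    studies may use 1 for speed.
    """
    needed = {spec.response, "tree_id", "year", spec.random_factor}
    needed.update(t for t in spec.fixed_terms)
    if spec.heteroscedastic_by:
        needed.add(spec.heteroscedastic_by)
    missing = needed - set(data.columns)
    if missing:
        raise LMMError(f"missing columns: {sorted(missing)}")
    if data[spec.response].isna().any():
        raise LMMError("missing response values")
    if data[spec.random_factor].nunique() < 2:
        raise LMMError("random factor needs at least 2 levels")

    y = data[spec.response].to_numpy(dtype=float)
    X, info = build_design(data, spec)
    _check_full_rank(X, info.columns)
    n, p = X.shape
    if spec.heteroscedastic_by is not None:
        het_levels = sorted(pd.unique(data[spec.heteroscedastic_by]), key=str)
    else:
        het_levels = [None]
    n_het = len(het_levels)
    blocks = _prepare_blocks(data, X, y, spec, het_levels)

    n_var = 2 + int(spec.ar1) + (n_het - 1)
    n_theta = 1 + int(spec.ar1) + (n_het - 1)
    starts = [np.zeros(n_theta)]
    rng = np.random.default_rng(20201021)
    for _ in range(max(n_restarts, 1) - 1):
        starts.append(rng.normal(0.0, 0.8, n_theta))

    best = None
    for x0 in starts:
        res = optimize.minimize(
            _profiled_neg_remll, x0,
            args=(blocks, spec, n_het, p, n),
            method="L-BFGS-B",
            bounds=[(-25.0, 12.0)] * n_theta,
        )
        if not np.isfinite(res.fun) or res.fun >= _PENALTY:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise ConvergenceError(
            f"REML optimization failed for response {spec.response!r}: "
            "no start produced a finite restricted likelihood")

    _, fit = _profiled_neg_remll(best.x, blocks, spec, n_het, p, n,
                                 return_fit=True)
    beta, sigma2_R, gamma, rho, mult, _ = fit
    boundary = gamma <= max(_GAMMA_FLOOR, math.exp(-25.0) * 1.01)
    sigma2_random = 0.0 if boundary else gamma * sigma2_R
    log_reml = -float(best.fun)
    k = p + n_var
    multipliers = ({lv: float(m) for lv, m in zip(het_levels, mult)}
                   if spec.heteroscedastic_by is not None else {})
    return FittedLMM(
        spec=spec, beta=beta, design=info,
        sigma2_random=sigma2_random, sigma2_R=float(sigma2_R),
        rho=float(rho), group_multipliers=multipliers,
        logREML=log_reml, k=k, n_obs=n,
        aicc=aicc(log_reml, k, n) if n > k + 1 else math.nan,
        converged=bool(best.success), boundary=boundary,
    )


def aicc(log_lik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: −2·logL + 2k + 2k(k+1)/(n−k−1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * log_lik + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def extract_variance_components(model: FittedLMM) -> tuple[float, float]:
    """(random-intercept variance, base residual variance) of a fit.

    The residual variance is reported at the reference level of the
    heteroscedasticity factor (multiplier 1).
    """
    return model.sigma2_random, model.sigma2_R


# ---------------------------------------------------------------------------
# prediction on standardized covariate trajectories

def average_annual_increment(cdbh: np.ndarray, years: np.ndarray) -> float:
    """Mean annual DBH increment over a period: (last − first) / span."""
    years = np.asarray(years, dtype=float)
    cdbh = np.asarray(cdbh, dtype=float)
    span = years.max() - years.min()
    if span <= 0:
        raise ValueError("need at least two distinct years")
    first = cdbh[np.argmin(years)]
    last = cdbh[np.argmax(years)]
    return float((last - first) / span)


def standardized_newdata(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Copy of ``data`` with cDBH replaced by the population-average trajectory.

    Every tree is assigned the across-tree mean cDBH of its year, i.e.
    all trees are assumed to follow the average growth of the sample —
    the size standardization used before re-estimating heritability on
    predicted values.
    """
    out = data.copy()
    mean_by_year = data.groupby("year")["cDBH"].mean()
    out["cDBH"] = out["year"].map(mean_by_year)
    return out


def predict_standardized(model: FittedLMM, newdata: pd.DataFrame) -> np.ndarray:
    """Fixed-effects-only predictions (random effects at zero).

    ``newdata`` must use factor levels seen at fit time; unseen levels
    raise.  Typically called on :func:`standardized_newdata` output so
    that size-driven differences between trees are removed.
    """
    X, _ = build_design(newdata, model.spec, info=model.design)
    return X @ model.beta


# ---------------------------------------------------------------------------
# sequential ANOVA of fixed terms

def term_significance(model: FittedLMM, data: pd.DataFrame,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Sequential (type-I) conditional F tests of the fixed terms.

    The data are whitened with the estimated marginal covariance and the
    terms are added in specification order; each term's F statistic is
    the drop in whitened residual sum of squares per numerator df (the
    whitened residual variance is 1 by the REML profiling identity).
    Denominator df follow the containment rule: terms constant within
    the random-factor levels are tested against the between-level df,
    terms varying within levels against the within-level df.
    Returns a frame with term, df_num, df_den, F, p, significant.
    """
    spec = model.spec
    y = data[spec.response].to_numpy(dtype=float)
    X, info = build_design(data, spec, info=model.design)
    n, p = X.shape
    het_levels = (sorted(model.group_multipliers) if model.group_multipliers
                  else [None])
    blocks = _prepare_blocks(data, X, y, spec, het_levels)

    gamma = (model.sigma2_random / model.sigma2_R
             if model.sigma2_R > 0 else 0.0)
    mult = (np.array([model.group_multipliers[lv] for lv in het_levels])
            if model.group_multipliers else np.ones(1))
    wx_parts, wy_parts = [], []
    for b in blocks:
        m = mult[b.het_codes]
        if spec.ar1:
            corr = np.where(b.same_tree, np.power(model.rho, b.lag), 0.0)
        else:
            corr = np.eye(len(m))
        v = model.sigma2_R * (np.outer(m, m) * corr + gamma)
        c = linalg.cholesky(v, lower=True, check_finite=False)
        wx_parts.append(linalg.solve_triangular(c, b.X, lower=True,
                                                check_finite=False))
        wy_parts.append(linalg.solve_triangular(c, b.y, lower=True,
                                                check_finite=False))
    wx = np.vstack(wx_parts)
    wy = np.concatenate(wy_parts)

    # containment: is each column constant within random-factor levels?
    codes = pd.Categorical(data[spec.random_factor]).codes.astype(np.int64)
    n_levels = int(codes.max()) + 1
    col_between = np.zeros(p, dtype=bool)
    order = np.argsort(codes, kind="stable")
    bounds = np.flatnonzero(np.diff(codes[order]) != 0) + 1
    for j in range(p):
        groups = np.split(X[order, j], bounds)
        col_between[j] = all(np.ptp(g) == 0 for g in groups)
    p_between = int(col_between.sum())
    p_within = p - p_between
    df_between = max(n_levels - p_between, 1)
    df_within = max(n - n_levels - p_within, 1)

    def rss(cols_stop: int) -> float:
        sub = wx[:, :cols_stop]
        resid = wy - sub @ np.linalg.lstsq(sub, wy, rcond=None)[0]
        return float(resid @ resid)

    rows = []
    terms = ["(Intercept)"] + list(spec.fixed_terms)
    prev_rss = float(wy @ wy)
    for term in terms:
        start, stop = info.term_slices[term]
        q = stop - start
        if q == 0:
            logger.warning("term %r has no estimable contrast: skipped", term)
            continue
        cur = rss(stop)
        is_between = bool(col_between[start:stop].all())
        df_den = df_between if is_between else df_within
        f_stat = (prev_rss - cur) / q
        p_val = float(stats.f.sf(f_stat, q, df_den))
        rows.append({"term": term, "df_num": q, "df_den": df_den,
                     "F": f_stat, "p": p_val,
                     "significant": p_val < alpha})
        prev_rss = cur
    return pd.DataFrame(rows)
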