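"""Model selection, thresholds and segmented regression.

The statistical layer behind the analyses: predictor standardization with
invertible back-transforms, variance-inflation-factor (VIF) screening of
collinear predictors, fixed-effects GLM fitting (gaussian-identity and
binomial-logit), AICc-based model selection with Akaike weights and
full-model averaging over the ΔAICc < 2 set, Pearson dispersion
diagnostics, extraction of the covariate value at which a logistic response
crosses a probability (e.g. the air temperature at which hatching
probability drops below 50%), two-segment breakpoint regression with a
case-resampling bootstrap CI, and simulation-based power estimation.

Model fitting itself is delegated to statsmodels (OLS; GLM via IRLS); the
selection, averaging, threshold and breakpoint machinery is implemented
here.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import (
    ComparabilityError,
    ConvergenceError,
    DegeneratePredictorError,
    InvalidInputError,
    NoBreakpointError,
    SingularityError,
    UndefinedThresholdError,
)

#: Wald CI multiplier (95%)
Z_95 = 1.96
#: VIF threshold above which predictors may not share an additive model
DEFAULT_VIF_THRESHOLD = 2.0
#: ΔAICc window defining the top model set for averaging
AICC_AVERAGING_WINDOW = 2.0
#: Pearson chi^2/df above which a binomial fit is flagged overdispersed
OVERDISPERSION_FLAG = 1.5


class SeparationWarning(UserWarning):
    """Raised when a logistic fit shows signs of (quasi-)separation."""


# ---------------------------------------------------------------------------
# standardization


@dataclass(frozen=True)
class StandardizeTransform:
    """Stored centre/scale per predictor, invertible for back-mapping."""

    means: dict
    sds: dict

    def forward(self, predictor: str, x):
        return (np.asarray(x) - self.means[predictor]) / self.sds[predictor]

    def inverse(self, predictor: str, z):
        return self.means[predictor] + self.sds[predictor] * np.asarray(z)


def standardize(table: pd.DataFrame, predictors) -> tuple[pd.DataFrame, StandardizeTransform]:
    """Centre (subtract mean) and scale (divide by sd) each predictor."""
    out = table.copy()
    means, sds = {}, {}
    for p in predictors:
        col = table[p].astype(float)
        sd = float(col.std(ddof=1)) if len(col) > 1 else 0.0
        if not np.isfinite(sd) or sd == 0.0:
            raise DegeneratePredictorError(f"predictor {p!r} has zero variance")
        means[p] = float(col.mean())
        sds[p] = sd
        out[p] = (col - means[p]) / sd
    return out, StandardizeTransform(means=means, sds=sds)


# ---------------------------------------------------------------------------
# VIF screening


def _vif_for(X: np.ndarray, j: int) -> float:
    """VIF of column j of X from the auxiliary regression R^2."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return float("inf")
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return 1.0 / (1.0 - r2)


def vif_screen(
    table: pd.DataFrame, predictors, threshold: float = DEFAULT_VIF_THRESHOLD
) -> tuple[dict, list[tuple]]:
    """Variance inflation factors and the maximal admissible predictor sets.

    Returns ``(vifs, subsets)`` where ``vifs`` maps each predictor to its
    VIF in the full design and ``subsets`` lists the maximal subsets within
    which every predictor's VIF stays <= ``threshold`` (such subsets may
    share an additive model; collinear pairs never co-occur).
    """
    predictors = list(predictors)
    if len(predictors) < 2:
        raise InvalidInputError("need >= 2 predictors to screen")
    if len(table) <= len(predictors) + 1:
        raise SingularityError("fewer rows than predictors + intercept")
    X = table[predictors].to_numpy(dtype=float)
    vifs = {p: _vif_for(X, j) for j, p in enumerate(predictors)}

    def admissible(subset) -> bool:
        if len(subset) == 1:
            return True
        idx = [predictors.index(p) for p in subset]
        Xs = X[:, idx]
        return all(_vif_for(Xs, j) <= threshold for j in range(len(idx)))

    found: list[tuple] = []
    for size in range(len(predictors), 0, -1):
        for subset in itertools.combinations(predictors, size):
            if any(set(subset) <= set(big) for big in found):
                continue
            if admissible(subset):
                found.append(subset)
    return vifs, found


# ---------------------------------------------------------------------------
# GLM fitting


@dataclass
class ModelSpec:
    """One candidate model: response ~ predictors (+ pairwise interactions)."""

    response: str
    family: str  # "gaussian" | "binomial"
    predictors: list
    data: pd.DataFrame
    interactions: list = field(default_factory=list)
    weights: str | None = None  # binomial trials column (proportion response)
    name: str | None = None

    def label(self) -> str:
        if self.name:
            return self.name
        terms = list(self.predictors) + [f"{a}:{b}" for a, b in self.interactions]
        return " + ".join(terms) if terms else "1"


@dataclass
class FitResult:
    """Coefficients, Wald CIs and AICc bookkeeping for one fitted model."""

    spec: ModelSpec
    params: pd.Series
    se: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    loglik: float
    n: int
    k: int
    aicc: float
    dispersion: float
    converged: bool = True

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.values,
                "se": self.se.values,
                "ci_lower": self.ci_lower.values,
                "ci_upper": self.ci_upper.values,
            }
        )


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise InvalidInputError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _design(spec: ModelSpec) -> tuple[pd.Series, pd.DataFrame]:
    data = spec.data
    y = data[spec.response].astype(float)
    X = pd.DataFrame(index=data.index)
    X["Intercept"] = 1.0
    for p in spec.predictors:
        X[p] = data[p].astype(float)
    for a, b in spec.interactions:
        X[f"{a}:{b}"] = data[a].astype(float) * data[b].astype(float)
    return y, X


def fit_glm(spec: ModelSpec, maxiter: int = 100) -> FitResult:
    """Fit one candidate by maximum likelihood.

    Gaussian-identity models use ordinary least squares; binomial-logit
    models use iteratively reweighted least squares. ``k`` counts estimated
    parameters (coefficients, plus the residual variance for gaussian
    models) for the AICc correction. Suspected separation in logistic fits
    emits a :class:`SeparationWarning`.
    """
    y, X = _design(spec)
    n, p = X.shape
    if n <= p + 1:
        raise InvalidInputError(f"n={n} too small for {p} coefficients")
    if np.linalg.matrix_rank(X.to_numpy()) < p:
        raise SingularityError("design matrix is rank deficient")

    if spec.family == "gaussian":
        res = sm.OLS(y, X).fit()
        k = p + 1  # + residual variance
        dispersion = float(res.ssr / (n - p))
        loglik = float(res.llf)
    elif spec.family == "binomial":
        var_weights = (
            spec.data[spec.weights].astype(float).to_numpy()
            if spec.weights
            else np.ones(n)
        )
        model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=var_weights)
        res = model.fit(maxiter=maxiter)
        if not res.converged:
            raise ConvergenceError(f"IRLS did not converge in {maxiter} iterations")
        eta = np.asarray(X.to_numpy() @ res.params.to_numpy(), dtype=float)
        if np.any(np.abs(eta) > 30):
            warnings.warn(
                "extreme fitted log-odds: possible separation", SeparationWarning
            )
        k = p
        dispersion = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else float("nan")
        loglik = float(res.llf)
    else:
        raise InvalidInputError(f"unknown family {spec.family!r}")

    params = pd.Series(np.asarray(res.params, dtype=float), index=X.columns)
    se = pd.Series(np.asarray(res.bse, dtype=float), index=X.columns)
    return FitResult(
        spec=spec,
        params=params,
        se=se,
        ci_lower=params - Z_95 * se,
        ci_upper=params + Z_95 * se,
        loglik=loglik,
        n=n,
        k=k,
        aicc=aicc(loglik, k, n),
        dispersion=dispersion,
    )


# ---------------------------------------------------------------------------
# model selection and averaging


def akaike_weights(aicc_values) -> np.ndarray:
    """Normalized relative likelihoods w_i = exp(-Δ_i/2) / Σ exp(-Δ_j/2)."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ModelSet:
    """Ranked candidate models with weights and averaged coefficients."""

    fits: list  # sorted by AICc
    delta_aicc: np.ndarray
    weights: np.ndarray
    averaging_mask: np.ndarray  # ΔAICc < 2
    averaged_coefficients: pd.Series

    @property
    def best(self) -> FitResult:
        return self.fits[0]

    def table(self) -> pd.DataFrame:
        """Per-term table mirroring a supplementary model-selection table."""
        rows = []
        for fit, d, w in zip(self.fits, self.delta_aicc, self.weights):
            for term in fit.params.index:
                rows.append(
                    {
                        "model": fit.spec.label(),
                        "term": term,
                        "estimate": fit.params[term],
                        "se": fit.se[term],
                        "ci_lower": fit.ci_lower[term],
                        "ci_upper": fit.ci_upper[term],
                        "aicc": fit.aicc,
                        "delta_aicc": d,
                        "weight": w,
                    }
                )
        return pd.DataFrame(rows)


def model_selection(candidates) -> ModelSet:
    """Fit candidates, rank by AICc and average the ΔAICc < 2 set.

    Candidates must be fitted on identical rows (checked on n and row
    index). Averaging is *full* (zero-substitution): a term absent from a
    model contributes 0 with that model's weight.
    """
    specs = list(candidates)
    if not specs:
        raise InvalidInputError("no candidate models")
    fits = [c if isinstance(c, FitResult) else fit_glm(c) for c in specs]
    idx0 = fits[0].spec.data.index
    for f in fits[1:]:
        if f.n != fits[0].n or not f.spec.data.index.equals(idx0):
            raise ComparabilityError("candidates fitted on differing row sets")
    order = np.argsort([f.aicc for f in fits], kind="stable")
    fits = [fits[i] for i in order]
    a = np.array([f.aicc for f in fits])
    w = akaike_weights(a)
    delta = a - a[0]
    mask = delta < AICC_AVERAGING_WINDOW
    w_set = w[mask] / w[mask].sum()
    terms: list[str] = []
    for f, m in zip(fits, mask):
        if m:
            terms.extend(t for t in f.params.index if t not in terms)
    avg = pd.Series(0.0, index=terms)
    for f, wi in zip([f for f, m in zip(fits, mask) if m], w_set):
        for t in f.params.index:
            avg[t] += wi * f.params[t]
    return ModelSet(
        fits=fits,
        delta_aicc=delta,
        weights=w,
        averaging_mask=mask,
        averaged_coefficients=avg,
    )


@dataclass(frozen=True)
class DispersionResult:
    ratio: float
    overdispersed: bool


def dispersion_check(fit: FitResult, flag_above: float = OVERDISPERSION_FLAG) -> DispersionResult:
    """Pearson chi^2 / residual df for a binomial fit; flags ratio > 1.5.

    Stands in for an observation-level random effect as the overdispersion
    diagnostic: a ratio well above 1 means the binomial variance is too
    small for the data.
    """
    if fit.spec.family != "binomial":
        raise InvalidInputError("dispersion check is defined for binomial fits")
    ratio = fit.dispersion
    return DispersionResult(ratio=ratio, overdispersed=bool(ratio > flag_above))


# ---------------------------------------------------------------------------
# logistic threshold


def threshold_from_logistic(
    fit: FitResult,
    transform: StandardizeTransform,
    predictor: str,
    p: float = 0.5,
) -> float:
    """Covariate value (original units) where the fitted probability equals p.

    Solves logit(p) = b0 + b1*z on the standardized scale and back-maps z
    through the stored centre/scale.
    """
    if not 0.0 < p < 1.0:
        raise InvalidInputError("p must lie in (0, 1)")
    b0 = float(fit.params["Intercept"])
    b1 = float(fit.params[predictor])
    if b1 == 0.0:
        raise UndefinedThresholdError("zero slope: threshold undefined")
    z = (math.log(p / (1.0 - p)) - b0) / b1
    return float(transform.inverse(predictor, z))


# ---------------------------------------------------------------------------
# segmented (breakpoint) regression


def _segment_rss_prefix(xs: np.ndarray, ys: np.ndarray):
    """RSS of separate OLS lines below/above every split index, via prefix sums."""
    n = len(xs)
    ones = np.ones(n)
    cs = {
        "n": np.concatenate([[0.0], np.cumsum(ones)]),
        "x": np.concatenate([[0.0], np.cumsum(xs)]),
        "y": np.concatenate([[0.0], np.cumsum(ys)]),
        "xx": np.concatenate([[0.0], np.cumsum(xs * xs)]),
        "xy": np.concatenate([[0.0], np.cumsum(xs * ys)]),
        "yy": np.concatenate([[0.0], np.cumsum(ys * ys)]),
    }

    def seg_rss(lo_idx, hi_idx):
        m = cs["n"][hi_idx] - cs["n"][lo_idx]
        sx = cs["x"][hi_idx] - cs["x"][lo_idx]
        sy = cs["y"][hi_idx] - cs["y"][lo_idx]
        sxx = cs["xx"][hi_idx] - cs["xx"][lo_idx]
        sxy = cs["xy"][hi_idx] - cs["xy"][lo_idx]
        syy = cs["yy"][hi_idx] - cs["yy"][lo_idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            sxx_c = sxx - sx * sx / m
            sxy_c = sxy - sx * sy / m
            syy_c = syy - sy * sy / m
            slope_part = np.where(sxx_c > 1e-12, sxy_c**2 / np.where(sxx_c > 1e-12, sxx_c, 1.0), 0.0)
        return np.maximum(syy_c - slope_part, 0.0)

    return seg_rss


def _best_breakpoint(
    x: np.ndarray,
    y: np.ndarray,
    grid_step: float,
    min_points: int,
) -> tuple[float, float]:
    """(breakpoint, total RSS) minimizing two independent-segment OLS RSS.

    The split is searched on a regular grid (step ``grid_step``); RSS is
    piecewise constant between data points, so tying grid candidates are
    resolved by their midpoint.
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(xs)
    i_lo, i_hi = min_points, n - min_points
    if i_hi < i_lo:
        raise NoBreakpointError(f"need >= {min_points} points on each side")
    seg_rss = _segment_rss_prefix(xs, ys)
    idx = np.arange(i_lo, i_hi + 1)
    rss = seg_rss(np.zeros_like(idx), idx) + seg_rss(idx, np.full_like(idx, n))
    lo_x, hi_x = xs[i_lo - 1], xs[i_hi]
    if hi_x <= lo_x:
        raise NoBreakpointError("no admissible split: tied covariate values")
    start = math.floor(lo_x / grid_step) * grid_step
    grid = np.arange(start, hi_x + grid_step, grid_step)
    grid = grid[(grid > lo_x) & (grid <= hi_x)]
    if len(grid) == 0:
        grid = np.array([0.5 * (lo_x + hi_x)])
    gi = np.searchsorted(xs, grid, side="left") - i_lo
    gi = np.clip(gi, 0, len(idx) - 1)
    grid_rss = rss[gi]
    best = grid_rss.min()
    tol = 1e-10 * max(best, 1.0)
    ties = grid[grid_rss <= best + tol]
    return float(0.5 * (ties.min() + ties.max())), float(best)


@dataclass
class BreakpointFit:
    """Two-segment fit: threshold estimate, bootstrap CI and segment models."""

    breakpoint: float
    ci_lower: float
    ci_upper: float
    below: FitResult
    above: FitResult
    rss: float
    n_below: int
    n_above: int
    n_bootstrap: int
    uninformative: bool


def fit_breakpoint(
    x,
    y,
    grid_step: float = 0.01,
    ci_bootstrap_reps: int = 1000,
    seed: int | None = None,
    min_points: int = 10,
    xname: str = "x",
    yname: str = "y",
) -> BreakpointFit:
    """Breakpoint of a two-segment regression with a bootstrap CI.

    The breakpoint is the covariate value splitting the data into two
    independently fitted OLS segments (continuity not enforced) with
    minimal total RSS, searched on a 0.01-unit grid with >= ``min_points``
    points per side. The 95% CI is a case-resampling percentile bootstrap
    (widened, if necessary, to contain the point estimate). A CI spanning
    more than 80% of the covariate range is flagged uninformative.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2 * min_points:
        raise InvalidInputError(f"need >= {2 * min_points} (x, y) points")
    bp, rss = _best_breakpoint(x, y, grid_step, min_points)

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(ci_bootstrap_reps):
        idx = rng.integers(0, len(x), len(x))
        try:
            b, _ = _best_breakpoint(x[idx], y[idx], grid_step, min_points)
        except NoBreakpointError:
            continue
        boots.append(b)
    if len(boots) >= max(50, ci_bootstrap_reps // 2):
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo, hi = x.min(), x.max()
    lo, hi = min(float(lo), bp), max(float(hi), bp)

    below_mask = x < bp
    data_lo = pd.DataFrame({yname: y[below_mask], xname: x[below_mask]})
    data_hi = pd.DataFrame({yname: y[~below_mask], xname: x[~below_mask]})
    below = fit_glm(ModelSpec(yname, "gaussian", [xname], data_lo, name="below"))
    above = fit_glm(ModelSpec(yname, "gaussian", [xname], data_hi, name="above"))
    return BreakpointFit(
        breakpoint=bp,
        ci_lower=lo,
        ci_upper=hi,
        below=below,
        above=above,
        rss=rss,
        n_below=int(below_mask.sum()),
        n_above=int((~below_mask).sum()),
        n_bootstrap=len(boots),
        uninformative=bool((hi - lo) > 0.8 * (x.max() - x.min())),
    )


# ---------------------------------------------------------------------------
# simulation-based power


@dataclass(frozen=True)
class PowerEstimate:
    power: float
    mc_se: float
    reps: int


def estimate_power(
    effect: float,
    n: int,
    term: str = "main",
    alpha: float = 0.05,
    reps: int = 1000,
    seed: int | None = None,
    residual_sd: float = 1.0,
) -> PowerEstimate:
    """Power to detect one coefficient in a main-effect + interaction design.

    Each replicate draws a continuous covariate x ~ N(0,1), a centred
    binary group g in {-1/2, +1/2}, and y = effect*focal + noise, where the
    focal term is x (``term="main"``) or x*g (``term="interaction"``). The
    full model (x, g, x:g) is fitted by OLS and the focal Wald CI (t-based)
    checked against zero. Returns the rejection fraction and its binomial
    Monte-Carlo standard error. With ``effect=0`` this calibrates the
    type-I error to alpha.
    """
    if reps < 100:
        raise InvalidInputError("reps must be >= 100")
    if term not in ("main", "interaction"):
        raise InvalidInputError("term must be 'main' or 'interaction'")
    rng = np.random.default_rng(seed)
    p = 4  # intercept, x, g, x:g
    tcrit = scipy.stats.t.ppf(1 - alpha / 2, df=n - p)
    hits = 0
    col = 1 if term == "main" else 3
    for _ in range(reps):
        xv = rng.standard_normal(n)
        g = rng.integers(0, 2, n) - 0.5
        X = np.column_stack([np.ones(n), xv, g, xv * g])
        y = effect * X[:, col] + residual_sd * rng.standard_normal(n)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - p)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = math.sqrt(cov[col, col])
        if abs(beta[col]) > tcrit * se:
            hits += 1
    power = hits / reps
    return PowerEstimate(
        power=power, mc_se=math.sqrt(power * (1 - power) / reps), reps=reps
    )
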