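"""Bernoulli generalized functional linear models (scalar-on-function logit).

The model for a binary outcome y_i (GSD use) with scalar covariates z_i and
at most one functional covariate x_i(t) on [0, 30] s is

    logit P(y_i = 1) = gamma_0 + z_i' gamma + \\int_0^30 x_i(t) beta(t) dt

where the regression curve beta(t) = sum_k b_k B_k(t) is expanded in a
B-spline basis.  The integral reduces the functional term to a row of
basis-integrated covariate values, so the model is an ordinary logistic
regression in (gamma, b), fitted by iteratively reweighted least squares
with an optional light ridge penalty on the basis coefficients only (the
scalar block is never penalized).

The fitted curve's pointwise 95% band and the time intervals where it
excludes zero localize when the sway signal carries class information.
Backward selection with AIC over the scalar features implements the
study's variable-selection step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.stats import norm

from .features import GRID

_MAX_LP = 35.0  # linear-predictor clamp: expit saturates well before this


@dataclass(frozen=True)
class BasisSpec:
    """Equally spaced B-spline basis on the test's time domain."""

    n_basis: int = 10
    degree: int = 3
    domain: tuple[float, float] = (0.0, 30.0)

    def __post_init__(self):
        if self.n_basis < self.degree + 1:
            raise ValueError("n_basis must be at least degree + 1")

    @property
    def knots(self) -> np.ndarray:
        lo, hi = self.domain
        n_interior = self.n_basis - self.degree - 1
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
        return np.concatenate([
            np.full(self.degree + 1, lo), interior, np.full(self.degree + 1, hi)
        ])

    def design(self, times: np.ndarray) -> np.ndarray:
        """Basis function values B_k(t): shape (len(times), n_basis)."""
        times = np.clip(np.asarray(times, dtype=float), *self.domain)
        return BSpline.design_matrix(times, self.knots, self.degree).toarray()


def functional_design(
    values: np.ndarray, basis: BasisSpec, grid: np.ndarray | None = None
) -> np.ndarray:
    """Integrate functional covariates against the basis functions.

    Row i, entry k approximates \\int x_i(t) B_k(t) dt by the trapezoidal
    rule.  The grid (0.1 ... 30 s) excludes the left domain endpoint, so the
    curve is linearly extrapolated to t=0 from its first two grid values
    before integrating; this makes the quadrature exact for integrands that
    are linear in t over the full domain.
    """
    if grid is None:
        grid = GRID
    X = np.atleast_2d(np.asarray(values, dtype=float))
    if X.shape[1] != len(grid):
        raise ValueError(f"covariate length {X.shape[1]} does not match grid {len(grid)}")
    lo, hi = basis.domain
    if grid[0] < lo or grid[-1] > hi:
        raise ValueError("grid extends outside the basis domain")
    if grid[0] > lo:
        t = np.concatenate([[lo], grid])
        # linear extrapolation of both x(t) and the integrand to t = lo
        x0 = X[:, 0] + (X[:, 0] - X[:, 1]) * (grid[0] - lo) / (grid[1] - grid[0])
        X = np.column_stack([x0, X])
    else:
        t = np.asarray(grid, dtype=float)
    B = basis.design(t)  # (len(t), n_basis)
    w = np.zeros(len(t))
    dt = np.diff(t)
    w[:-1] += dt / 2
    w[1:] += dt / 2
    return (X * w) @ B


@dataclass
class FittedFGLM:
    """A fitted Bernoulli functional GLM."""

    coef: np.ndarray  # (intercept, scalars..., basis coefficients...)
    names: list[str]
    cov: np.ndarray  # inverse penalized observed information
    loglik: float  # unpenalized log-likelihood at the solution
    aic: float
    converged: bool
    n_scalar: int  # columns before the basis block (incl. intercept)
    basis: BasisSpec | None = None
    separation: bool = False
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def scalar_coef(self) -> np.ndarray:
        return self.coef[: self.n_scalar]

    @property
    def basis_coef(self) -> np.ndarray:
        return self.coef[self.n_scalar:]

    @property
    def basis_cov(self) -> np.ndarray:
        return self.cov[self.n_scalar:, self.n_scalar:]


def _bernoulli_loglik(lp: np.ndarray, y: np.ndarray) -> float:
    # numerically stable: -log(1+exp(-lp)) for y=1, -log(1+exp(lp)) for y=0
    return float(-np.sum(np.logaddexp(0.0, np.where(y == 1, -lp, lp))))


def fit_bernoulli(
    X: np.ndarray,
    y: np.ndarray,
    ridge_penalty: float = 0.0,
    n_basis: int = 0,
    names: list[str] | None = None,
    basis: BasisSpec | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> FittedFGLM:
    """Maximize the (ridge-penalized) Bernoulli log-likelihood by IRLS.

    ``X`` must contain the intercept column; the last ``n_basis`` columns
    are the functional block, the only block the ridge penalty applies to.
    Newton steps are halved whenever they would decrease the penalized
    log-likelihood, so the iteration is monotone.  Convergence is declared
    when the relative change in penalized log-likelihood drops below
    ``tol``; AIC uses the raw parameter count and unpenalized likelihood.

    Complete or quasi-complete separation (diverging coefficients) is
    reported through ``separation`` on the result, never silently.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n != len(y):
        raise ValueError("X and y disagree on sample count")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcome must be binary 0/1")
    if n <= p:
        warnings.warn(f"fitting {p} parameters on {n} subjects", stacklevel=2)
    pen = np.zeros(p)
    if n_basis:
        pen[p - n_basis:] = ridge_penalty
    P = np.diag(pen)

    beta = np.zeros(p)
    lp = X @ beta
    pll_prev = _bernoulli_loglik(lp, y)  # penalty term is 0 at beta=0
    path = [pll_prev]
    converged = False
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-np.clip(lp, -_MAX_LP, _MAX_LP)))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        grad = X.T @ (y - mu) - pen * beta
        H = (X.T * w) @ X + P
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving keeps the penalized log-likelihood monotone
        scale = 1.0
        for _half in range(30):
            cand = beta + scale * step
            lp_c = X @ cand
            pll = _bernoulli_loglik(lp_c, y) - 0.5 * np.sum(pen * cand**2)
            if pll >= pll_prev - 1e-12:
                break
            scale /= 2
        beta, lp = cand, lp_c
        path.append(pll)
        # scale-guarded criterion: near-separated fits have loglik -> 0, so a
        # purely relative test would spin; max(1, |ll|) keeps it meaningful.
        # Under detected separation the likelihood plateaus while coefficients
        # drift outward; once the plateau is flat to 1e-6 further Newton
        # steps carry no information, so that also counts as converged
        # (the separation flag still reports the degeneracy).
        delta = abs(pll - pll_prev)
        stalled = np.max(np.abs(beta)) > 30.0 and delta <= 1e-6
        if delta <= tol * max(1.0, abs(pll_prev)) or stalled:
            converged = True
            pll_prev = pll
            break
        pll_prev = pll

    mu = 1.0 / (1.0 + np.exp(-np.clip(lp, -_MAX_LP, _MAX_LP)))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    H = (X.T * w) @ X + P
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    cov = (cov + cov.T) / 2
    ll = _bernoulli_loglik(lp, y)
    separation = bool(np.max(np.abs(beta)) > 30.0)
    return FittedFGLM(
        coef=beta,
        names=list(names) if names is not None else [f"x{j}" for j in range(p)],
        cov=cov,
        loglik=ll,
        aic=2.0 * p - 2.0 * ll,
        converged=converged,
        n_scalar=p - (n_basis or 0),
        basis=basis,
        separation=separation,
        loglik_path=np.asarray(path),
    )


def _scalar_design(features: pd.DataFrame, columns: list[str]) -> tuple[np.ndarray, list[str]]:
    X = np.column_stack([np.ones(len(features))] + [features[c].to_numpy(float) for c in columns])
    return X, ["intercept"] + list(columns)


def backward_select_aic(
    features: pd.DataFrame,
    y: np.ndarray,
    candidates: list[str] | None = None,
) -> tuple[list[str], list[float]]:
    """Backward selection with AIC over scalar features.

    Starting from the model with all candidates, repeatedly drop the single
    feature whose removal most decreases AIC; stop when no removal helps.
    Ties break toward the earlier candidate.  Returns the selected feature
    names (original order) and the AIC trace, full model first.
    """
    if candidates is None:
        candidates = list(features.columns)
    current = list(candidates)

    def _aic(cols: list[str], strict: bool = True) -> float:
        X, names = _scalar_design(features, cols)
        fit = fit_bernoulli(X, y, names=names)
        if strict and not fit.converged:
            raise _NonConvergence(cols)
        return fit.aic

    trace = [_aic(current, strict=False)]
    while current:
        best_aic, best_drop = trace[-1], None
        for feat in current:  # earlier candidate wins ties via strict <
            cols = [c for c in current if c != feat]
            try:
                aic = _aic(cols)
            except _NonConvergence:
                warnings.warn(
                    f"skipping removal of {feat!r}: candidate fit did not converge",
                    stacklevel=2,
                )
                continue
            if aic < best_aic - 1e-10:
                best_aic, best_drop = aic, feat
        if best_drop is None:
            break
        current.remove(best_drop)
        trace.append(best_aic)
    return current, trace


class _NonConvergence(Exception):
    pass


def fit_with_functional(
    features: pd.DataFrame,
    selected: list[str],
    functional: np.ndarray | None,
    y: np.ndarray,
    basis: BasisSpec | None = None,
    ridge_penalty: float = 1e-4,
) -> FittedFGLM:
    """Fit the combined model: selected scalars plus 0 or 1 functional covariate.

    ``functional`` is an (n_subjects, 300) matrix of one functional
    covariate, or None for the scalar-only model.  Supplying more than one
    functional covariate is not supported: the design targets cohorts too
    small to identify several regression curves at once.
    """
    X, names = _scalar_design(features, list(selected))
    y = np.asarray(y, dtype=float)
    if functional is None:
        return fit_bernoulli(X, y, names=names)
    functional = np.asarray(functional, dtype=float)
    if functional.ndim != 2:
        raise ValueError(
            "expected a single (n_subjects, n_grid) functional covariate; "
            "models with more than one functional covariate are not supported"
        )
    if basis is None:
        basis = BasisSpec()
    F = functional_design(functional, basis)
    Xf = np.column_stack([X, F])
    names = names + [f"basis_{k}" for k in range(basis.n_basis)]
    return fit_bernoulli(
        Xf, y, ridge_penalty=ridge_penalty, n_basis=basis.n_basis,
        names=names, basis=basis,
    )


@dataclass(frozen=True)
class RegressionCurve:
    """beta(t) with a pointwise confidence band and its significant region."""

    grid: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    significant_region: list[tuple[float, float]]


def regression_curve(
    fit: FittedFGLM,
    basis: BasisSpec | None = None,
    grid: np.ndarray | None = None,
    level: float = 0.95,
) -> RegressionCurve:
    """Evaluate beta(t) = sum b_k B_k(t) with a pointwise confidence band.

    The band at each time is the estimate +/- z * SE(t) with SE(t)^2 =
    B(t)' Cov(b) B(t); the significant region collects the maximal grid
    intervals where the band excludes zero.
    """
    if not fit.converged:
        raise ValueError("cannot build a regression curve from a non-converged fit")
    if basis is None:
        basis = fit.basis
    if basis is None:
        raise ValueError("fit has no functional block")
    if grid is None:
        grid = np.linspace(*basis.domain, 301)
    B = basis.design(grid)
    est = B @ fit.basis_coef
    var = np.einsum("ij,jk,ik->i", B, fit.basis_cov, B)
    se = np.sqrt(np.maximum(var, 0.0))
    z = norm.ppf(0.5 + level / 2)
    lower, upper = est - z * se, est + z * se

    sig = (lower > 0) | (upper < 0)
    region: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(sig):
        if flag and start is None:
            start = grid[i]
        elif not flag and start is not None:
            region.append((float(start), float(grid[i - 1])))
            start = None
    if start is not None:
        region.append((float(start), float(grid[-1])))
    return RegressionCurve(
        grid=np.asarray(grid, float), estimate=est, lower=lower, upper=upper,
        level=level, significant_region=region,
    )


def predict_probability(
    fit: FittedFGLM,
    features: np.ndarray,
    functional: np.ndarray | None = None,
    unable_flag: bool = False,
) -> float:
    """Predicted probability of GSD use for one subject.

    A subject unable to complete the balance tests unassisted is predicted
    GSD+ outright (probability 1.0): such a subject is less stable than any
    subject who finished the tests, so the model is bypassed.
    """
    if unable_flag:
        return 1.0
    features = np.atleast_1d(np.asarray(features, dtype=float))
    if len(features) != fit.n_scalar - 1:
        raise ValueError(
            f"expected {fit.n_scalar - 1} scalar features, got {len(features)}"
        )
    lp = fit.coef[0] + features @ fit.coef[1:fit.n_scalar]
    n_basis = len(fit.coef) - fit.n_scalar
    if n_basis:
        if functional is None:
            raise ValueError("fit includes a functional block but no covariate was given")
        row = functional_design(np.atleast_2d(functional), fit.basis)[0]
        lp += row @ fit.basis_coef
    elif functional is not None:
        raise ValueError("fit has no functional block but a covariate was given")
    return float(1.0 / (1.0 + np.exp(-np.clip(lp, -_MAX_LP, _MAX_LP))))
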