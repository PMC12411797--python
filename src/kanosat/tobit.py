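"""Two-limit Tobit regression of rating deviations on topic attention.

A review's satisfaction outcome is its positive deviation PD = max(rating −
comprehensive, 0); its dissatisfaction outcome is the negative deviation
ND = max(comprehensive − rating, 0).  Ratings are 1..5 stars and the
comprehensive (store-level aggregate) rating lies in [1, 5], so both
deviations live on [0, 4] and are censored at those limits: the latent
linear response

    y*_i = x_i' beta + delta_i,   delta_i ~ Normal(0, sigma^2)

is observed as y_i = min(max(y*_i, L), U) with L = 0, U = 4.  The model is
fit by maximizing the two-limit censored-normal log-likelihood

    sum_{L<y<U} [ log phi((y − x'b)/s) − log s ]
  + sum_{y=L}   log Phi((L − x'b)/s)
  + sum_{y=U}   log(1 − Phi((U − x'b)/s)),

with standard errors from the inverse observed information at the optimum.
Covariates are per-topic attention values (min-max normalized document–
topic probabilities) in [0, 1]; no intercept is included by default.

The satisfaction (PD) and dissatisfaction (ND) models are fit separately;
coefficient asymmetry between them is tested per topic with a Wald
statistic using the independent-variance formula (the two fits share
observations, so an optional bootstrap covariance is provided for
sensitivity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from statsmodels.tools import numdiff

__all__ = [
    "DeviationOutcome",
    "TobitConfig",
    "TobitFit",
    "WaldResult",
    "compute_deviations",
    "minmax_normalize",
    "tobit_loglik",
    "fit_tobit",
    "fit_both_models",
    "wald_asymmetry",
    "wald_from_summary",
    "bootstrap_wald_asymmetry",
    "vif",
]


@dataclass
class DeviationOutcome:
    """Per-review one-sided deviations; for every review pd = 0 or nd = 0."""

    pd: np.ndarray
    nd: np.ndarray

    def __post_init__(self):
        self.pd = np.asarray(self.pd, dtype=float)
        self.nd = np.asarray(self.nd, dtype=float)
        if self.pd.shape != self.nd.shape:
            raise ValueError("pd and nd must be aligned")


def compute_deviations(
    ratings: Sequence[int], comprehensive: Sequence[float]
) -> DeviationOutcome:
    """One-sided gaps between a user's stars and the app's aggregate rating.

    pd_i = max(rating_i − comprehensive_i, 0) measures satisfaction beyond
    the consensus; nd_i = max(comprehensive_i − rating_i, 0) dissatisfaction
    below it.  Exactly one of the two is nonzero (or both are zero).
    """
    r = np.asarray(ratings, dtype=float)
    c = np.asarray(comprehensive, dtype=float)
    if r.shape != c.shape:
        raise ValueError("ratings and comprehensive ratings must be aligned")
    if np.any((r < 1) | (r > 5)) or np.any(r != np.round(r)):
        raise ValueError("ratings must be integers in 1..5")
    if np.any((c < 1) | (c > 5)):
        raise ValueError("comprehensive ratings must lie in [1, 5]")
    diff = r - c
    return DeviationOutcome(pd=np.maximum(diff, 0.0), nd=np.maximum(-diff, 0.0))


def minmax_normalize(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise min-max compression of document-topic probabilities to [0, 1].

    Returns (attention matrix, constant-column flags); constant columns map
    to all zeros and are flagged because they carry no regression signal.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta contains non-finite entries")
    lo = theta.min(axis=0)
    hi = theta.max(axis=0)
    span = hi - lo
    constant = span == 0
    safe_span = np.where(constant, 1.0, span)
    x = (theta - lo) / safe_span
    x[:, constant] = 0.0
    return x, constant


@dataclass(frozen=True)
class TobitConfig:
    lower: float = 0.0
    upper: float = 4.0
    include_intercept: bool = False
    tol: float = 1e-8
    max_iter: int = 500

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")


@dataclass
class TobitFit:
    beta: np.ndarray
    sigma: float
    se: np.ndarray  # per coefficient, sigma's SE in se_sigma
    se_sigma: float
    p: np.ndarray
    loglik: float
    converged: bool
    n_left: int
    n_interior: int
    n_right: int
    config: TobitConfig
    names: list[str]

    @property
    def n(self) -> int:
        return self.n_left + self.n_interior + self.n_right


def _censoring_masks(y: np.ndarray, lower: float, upper: float):
    left = y <= lower
    right = y >= upper
    interior = ~(left | right)
    return left, interior, right


def tobit_loglik(
    y: np.ndarray, X: np.ndarray, beta: np.ndarray, sigma: float,
    lower: float = 0.0, upper: float = 4.0,
) -> float:
    """Two-limit censored-normal log-likelihood at given (beta, sigma)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    mu = X @ beta
    left, interior, right = _censoring_masks(y, lower, upper)
    ll = 0.0
    if interior.any():
        ll += float(
            np.sum(stats.norm.logpdf((y[interior] - mu[interior]) / sigma) - np.log(sigma))
        )
    if left.any():
        ll += float(np.sum(stats.norm.logcdf((lower - mu[left]) / sigma)))
    if right.any():
        ll += float(np.sum(stats.norm.logsf((upper - mu[right]) / sigma)))
    return ll


def _negloglik_and_grad(params, y, X, lower, upper, left, interior, right):
    """Negative loglik and gradient in (beta, log sigma) parametrization."""
    beta = params[:-1]
    log_sigma = params[-1]
    sigma = np.exp(log_sigma)
    mu = X @ beta
    ll = 0.0
    grad_beta = np.zeros_like(beta)
    grad_ls = 0.0
    if interior.any():
        r = (y[interior] - mu[interior]) / sigma
        ll += float(np.sum(stats.norm.logpdf(r) - log_sigma))
        grad_beta += X[interior].T @ (r / sigma)
        grad_ls += float(np.sum(r * r - 1.0))
    if left.any():
        a = (lower - mu[left]) / sigma
        ll += float(np.sum(stats.norm.logcdf(a)))
        lam = np.exp(stats.norm.logpdf(a) - stats.norm.logcdf(a))  # inverse Mills
        grad_beta += X[left].T @ (-lam / sigma)
        grad_ls += float(np.sum(-lam * a))
    if right.any():
        b = (upper - mu[right]) / sigma
        ll += float(np.sum(stats.norm.logsf(b)))
        lam = np.exp(stats.norm.logpdf(b) - stats.norm.logsf(b))
        grad_beta += X[right].T @ (lam / sigma)
        grad_ls += float(np.sum(lam * b))
    grad = np.append(grad_beta, grad_ls)
    return -ll, -grad


def fit_tobit(
    y: np.ndarray,
    X: np.ndarray,
    config: TobitConfig | None = None,
    names: Sequence[str] | None = None,
) -> TobitFit:
    """Maximum-likelihood two-limit Tobit fit.

    Starts from the least-squares solution (sigma from its residuals) and
    ascends the censored likelihood with BFGS on (beta, log sigma); SEs come
    from the inverse observed information (numerical Hessian) in the
    (beta, sigma) parametrization and p-values from the normal reference.
    """
    config = config or TobitConfig()
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.shape[0] != X.shape[0]:
        raise ValueError("y and X must have the same number of rows")
    if config.include_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > {p + 1} observations to fit {p} coefficients plus sigma")
    if names is None:
        names = [f"x{j}" for j in range(p - int(config.include_intercept))]
    names = (["intercept"] if config.include_intercept else []) + list(names)
    left, interior, right = _censoring_masks(y, config.lower, config.upper)
    if not interior.any():
        raise ValueError("every observation is censored; the model is not identified")
    if np.all(X == 0):
        raise ValueError("design matrix has no variation (all zeros)")
    # OLS start
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    sigma0 = float(np.std(resid))
    if sigma0 <= 0 or not np.isfinite(sigma0):
        sigma0 = 1.0
    x0 = np.append(beta0, np.log(sigma0))
    args = (y, X, config.lower, config.upper, left, interior, right)
    result = optimize.minimize(
        _negloglik_and_grad, x0, args=args, jac=True, method="BFGS",
        options={"gtol": config.tol, "maxiter": config.max_iter},
    )
    # BFGS can report precision loss while sitting at the optimum; accept the
    # solution when the gradient is negligible relative to the loglik scale
    grad_ok = bool(np.max(np.abs(result.jac)) <= 1e-6 * max(1.0, abs(float(result.fun))))
    converged = bool(result.success) or grad_ok
    if not converged:
        warnings.warn(
            f"Tobit optimizer did not converge: {result.message}", RuntimeWarning, stacklevel=2
        )
    beta = result.x[:-1]
    sigma = float(np.exp(result.x[-1]))

    # observed information in the (beta, sigma) parametrization
    def _nll_sigma(params):
        return -tobit_loglik(y, X, params[:-1], params[-1], config.lower, config.upper)

    hess = numdiff.approx_hess(np.append(beta, sigma), _nll_sigma)
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        warnings.warn("observed information is singular; SEs unavailable", RuntimeWarning,
                      stacklevel=2)
        se_all = np.full(p + 1, np.nan)
    se = se_all[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        zscores = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zscores))
    return TobitFit(
        beta=beta,
        sigma=sigma,
        se=se,
        se_sigma=float(se_all[-1]),
        p=pvals,
        loglik=float(-result.fun),
        converged=converged,
        n_left=int(left.sum()),
        n_interior=int(interior.sum()),
        n_right=int(right.sum()),
        config=config,
        names=names,
    )


def fit_both_models(
    deviations: DeviationOutcome,
    X: np.ndarray,
    config: TobitConfig | None = None,
    names: Sequence[str] | None = None,
) -> tuple[TobitFit, TobitFit]:
    """Model 1 (satisfaction): PD on attention; Model 2 (dissatisfaction): ND on attention."""
    fit_pd = fit_tobit(deviations.pd, X, config, names)
    fit_nd = fit_tobit(deviations.nd, X, config, names)
    return fit_pd, fit_nd


@dataclass
class WaldResult:
    statistic: float
    df: int
    p: float
    mode: str


def wald_from_summary(
    beta_pd: float, se_pd: float, beta_nd: float, se_nd: float, mode: str = "difference"
) -> WaldResult:
    """Wald test of coefficient asymmetry from summary statistics.

    mode 'difference' tests beta_pd = beta_nd; 'sign_flipped_difference'
    tests beta_pd = −beta_nd (useful when the two models' effects are
    expected to mirror each other).  Variances are added as if independent.
    """
    if mode not in ("difference", "sign_flipped_difference"):
        raise ValueError(f"unknown mode {mode!r}")
    s = 1.0 if mode == "difference" else -1.0
    denom = se_pd**2 + se_nd**2
    if denom <= 0:
        raise ValueError("zero variance; Wald statistic undefined")
    w = (beta_pd - s * beta_nd) ** 2 / denom
    return WaldResult(statistic=float(w), df=1, p=float(stats.chi2.sf(w, df=1)), mode=mode)


def wald_asymmetry(
    fit_pd: TobitFit, fit_nd: TobitFit, topic: int, mode: str = "difference"
) -> WaldResult:
    """Per-topic asymmetry test between the satisfaction and dissatisfaction fits."""
    if not (fit_pd.converged and fit_nd.converged):
        raise ValueError("both fits must have converged")
    if not (0 <= topic < len(fit_pd.beta)) or len(fit_pd.beta) != len(fit_nd.beta):
        raise ValueError("topic index out of range or fits incompatible")
    return wald_from_summary(
        fit_pd.beta[topic], fit_pd.se[topic], fit_nd.beta[topic], fit_nd.se[topic], mode
    )


def bootstrap_wald_asymmetry(
    deviations: DeviationOutcome,
    X: np.ndarray,
    topic: int,
    config: TobitConfig | None = None,
    mode: str = "difference",
    n_boot: int = 200,
    seed: int = 0,
) -> WaldResult:
    """Wald asymmetry with a bootstrap variance of the coefficient contrast.

    Resamples reviews with replacement and refits both models, estimating
    Var(beta_pd − s·beta_nd) including their covariance — the sensitivity
    check for the independent-variance formula, which ignores that the two
    outcomes come from the same reviews.
    """
    if mode not in ("difference", "sign_flipped_difference"):
        raise ValueError(f"unknown mode {mode!r}")
    s = 1.0 if mode == "difference" else -1.0
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    fit_pd, fit_nd = fit_both_models(deviations, X, config)
    contrast = fit_pd.beta[topic] - s * fit_nd.beta[topic]
    draws = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        dev_b = DeviationOutcome(pd=deviations.pd[idx], nd=deviations.nd[idx])
        f1, f2 = fit_both_models(dev_b, X[idx], config)
        draws[b] = f1.beta[topic] - s * f2.beta[topic]
    var = float(np.var(draws, ddof=1))
    if var <= 0:
        raise ValueError("zero bootstrap variance; Wald statistic undefined")
    w = contrast**2 / var
    return WaldResult(statistic=float(w), df=1, p=float(stats.chi2.sf(w, df=1)), mode=mode)


def vif(
    X: np.ndarray, names: Sequence[str] | None = None, include_intercept: bool = True
) -> dict[str, float]:
    """Variance inflation factors: 1/(1 − R²) of each column on the rest.

    By default the auxiliary regressions include an intercept and R² is
    centered.  For an intercept-free main model (the attention design,
    whose columns are affinely tied through the topic-probability simplex
    and would be flagged as perfectly collinear with an intercept) pass
    ``include_intercept=False`` for the uncentered variant.  Perfectly
    collinear columns report ``inf`` with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("VIF needs at least two columns")
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    out: dict[str, float] = {}
    for j in range(k):
        yj = X[:, j]
        if np.ptp(yj) == 0:
            raise ValueError(f"column {names[j]!r} is constant")
        others = np.delete(X, j, axis=1)
        if include_intercept:
            others = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_res = float(resid @ resid)
        center = yj.mean() if include_intercept else 0.0
        ss_tot = float(np.sum((yj - center) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0 - 1e-12:
            warnings.warn(
                f"column {names[j]!r} is perfectly collinear with the others",
                RuntimeWarning, stacklevel=2,
            )
            out[names[j]] = float("inf")
        else:
            out[names[j]] = float(1.0 / (1.0 - r2))
    return out
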