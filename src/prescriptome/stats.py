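"""Statistical primitives shared by every analysis stage.

The centrepiece is :func:`fit_bayes_logistic`, a separation-robust logistic
regression that returns the posterior mode under independent weakly
informative priors (Cauchy by default, following the convention of putting
scale 2.5 on slopes and 10 on the intercept after centering binary
predictors and rescaling continuous predictors to SD 0.5).  Under complete
separation — a drug prescribed only to readmitted patients, say — the
maximum-likelihood estimate diverges, while the posterior mode stays finite
with a usable curvature-based standard error.

Everything else (BH step-up, Wilson intervals, Fisher's exact test,
hypergeometric tails, Welch's t) delegates to scipy / statsmodels behind a
stable in-package surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PriorSpec",
    "FitResult",
    "ContingencyTable2x2",
    "fit_bayes_logistic",
    "penalized_loglik",
    "wald_or_ci",
    "bh_adjust",
    "wilson_interval",
    "fisher_exact_2x2",
    "hypergeom_tail",
    "welch_t_test",
    "haldane_odds_ratio",
    "format_p",
]

#: display floor for human-readable reports; machine output keeps full precision
P_FLOOR = 2.2e-16


@dataclass(frozen=True)
class PriorSpec:
    """Independent prior on each regression coefficient.

    family
        ``"cauchy"`` (Student t with 1 df), ``"student_t"`` or ``"flat"``
        (no penalty: ordinary maximum likelihood, not separation-robust).
    scale_coeff / scale_intercept
        Prior scales applied on the internally standardized predictor scale.
    df
        Degrees of freedom for the Student-t family.
    """

    family: str = "cauchy"
    scale_coeff: float = 2.5
    scale_intercept: float = 10.0
    df: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in {"cauchy", "student_t", "flat"}:
            raise ValueError(f"unknown prior family: {self.family!r}")
        if self.family != "flat":
            if not (self.scale_coeff > 0 and self.scale_intercept > 0):
                raise ValueError("prior scales must be > 0")
            if self.df < 1:
                raise ValueError("prior df must be >= 1")

    @property
    def effective_df(self) -> float:
        return 1.0 if self.family == "cauchy" else self.df


@dataclass
class FitResult:
    """Posterior-mode logistic fit: coefficients on the original data scale."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    converged: bool
    n_iter: int
    penalized_loglik: float
    cov: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    term_names: tuple[str, ...] = ()

    def term_index(self, term: str | int) -> int:
        if isinstance(term, int):
            return term
        try:
            return self.term_names.index(term)
        except ValueError:
            raise KeyError(f"term {term!r} not in fit (terms: {self.term_names})")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d) = (exposed-case, exposed-control, unexposed-case,
    unexposed-control)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


# ---------------------------------------------------------------------------
# penalized logistic regression
# ---------------------------------------------------------------------------


def _prior_scales(p: int, prior: PriorSpec) -> np.ndarray:
    """Per-term prior scales; column 0 is the intercept by convention."""
    s = np.full(p, prior.scale_coeff)
    s[0] = prior.scale_intercept
    return s


def _log_prior(beta: np.ndarray, scales: np.ndarray, df: float) -> float:
    # independent scaled Student-t log densities (Cauchy when df == 1)
    z2 = (beta / scales) ** 2
    const = (
        math.lgamma((df + 1) / 2)
        - math.lgamma(df / 2)
        - 0.5 * math.log(df * math.pi)
    )
    return float(np.sum(const - np.log(scales) - (df + 1) / 2 * np.log1p(z2 / df)))


def _log_prior_grad_hess(
    beta: np.ndarray, scales: np.ndarray, df: float
) -> tuple[np.ndarray, np.ndarray]:
    v = df * scales**2
    denom = v + beta**2
    grad = -(df + 1) * beta / denom
    hess = -(df + 1) * (v - beta**2) / denom**2  # d2/dbeta2 of log prior
    return grad, hess


def penalized_loglik(
    y: np.ndarray, X: np.ndarray, beta: np.ndarray, prior: PriorSpec
) -> float:
    """Bernoulli log-likelihood plus independent prior log densities.

    Evaluated on whatever scale ``X`` is supplied in; used both by the
    optimizer and as the quantity oracle tests compare at the mode.
    """
    eta = X @ beta
    # numerically stable: sum y*eta - log(1+exp(eta))
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    if prior.family == "flat":
        return ll
    return ll + _log_prior(beta, _prior_scales(X.shape[1], prior), prior.effective_df)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center every non-intercept column; rescale non-binary columns to SD 0.5.

    Returns (Xs, shift, scale) with  Xs[:, j] = (X[:, j] - shift[j]) / scale[j].
    """
    n, p = X.shape
    shift = np.zeros(p)
    scale = np.ones(p)
    for j in range(1, p):
        col = X[:, j]
        shift[j] = col.mean()
        uniq = np.unique(col)
        if uniq.size > 2:  # continuous: SD 0.5 convention
            sd = col.std(ddof=0)
            if sd > 0:
                scale[j] = 2.0 * sd
    Xs = (X - shift) / scale
    Xs[:, 0] = 1.0
    return Xs, shift, scale


def fit_bayes_logistic(
    y: np.ndarray,
    X: np.ndarray,
    prior: PriorSpec | None = None,
    *,
    term_names: tuple[str, ...] | list[str] | None = None,
    standardize: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> FitResult:
    """Posterior mode of a logistic regression with independent t-family priors.

    Parameters
    ----------
    y, X
        Binary outcome and design matrix; column 0 of ``X`` must be the
        intercept (all ones).
    prior
        Prior specification; defaults to Cauchy(2.5) slopes / Cauchy(10)
        intercept on the standardized scale.
    standardize
        Apply the center/rescale convention internally before the prior and
        back-transform the mode and covariance to the original data scale.
        Reported coefficients are always on the original scale.

    Notes
    -----
    Newton iterations with step-halving on the penalized log-likelihood;
    the Cauchy log-prior is not concave for ``|beta| > scale`` so the Hessian
    is Levenberg-damped toward positive definiteness when needed.  Standard
    errors come from the inverse observed information (negative Hessian of
    the log posterior) at the mode.
    """
    prior = prior or PriorSpec()
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X have incompatible shapes")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("y must be binary 0/1")
    if not np.allclose(X[:, 0], 1.0):
        raise ValueError("X[:, 0] must be the intercept column of ones")

    if standardize:
        Xw, shift, scale = _standardize(X)
    else:
        Xw, shift, scale = X, np.zeros(p), np.ones(p)

    flat = prior.family == "flat"
    scales = _prior_scales(p, prior)
    df = prior.effective_df

    def objective(beta: np.ndarray) -> float:
        return penalized_loglik(y, Xw, beta, prior)

    beta = np.zeros(p)
    beta[0] = math.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6))
    f = objective(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xw @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = Xw.T @ (y - mu)
        hess = -(Xw.T * w) @ Xw  # of log-likelihood
        if not flat:
            pg, ph = _log_prior_grad_hess(beta, scales, df)
            grad = grad + pg
            hess = hess + np.diag(ph)
        # solve (-hess + tau I) step = grad, damping until PD
        A = -hess
        tau = 0.0
        for _ in range(20):
            try:
                L = np.linalg.cholesky(A + tau * np.eye(p))
                break
            except np.linalg.LinAlgError:
                tau = max(1e-8, 10.0 * tau) if tau else 1e-8
        step = np.linalg.solve(A + tau * np.eye(p), grad)
        # step-halving
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            fc = objective(cand)
            if np.isfinite(fc) and fc >= f - 1e-12:
                break
            t /= 2.0
        else:
            cand, fc = beta, f
        delta = np.max(np.abs(cand - beta))
        beta, f = cand, fc
        if delta < tol:
            converged = True
            break

    # observed information at the mode
    eta = Xw @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (Xw.T * w) @ Xw
    if not flat:
        _, ph = _log_prior_grad_hess(beta, scales, df)
        info = info - np.diag(ph)
    try:
        cov_s = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov_s = np.linalg.pinv(info)

    # back-transform:  eta = b0 + sum_j bj * (xj - mj)/dj
    #   => slope_orig_j = bj/dj ;  b0_orig = b0 - sum bj mj/dj
    A = np.zeros((p, p))
    A[0, 0] = 1.0
    for j in range(1, p):
        A[j, j] = 1.0 / scale[j]
        A[0, j] = -shift[j] / scale[j]
    coef = A @ beta
    cov = A @ cov_s @ A.T
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    return FitResult(
        coefficients=coef,
        standard_errors=se,
        converged=converged,
        n_iter=it,
        penalized_loglik=f,
        cov=cov,
        term_names=tuple(term_names) if term_names is not None else tuple(f"x{j}" for j in range(p)),
    )


def wald_or_ci(
    fit: FitResult, term: str | int, level: float = 0.95
) -> tuple[float, float, float, float]:
    """Odds ratio, (lo, hi) CI and two-sided normal p for one fitted term."""
    j = fit.term_index(term)
    beta = fit.coefficients[j]
    se = fit.standard_errors[j]
    z = sps.norm.ppf(0.5 + level / 2.0)
    or_ = math.exp(beta)
    lo, hi = math.exp(beta - z * se), math.exp(beta + z * se)
    p = 2.0 * sps.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
    return or_, lo, hi, p


# ---------------------------------------------------------------------------
# classical small-sample machinery
# ---------------------------------------------------------------------------


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order kept."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    lo = 0.0 if k == 0 else min(max(float(lo), 0.0), k / n)
    hi = 1.0 if k == n else max(min(float(hi), 1.0), k / n)
    return lo, hi


def haldane_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample cross-product OR; 0.5 added to every cell when any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def fisher_exact_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact p (point-probability rule) and Haldane-corrected OR.

    An all-zero table returns (1.0, nan): there is no information and the
    odds ratio is undefined.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if table.total == 0:
        return 1.0, float("nan")
    p = float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return min(p, 1.0), haldane_odds_ratio(a, b, c, d)


def hypergeom_tail(N: int, m: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, m, n).

    ``m`` and ``n`` are the two set sizes drawn from a universe of ``N``;
    ``k`` is the observed overlap.
    """
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError("set sizes must lie in [0, N]")
    if not 0 <= k <= min(m, n):
        raise ValueError("overlap k must lie in [0, min(m, n)]")
    return float(sps.hypergeom.sf(k - 1, N, m, n))


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sided t-test: (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def format_p(p: float) -> str:
    """Human-readable p with the conventional display floor."""
    if p < P_FLOOR:
        return "< 2.2e-16"
    return f"{p:.3g}"
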