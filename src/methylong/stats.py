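"""Statistical primitives shared by every stage of the pipeline.

Everything here is a small, closed-form-checkable building block: Huber
robust regression (single response and a batched many-phenotype variant
used by the per-CpG scans), Benjamini-Hochberg FDR, Bonferroni
thresholds, inverse-variance fixed-effect meta-analysis, 2x2 chi-square
and Fisher tests, a one-sample proportion test that survives titanic z
values, permutation-calibrated selection of control-probe principal
components, and Pearson correlation.

All tests are two-sided unless stated otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.utils.extmath import randomized_svd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Huber tuning constant giving 95% efficiency under Gaussian errors.
DEFAULT_HUBER_TUNING = 1.345
#: Consistency factor making the MAD estimate sigma for Gaussian data.
MAD_CONSISTENCY = 1.4826


@dataclass
class RegressionFit:
    """Result of a robust (Huber M-estimator) linear regression."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    two_sided_p: np.ndarray
    n_obs: int
    converged: bool
    n_iterations: int


@dataclass
class BatchRegressionFit:
    """Per-phenotype Huber fits sharing one design matrix.

    Arrays are shaped (n_phenotypes, n_predictors) except ``converged``
    which is per phenotype.
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    two_sided_p: np.ndarray
    n_obs: int
    converged: np.ndarray
    n_iterations: int


@dataclass
class MetaResult:
    """Inverse-variance fixed-effect meta-analysis result."""

    beta: float
    se: float
    z: float
    p: float
    n_studies: int


@dataclass
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in counts):
            raise ValueError("2x2 table counts must be non-negative")
        if sum(counts) == 0:
            raise ValueError("2x2 table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class PCSelection:
    """Outcome of permutation-calibrated PC selection on control probes."""

    n_selected: int
    scores: np.ndarray  # samples x n_selected
    p_values: np.ndarray  # permutation p per leading PC examined
    variances: np.ndarray  # observed PC variances examined
    n_perm: int = field(default=0)


def _as_table(t) -> ContingencyTable2x2:
    if isinstance(t, ContingencyTable2x2):
        return t
    a, b, c, d = t
    return ContingencyTable2x2(int(a), int(b), int(c), int(d))


# ---------------------------------------------------------------------------
# Huber robust regression
# ---------------------------------------------------------------------------

def _mad_scale(residuals: np.ndarray) -> np.ndarray:
    """Median absolute deviation scale (about the median), per row."""
    med = np.median(residuals, axis=1, keepdims=True)
    s = MAD_CONSISTENCY * np.median(np.abs(residuals - med), axis=1)
    return np.maximum(s, 1e-12)


def _huber_irls(
    X: np.ndarray,
    Y: np.ndarray,
    tuning: float,
    max_iter: int,
    tol: float,
):
    n, k = X.shape
    if Y.shape[1] != n:
        raise ValueError("response length does not match design matrix rows")
    if n <= k:
        raise ValueError("need more observations than predictors")
    if np.linalg.matrix_rank(X) < k:
        raise np.linalg.LinAlgError("design matrix is rank deficient")

    beta = np.linalg.lstsq(X, Y.T, rcond=None)[0].T  # (P, k)
    converged = np.zeros(Y.shape[0], dtype=bool)
    n_iter = 0
    for it in range(max_iter):
        R = Y - beta @ X.T
        s = _mad_scale(R)
        u = np.abs(R) / s[:, None]
        w = np.minimum(1.0, tuning / np.maximum(u, 1e-300))
        if k == 1:  # scalar normal equations (the per-CpG location scans)
            x2 = (X[:, 0] ** 2)[None, :]
            new = ((w * Y * X[:, 0][None, :]).sum(axis=1)
                   / (w * x2).sum(axis=1))[:, None]
        else:
            A = np.einsum("pn,ni,nj->pij", w, X, X, optimize=True)
            b = np.einsum("pn,ni->pi", w * Y, X, optimize=True)
            new = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        delta = np.max(np.abs(new - beta), axis=1)
        beta = new
        n_iter = it + 1
        converged = delta < tol
        if converged.all():
            break

    # M-estimator sandwich standard errors; reduces exactly to the OLS
    # formula when no residual is clipped (psi(u) = u everywhere).
    R = Y - beta @ X.T
    s = _mad_scale(R)
    u = R / s[:, None]
    psi = np.clip(u, -tuning, tuning)
    psi_prime_mean = np.maximum(np.mean(np.abs(u) <= tuning, axis=1), 1e-12)
    num = np.sum(psi**2, axis=1) / (n - k)
    scale_factor = (s**2) * num / (psi_prime_mean**2)
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.outer(scale_factor, np.diag(XtX_inv)))

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(
            se > 0,
            beta / np.where(se > 0, se, 1.0),
            np.where(beta == 0, 0.0, np.inf),
        )
    p = 2.0 * sps.t.sf(np.abs(t_stat), df=n - k)
    return beta, se, t_stat, p, converged, n_iter


def huber_regress(
    X,
    y,
    tuning: float = DEFAULT_HUBER_TUNING,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> RegressionFit:
    """Huber M-estimate via IRLS with MAD scale re-estimated per iteration.

    Non-convergence within ``max_iter`` is flagged in the result, never
    raised. P-values use a t reference with n - k degrees of freedom.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    beta, se, t_stat, p, conv, n_iter = _huber_irls(
        X, y[None, :], tuning, max_iter, tol
    )
    if not conv[0]:
        logger.warning("huber_regress did not converge in %d iterations", n_iter)
    return RegressionFit(
        coefficients=beta[0],
        standard_errors=se[0],
        t_statistics=t_stat[0],
        two_sided_p=p[0],
        n_obs=X.shape[0],
        converged=bool(conv[0]),
        n_iterations=n_iter,
    )


def huber_regress_many(
    X,
    Y,
    tuning: float = DEFAULT_HUBER_TUNING,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> BatchRegressionFit:
    """Huber fits of many phenotypes (rows of ``Y``) on one design matrix.

    This is the workhorse of the per-CpG scans: one IRLS loop runs all
    phenotypes simultaneously with per-phenotype weights and scales.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    beta, se, t_stat, p, conv, n_iter = _huber_irls(X, Y, tuning, max_iter, tol)
    return BatchRegressionFit(
        coefficients=beta,
        standard_errors=se,
        t_statistics=t_stat,
        two_sided_p=p,
        n_obs=X.shape[0],
        converged=conv,
        n_iterations=n_iter,
    )


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test threshold controlling the family-wise error at ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# Meta-analysis
# ---------------------------------------------------------------------------

def ivw_meta(betas, ses) -> MetaResult:
    """Fixed-effect meta-analysis with inverse-variance (1/se^2) weights."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.shape != ses.shape or betas.ndim != 1 or betas.size == 0:
        raise ValueError("betas and ses must be equal-length non-empty vectors")
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    z = beta / se
    p = min(1.0, math.exp(math.log(2.0) + sps.norm.logsf(abs(z))))
    return MetaResult(beta=beta, se=se, z=z, p=p, n_studies=betas.size)


def ivw_meta_arrays(betas: np.ndarray, ses: np.ndarray):
    """Vectorized IVW meta over columns = studies, rows = tests.

    Returns (beta, se, z, p) arrays, one entry per row.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    beta = np.sum(w * betas, axis=1) / np.sum(w, axis=1)
    se = 1.0 / np.sqrt(np.sum(w, axis=1))
    z = beta / se
    p = np.minimum(1.0, np.exp(np.log(2.0) + sps.norm.logsf(np.abs(z))))
    return beta, se, z, p


# ---------------------------------------------------------------------------
# 2x2 tables
# ---------------------------------------------------------------------------

def chi2_2x2(t) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1."""
    t = _as_table(t)
    arr = t.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("2x2 table has a zero margin")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def fisher_exact_2x2(t, sided: str = "two") -> float:
    """Exact hypergeometric p for a 2x2 table.

    Two-sided p sums the probabilities of all tables (at fixed margins)
    no more probable than the observed one.
    """
    t = _as_table(t)
    alternative = {"two": "two-sided", "greater": "greater"}.get(sided)
    if alternative is None:
        raise ValueError("sided must be 'two' or 'greater'")
    return float(sps.fisher_exact(t.as_array(), alternative=alternative)[1])


def prop_test_one_sample(successes: int, n: int, p0: float) -> tuple[float, float]:
    """One-sample proportion z-test (no continuity correction).

    The two-sided p is assembled in log space, so extreme z values give
    the correct subnormal-range p instead of underflowing to zero.
    """
    if n == 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be between 0 and n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    phat = successes / n
    z = (phat - p0) / math.sqrt(p0 * (1.0 - p0) / n)
    log_p = math.log(2.0) + sps.norm.logsf(abs(z))
    try:
        p = min(1.0, math.exp(log_p))
    except OverflowError:  # pragma: no cover
        p = 0.0
    return z, p


# ---------------------------------------------------------------------------
# Control-probe PCA with permutation selection
# ---------------------------------------------------------------------------

def _leading_pc_variances(Z: np.ndarray, k: int, random_state: int) -> np.ndarray:
    """Variances of the top-k PCs of a column-standardized matrix."""
    n, p = Z.shape
    if min(n, p) <= 2 * k + 20:
        sv = np.linalg.svd(Z, compute_uv=False)[:k]
    else:
        _, sv, _ = randomized_svd(
            Z, n_components=k, n_oversamples=15, n_iter=5,
            random_state=random_state,
        )
    return sv**2 / (n - 1)


def pca_permutation_select(
    control,
    n_perm: int = 10000,
    alpha: float = 1e-4,
    max_components: int = 10,
    random_state: int = 0,
) -> PCSelection:
    """Select leading control-probe PCs against a permutation null.

    PCA runs on the column-standardized control matrix (samples x control
    probes). Each permutation shuffles every probe column independently,
    destroying sample structure while keeping marginals; the k-th PC's
    permutation p is the plain ratio (count of permuted k-th variances
    exceeding the observed one) / n_perm. Leading PCs are accepted while
    p < alpha and selection stops at the first failure, since variance
    ordering makes gaps uninterpretable.
    """
    X = np.asarray(control, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("control matrix needs at least 2 rows and 2 columns")
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    n = X.shape[0]
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.info("dropping %d constant control probe columns", int((~keep).sum()))
        X = X[:, keep]
        sd = sd[keep]
        if X.shape[1] < 2:
            raise ValueError("fewer than 2 non-constant control probes")
    Z = (X - X.mean(axis=0)) / sd

    K = int(min(max_components, n - 1, Z.shape[1]))
    obs_var = _leading_pc_variances(Z, K, random_state)

    rng = np.random.default_rng(random_state)
    exceed = np.zeros(K)
    for _ in range(n_perm):
        Zp = rng.permuted(Z, axis=0)  # shuffle every probe column independently
        exceed += _leading_pc_variances(Zp, K, random_state) > obs_var
    p_values = exceed / n_perm

    n_selected = 0
    for k in range(K):
        if p_values[k] < alpha:
            if exceed[k] == 0:
                logger.info("PC%d permutation p < 1/%d", k + 1, n_perm)
            n_selected += 1
        else:
            break

    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :n_selected] * S[:n_selected]
    return PCSelection(
        n_selected=n_selected,
        scores=scores,
        p_values=p_values,
        variances=obs_var,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of two non-constant vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("inputs must not be constant")
    return float(sps.pearsonr(x, y).statistic)
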