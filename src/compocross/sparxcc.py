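"""SparXCC: sparse cross-correlations between two compositional datasets.

Case C: microbiome counts x (p OTUs) and a second compositional dataset y
(q genes, fungal OTUs, ...), both sequenced on the same n replicates.  The
target is the p x q matrix of Corr[log a_i, log b_k] between the latent
absolute abundances.  Writing C_ik = Cov[log x_i, log y_k] (pseudo-counted),
every log-ratio cross-covariance expands into four C terms, and the double
sum over reference pairs

    t_ik = sum_{j != i} sum_{l != k} Cov[log(x_i/x_j), log(y_k/y_l)]

has the closed form  t_ik = pq C_ik - p R_i - q S_k + T_sum  with
R_i = sum_l C_il, S_k = sum_j C_jk, T_sum = sum C — an O(pq) computation
verified against the quadruple sum in the test suite.  The base estimator is

    rho_ik = t_ik / ((p-1)(q-1) alpha_i beta_k),

with alpha, beta the SparCC basis variances of each dataset estimated
independently.  The iterative variant restricts the reference pairs to
features currently deemed near-uncorrelated on average (sets S_n, T_n) to
remove the residual bias when sparsity is imperfect; the restricted double
sum is still computed via restricted marginal sums, never a quadruple loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .sparcc import BasisVariances, basis_variances_from_counts, log_cov_matrix
from .transforms import _as_matrix

__all__ = [
    "CrossLogCovariance",
    "CaseCResult",
    "SparXCC",
    "cross_log_covariance",
    "t_matrix",
    "sparxcc_base",
    "sparxcc_iterative",
    "select_thresholds_case_c",
    "permutation_threshold_m_case_c",
    "base_vs_iterative_diagnostic",
]


@dataclass
class CrossLogCovariance:
    """Cross-covariances of log pseudo-counted columns, with marginal sums."""

    C: np.ndarray
    row_sums: np.ndarray
    col_sums: np.ndarray
    grand_sum: float

    @property
    def shape(self):
        return self.C.shape


@dataclass
class CaseCResult:
    """Output of a SparXCC fit (see :class:`CaseBResult` for conventions)."""

    rho: np.ndarray
    method: str
    alpha: BasisVariances
    beta: BasisVariances
    set_S: np.ndarray
    set_T: np.ndarray
    n_iterations: int = 0
    thresholds: tuple | None = None
    raw_rho: np.ndarray = field(default=None)  # type: ignore[assignment]
    clipped_to_unit: np.ndarray = field(default=None)  # type: ignore[assignment]
    converged: bool = True

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        if self.raw_rho is None:
            self.raw_rho = self.rho.copy()
        if self.clipped_to_unit is None:
            self.clipped_to_unit = np.abs(self.raw_rho) > 1.0


def cross_log_covariance(table_x, table_y, pseudo_count: float = 1.0) -> CrossLogCovariance:
    """Empirical Cov[log(x_i+pc), log(y_k+pc)] for all feature pairs."""
    xv, _, _ = _as_matrix(table_x)
    yv, _, _ = _as_matrix(table_y)
    if xv.shape[0] != yv.shape[0]:
        raise ValueError(
            f"replicate mismatch: X has {xv.shape[0]} rows, Y has {yv.shape[0]}"
        )
    n = xv.shape[0]
    if n < 3:
        raise ValueError("need at least 3 replicates")
    if (xv < 0).any() or (yv < 0).any():
        raise ValueError("count tables contain negative entries")
    lx = np.log(xv + pseudo_count)
    ly = np.log(yv + pseudo_count)
    lxc = lx - lx.mean(axis=0)
    lyc = ly - ly.mean(axis=0)
    # evaluate the matrix product in a canonical orientation: blocked BLAS
    # kernels are not bitwise transpose-symmetric, and downstream identities
    # promise sparxcc_base(Y, X) == sparxcc_base(X, Y).T exactly
    p_, q_ = lxc.shape[1], lyc.shape[1]
    if p_ > q_ or (p_ == q_ and lxc.tobytes() > lyc.tobytes()):
        C = (lyc.T @ lxc).T / (n - 1)
    else:
        C = lxc.T @ lyc / (n - 1)
    # marginal sums computed in replicate space (R_i = Cov[log x_i, sum_l
    # log y_l] etc.) so that every quantity is computed identically when the
    # two datasets are swapped, keeping sparxcc_base(Y, X) a bitwise
    # transpose of sparxcc_base(X, Y)
    sx = lxc.sum(axis=1)
    sy = lyc.sum(axis=1)
    return CrossLogCovariance(
        C=C,
        row_sums=lxc.T @ sy / (n - 1),
        col_sums=lyc.T @ sx / (n - 1),
        grand_sum=float(sx @ sy / (n - 1)),
    )


def t_matrix(cov: CrossLogCovariance) -> np.ndarray:
    """Closed-form t_ik = pq C_ik - p R_i - q S_k + T_sum."""
    p, q = cov.C.shape
    if p < 2 or q < 2:
        raise ValueError("t_matrix needs p >= 2 and q >= 2")
    # grouped so the expression is symmetric in the two datasets: swapping
    # them transposes the result bitwise (float addition is commutative)
    return ((p * q * cov.C + cov.grand_sum)
            - (p * cov.row_sums[:, None] + q * cov.col_sums[None, :]))


class _CollapsedSet(RuntimeError):
    """A restricted reference set left some feature without references."""


def _clip_unit(raw):
    clipped = np.abs(raw) > 1.0
    return np.clip(raw, -1.0, 1.0), clipped


def _prepare(table_x, table_y, pseudo_count):
    xv, _, _ = _as_matrix(table_x)
    yv, _, _ = _as_matrix(table_y)
    p, q = xv.shape[1], yv.shape[1]
    if p < 3 or q < 3:
        raise ValueError("SparXCC needs at least 3 features in each dataset")
    cov = cross_log_covariance(xv, yv, pseudo_count)
    alpha = basis_variances_from_counts(xv, pseudo_count)
    beta = basis_variances_from_counts(yv, pseudo_count)
    return xv, yv, cov, alpha, beta


def sparxcc_base(table_x, table_y, pseudo_count: float = 1.0) -> CaseCResult:
    """Base SparXCC estimator: rho_ik = t_ik / ((p-1)(q-1) alpha_i beta_k)."""
    xv, yv, cov, alpha, beta = _prepare(table_x, table_y, pseudo_count)
    p, q = cov.shape
    raw = t_matrix(cov) / ((p - 1) * (q - 1) * np.outer(alpha.std, beta.std))
    rho, clipped = _clip_unit(raw)
    return CaseCResult(
        rho=rho, raw_rho=raw, clipped_to_unit=clipped, method="base",
        alpha=alpha, beta=beta, set_S=np.arange(p), set_T=np.arange(q),
    )


def _restricted_estimate(cov, mask_s, mask_t, alpha_std, beta_std):
    """One iteration of the restricted estimator, O(pq) via marginal sums.

    For each (i, k):  sum_{j in S\\{i}} sum_{l in T\\{k}} of
    (C_ik - C_il - C_jk + C_jl), normalised by |S\\{i}| |T\\{k}| alpha_i beta_k.
    """
    C = cov.C
    p, q = C.shape
    if mask_s.all() and mask_t.all():
        # full reference sets: evaluate via the base closed form so that
        # t1 = t2 = inf reproduces sparxcc_base bit for bit
        return t_matrix(cov) / ((p - 1) * (q - 1) * np.outer(alpha_std, beta_std))
    ns, nt = int(mask_s.sum()), int(mask_t.sum())
    cnt_s = ns - mask_s.astype(int)       # |S \ {i}| per row i
    cnt_t = nt - mask_t.astype(int)       # |T \ {k}| per column k
    if (cnt_s == 0).any() or (cnt_t == 0).any():
        raise _CollapsedSet(
            "restricted reference set collapsed (|S_n \\ {i}| or |T_n \\ {k}| "
            "is zero); increase the thresholds t1/t2"
        )
    row_T = C[:, mask_t].sum(axis=1)      # sum_{l in T} C_il, per i
    col_S = C[mask_s, :].sum(axis=0)      # sum_{j in S} C_jk, per k
    grand_ST = float(C[np.ix_(mask_s, mask_t)].sum())

    in_s = mask_s.astype(float)
    in_t = mask_t.astype(float)
    # sums with self-indices removed
    row_T_excl = row_T[:, None] - in_t[None, :] * C           # sum_{l in T\{k}} C_il
    col_S_excl = col_S[None, :] - in_s[:, None] * C           # sum_{j in S\{i}} C_jk
    grand_excl = (grand_ST
                  - in_s[:, None] * row_T[:, None]
                  - in_t[None, :] * col_S[None, :]
                  + np.outer(in_s, in_t) * C)                 # sum over S\{i} x T\{k}

    cs = cnt_s[:, None].astype(float)
    ct = cnt_t[None, :].astype(float)
    total = cs * ct * C - cs * row_T_excl - ct * col_S_excl + grand_excl
    return total / (cs * ct * np.outer(alpha_std, beta_std))


def sparxcc_iterative(table_x, table_y, pseudo_count: float = 1.0,
                      t1: float = np.inf, t2: float = np.inf,
                      max_iter: int = 20) -> CaseCResult:
    """Iterative SparXCC with reference sets

        S_n = {i : (1/q) sum_l |rho_il^(n-1)| < t1},
        T_n = {k : (1/p) sum_j |rho_jk^(n-1)| < t2},

    iterated until both sets stabilise.  With t1 = t2 = inf this reduces
    exactly to :func:`sparxcc_base`.
    """
    if not (t1 > 0 and t2 > 0):
        raise ValueError("thresholds t1, t2 must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    xv, yv, cov, alpha, beta = _prepare(table_x, table_y, pseudo_count)
    p, q = cov.shape

    mask_s = np.ones(p, dtype=bool)
    mask_t = np.ones(q, dtype=bool)
    raw = _restricted_estimate(cov, mask_s, mask_t, alpha.std, beta.std)
    seen = {(mask_s.tobytes(), mask_t.tobytes())}
    n_iter = 0
    converged = True
    for _ in range(max_iter):
        rho_abs = np.abs(np.clip(raw, -1.0, 1.0))
        new_s = rho_abs.mean(axis=1) < t1
        new_t = rho_abs.mean(axis=0) < t2
        key = (new_s.tobytes(), new_t.tobytes())
        if key == (mask_s.tobytes(), mask_t.tobytes()):
            break
        try:
            new_raw = _restricted_estimate(cov, new_s, new_t, alpha.std, beta.std)
        except _CollapsedSet:
            # no (or almost no) features fall under the thresholds: the
            # procedure cannot restrict further and returns the current
            # iterate (the base estimates when this happens at n=1)
            warnings.warn(
                "iterative SparXCC found too few features with average "
                "absolute correlation under the thresholds; returning the "
                "previous iterate (consider larger t1/t2, e.g. the "
                "max-percentile permutation threshold)",
                RuntimeWarning, stacklevel=2,
            )
            break
        if key in seen:
            warnings.warn(
                "iterative SparXCC did not converge: reference sets oscillate; "
                "returning the last iterate",
                RuntimeWarning, stacklevel=2,
            )
            converged = False
            mask_s, mask_t = new_s, new_t
            raw = new_raw
            n_iter += 1
            break
        seen.add(key)
        mask_s, mask_t = new_s, new_t
        raw = new_raw
        n_iter += 1
    else:
        warnings.warn(
            f"iterative SparXCC did not converge within max_iter={max_iter}; "
            "returning the last iterate",
            RuntimeWarning, stacklevel=2,
        )
        converged = False

    rho, clipped = _clip_unit(raw)
    return CaseCResult(
        rho=rho, raw_rho=raw, clipped_to_unit=clipped, method="iterative",
        alpha=alpha, beta=beta,
        set_S=np.flatnonzero(mask_s), set_T=np.flatnonzero(mask_t),
        n_iterations=n_iter, thresholds=(float(t1), float(t2)),
        converged=converged,
    )


def _permute_rows(rng, arr):
    return arr[rng.permutation(arr.shape[0])]


def select_thresholds_case_c(table_x, table_y, pseudo_count: float = 1.0,
                             n_perm: int = 100, percentile: float = 80.0,
                             seed=None):
    """Permutation-based choice of (t1, t2).

    Each dataset's replicate rows are permuted independently, breaking all
    cross-correlation while preserving the within-dataset structure.  The
    per-OTU mean absolute estimates (1/q) sum_l |rho_il| are pooled over
    permutations for t1, the per-gene means for t2; the requested
    percentile of each pool is returned.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    rng = np.random.default_rng(seed)
    xv, _, _ = _as_matrix(table_x)
    yv, _, _ = _as_matrix(table_y)
    pool_otu, pool_gene = [], []
    for _ in range(n_perm):
        res = sparxcc_base(_permute_rows(rng, xv), _permute_rows(rng, yv),
                           pseudo_count)
        rho_abs = np.abs(res.rho)
        pool_otu.append(rho_abs.mean(axis=1))
        pool_gene.append(rho_abs.mean(axis=0))
    pool_otu = np.concatenate(pool_otu)
    pool_gene = np.concatenate(pool_gene)
    if percentile == 100:
        return float(pool_otu.max()), float(pool_gene.max())
    return (float(np.percentile(pool_otu, percentile)),
            float(np.percentile(pool_gene, percentile)))


def permutation_threshold_m_case_c(table_x, table_y, pseudo_count: float = 1.0,
                                   n_perm: int = 100, seed=None):
    """Detection threshold m = max |rho^Perm| over permutations and pairs.

    Returns ``(m, detected)`` with ``detected`` the p x q mask
    |rho_ik| > m for the unpermuted base estimates.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    xv, _, _ = _as_matrix(table_x)
    yv, _, _ = _as_matrix(table_y)
    m = 0.0
    for _ in range(n_perm):
        res = sparxcc_base(_permute_rows(rng, xv), _permute_rows(rng, yv),
                           pseudo_count)
        m = max(m, float(np.abs(res.rho).max()))
    observed = sparxcc_base(xv, yv, pseudo_count).rho
    return m, np.abs(observed) > m


def base_vs_iterative_diagnostic(base_rho, iter_rho):
    """Least-squares line through (base, iterative) estimate pairs.

    A line with slope ~1 and intercept away from 0 indicates a constant
    compositional bias that the iterative procedure removed; an intercept
    near 0 means the base estimates were already unbiased, and a poor fit
    means the iteration is unreliable (e.g. threshold too low).

    Returns
    -------
    (slope, intercept, max_abs_residual)
    """
    x = np.asarray(getattr(base_rho, "rho", base_rho), dtype=float).ravel()
    y = np.asarray(getattr(iter_rho, "rho", iter_rho), dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("base and iterative estimates differ in shape")
    if x.size < 3:
        raise ValueError("need at least 3 estimate pairs")
    if np.ptp(x) == 0:
        slope, intercept = 0.0, float(y.mean())
    else:
        slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(slope), float(intercept), float(np.abs(resid).max())


class SparXCC(BaseEstimator):
    """Sparse cross-correlations between two compositional count datasets.

    sklearn-style estimator; ``fit(X, Y)`` takes two raw count tables
    sharing replicate rows and estimates the p x q matrix of correlations
    between the latent log absolute abundances, stored in ``rho_``.

    Parameters mirror :class:`compocross.sparcev.SparCEV`, with a pair of
    thresholds (t1 for OTUs, t2 for the second dataset) selected jointly by
    permutation when ``thresholds="auto"``.

    Attributes
    ----------
    rho_ : ndarray (p, q)
    raw_rho_, clipped_ : as in SparCEV
    alpha2_, beta2_ : basis variances of each dataset
    set_S_, set_T_ : final reference sets
    thresholds_ : (t1, t2)
    n_iter_, converged_
    """

    def __init__(self, method: str = "iterative", thresholds="auto",
                 percentile: float = 80.0, n_perm: int = 100,
                 pseudo_count: float = 1.0, max_iter: int = 20,
                 random_state=None):
        self.method = method
        self.thresholds = thresholds
        self.percentile = percentile
        self.n_perm = n_perm
        self.pseudo_count = pseudo_count
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, Y):
        if self.method not in ("base", "iterative"):
            raise ValueError(f"method must be 'base' or 'iterative', got {self.method!r}")
        xv, x_cols, _ = _as_matrix(X)
        yv, y_cols, _ = _as_matrix(Y)
        if x_cols is not None:
            self.feature_names_x_ = np.asarray(x_cols, dtype=object)
        if y_cols is not None:
            self.feature_names_y_ = np.asarray(y_cols, dtype=object)
        self.n_features_in_ = xv.shape[1]

        if self.method == "base":
            res = sparxcc_base(xv, yv, self.pseudo_count)
            self.thresholds_ = (np.inf, np.inf)
        else:
            if self.thresholds == "auto":
                t1, t2 = select_thresholds_case_c(
                    xv, yv, self.pseudo_count, n_perm=self.n_perm,
                    percentile=self.percentile, seed=self.random_state,
                )
            else:
                t1, t2 = (float(v) for v in self.thresholds)
            res = sparxcc_iterative(xv, yv, self.pseudo_count, t1=t1, t2=t2,
                                    max_iter=self.max_iter)
            self.thresholds_ = (t1, t2)

        self.result_ = res
        self.rho_ = res.rho
        self.raw_rho_ = res.raw_rho
        self.clipped_ = res.clipped_to_unit
        self.alpha2_ = res.alpha.values
        self.beta2_ = res.beta.values
        self.set_S_ = res.set_S
        self.set_T_ = res.set_T
        self.n_iter_ = res.n_iterations
        self.converged_ = res.converged
        return self

    def detect(self, X, Y, n_perm=None, seed=None):
        """Permutation-threshold detection: returns (m, p x q mask)."""
        xv, _, _ = _as_matrix(X)
        yv, _, _ = _as_matrix(Y)
        return permutation_threshold_m_case_c(
            xv, yv, self.pseudo_count,
            n_perm=self.n_perm if n_perm is None else n_perm,
            seed=self.random_state if seed is None else seed,
        )
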