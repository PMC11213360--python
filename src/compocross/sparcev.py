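"""SparCEV: sparse correlations between OTU abundances and an external variable.

Case B of compositional cross-correlation: one compositional count dataset
(reads x, latent absolute abundances a) and one non-compositional phenotype
b observed per replicate.  The target is Corr[log a_i, b], which cannot be
read off the counts because the library size is arbitrary.  Log-ratios are
library-size invariant, and under the sparsity assumption that feature-wise
covariances average out,

    Corr[log a_i, b]  ~=  (1 / (sigma_b alpha_i)) * (1/(p-1)) *
                          sum_{j != i} Cov[log(x_i / x_j), b],

with alpha_i^2 = Var[log a_i] estimated by the SparCC linear system
(:mod:`compocross.sparcc`) and sigma_b^2 = Var[b] estimated directly.  By
bilinearity each Cov[log(x_i/x_j), b] = v_i - v_j with
v_i = Cov[log(x_i + pc), b], so the double sum collapses to
(p/(p-1)) (v_i - mean(v)).

When some features genuinely correlate with b the sparsity assumption is
violated and the base estimator is biased by -mean_j Cov[log a_j, b].  The
iterative variant re-estimates with the reference set restricted to features
currently deemed near-uncorrelated (|rho| < t), iterating until the set
stabilises.  The threshold t is chosen from permutations of b (default: the
80th percentile of the pooled null estimates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .sparcc import BasisVariances, basis_variances_from_counts
from .transforms import _as_matrix, apply_pseudo_count

__all__ = [
    "CaseBResult",
    "SparCEV",
    "phenotype_covariances",
    "sparcev_base",
    "sparcev_iterative",
    "select_threshold_case_b",
    "permutation_threshold_m",
    "bca_bootstrap_ci",
]


@dataclass
class CaseBResult:
    """Output of a SparCEV fit.

    ``rho`` is clipped to [-1, 1] (flags in ``clipped_to_unit``); ``raw_rho``
    keeps the unclipped values for the base-vs-iterative diagnostic.
    ``included_set`` is the final reference set R_n of the iteration (all
    features for the base method).
    """

    rho: np.ndarray
    method: str
    alpha: BasisVariances
    included_set: np.ndarray
    n_iterations: int = 0
    threshold_t: float | None = None
    raw_rho: np.ndarray = field(default=None)  # type: ignore[assignment]
    clipped_to_unit: np.ndarray = field(default=None)  # type: ignore[assignment]
    converged: bool = True

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        if self.raw_rho is None:
            self.raw_rho = self.rho.copy()
        if self.clipped_to_unit is None:
            self.clipped_to_unit = np.abs(self.raw_rho) > 1.0


def _validate_b(b, n):
    b = np.asarray(b, dtype=float).ravel()
    if b.shape[0] != n:
        raise ValueError(f"phenotype length {b.shape[0]} != replicate count {n}")
    if not np.all(np.isfinite(b)):
        raise ValueError("phenotype contains non-finite values")
    if np.ptp(b) == 0:
        raise ValueError("phenotype is constant (Var[b] = 0)")
    return b


def phenotype_covariances(table, b, pseudo_count: float = 1.0) -> np.ndarray:
    """v_i = Cov[log(x_i + pc), b] for every feature.

    The log-ratio covariances Cov[log(x_i/x_j), b] = v_i - v_j follow by
    bilinearity; only the p marginal covariances are ever computed.
    """
    vals, _, _ = _as_matrix(apply_pseudo_count(table, pseudo_count))
    n = vals.shape[0]
    b = _validate_b(b, n)
    logged = np.log(vals)
    bc = b - b.mean()
    return (logged - logged.mean(axis=0)).T @ bc / (n - 1)


def _clip_unit(raw):
    clipped = np.abs(raw) > 1.0
    return np.clip(raw, -1.0, 1.0), clipped


def sparcev_base(table, b, pseudo_count: float = 1.0) -> CaseBResult:
    """Base SparCEV estimator of Corr[log a_i, b] for all p features."""
    vals, _, _ = _as_matrix(table)
    n, p = vals.shape
    if p < 3:
        raise ValueError("SparCEV needs at least 3 features")
    b = _validate_b(b, n)
    v = phenotype_covariances(table, b, pseudo_count)
    alpha = basis_variances_from_counts(table, pseudo_count)
    sigma_b = np.std(b, ddof=1)
    raw = (p / (p - 1)) * (v - v.mean()) / (sigma_b * alpha.std)
    rho, clipped = _clip_unit(raw)
    return CaseBResult(
        rho=rho, raw_rho=raw, clipped_to_unit=clipped, method="base",
        alpha=alpha, included_set=np.arange(p), n_iterations=0,
    )


def sparcev_iterative(table, b, pseudo_count: float = 1.0, t: float = np.inf,
                      max_iter: int = 20) -> CaseBResult:
    """Iterative SparCEV with reference set R_n = {i : |rho_i^(n-1)| < t}.

    Each iteration re-estimates every feature's correlation against the
    mean of v over R_n excluding the feature itself; iteration stops when
    R_n stabilises (or a previously seen set recurs, reported as
    non-convergence).  With t = inf this reduces exactly to the base
    estimator.
    """
    if not t > 0:
        raise ValueError("threshold t must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    vals, _, _ = _as_matrix(table)
    n, p = vals.shape
    if p < 3:
        raise ValueError("SparCEV needs at least 3 features")
    b = _validate_b(b, n)

    v = phenotype_covariances(table, b, pseudo_count)
    alpha = basis_variances_from_counts(table, pseudo_count)
    denom = np.std(b, ddof=1) * alpha.std
    idx = np.arange(p)

    class _Collapsed(RuntimeError):
        pass

    def estimate(mask):
        m = int(mask.sum())
        if m == p:
            # full reference set: evaluate via the base formula itself so
            # that t = inf reproduces sparcev_base bit for bit
            return (p / (p - 1)) * (v - v.mean()) / denom
        counts = m - mask.astype(int)  # |R_n \ {i}| per feature
        if (counts == 0).any():
            raise _Collapsed
        sum_r = v[mask].sum()
        mean_rest = (sum_r - np.where(mask, v, 0.0)) / counts
        return (v - mean_rest) / denom

    mask = np.ones(p, dtype=bool)
    raw = estimate(mask)  # iteration with R_0 = all features == base
    seen = {mask.tobytes()}
    n_iter = 0
    converged = True
    for _ in range(max_iter):
        new_mask = np.abs(np.clip(raw, -1.0, 1.0)) < t
        if new_mask.tobytes() == mask.tobytes():
            break
        try:
            new_raw = estimate(new_mask)
        except _Collapsed:
            # no features fall under the threshold: nothing to restrict to;
            # keep the current iterate (the base estimates at n=1)
            warnings.warn(
                "iterative SparCEV found no features with absolute "
                "correlation under the threshold; returning the previous "
                "iterate (consider a larger t, e.g. the max-percentile "
                "permutation threshold)",
                RuntimeWarning, stacklevel=2,
            )
            break
        if new_mask.tobytes() in seen:
            warnings.warn(
                "iterative SparCEV did not converge: reference set oscillates; "
                "returning the last iterate",
                RuntimeWarning, stacklevel=2,
            )
            converged = False
            mask = new_mask
            raw = new_raw
            n_iter += 1
            break
        seen.add(new_mask.tobytes())
        mask = new_mask
        raw = new_raw
        n_iter += 1
    else:
        warnings.warn(
            f"iterative SparCEV did not converge within max_iter={max_iter}; "
            "returning the last iterate",
            RuntimeWarning, stacklevel=2,
        )
        converged = False

    rho, clipped = _clip_unit(raw)
    return CaseBResult(
        rho=rho, raw_rho=raw, clipped_to_unit=clipped, method="iterative",
        alpha=alpha, included_set=idx[mask], n_iterations=n_iter,
        threshold_t=float(t), converged=converged,
    )


def select_threshold_case_b(table, b, pseudo_count: float = 1.0,
                            n_perm: int = 100, percentile: float = 80.0,
                            seed=None) -> float:
    """Permutation-based choice of the iteration threshold t.

    Permuting b breaks its correlation with every feature; the base
    estimates on permuted data are therefore draws from the null.  All
    |rho| over ``n_perm`` permutations are pooled and the requested
    percentile (default 80, per the method's recommendation) returned.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    rng = np.random.default_rng(seed)
    b = np.asarray(b, dtype=float).ravel()
    pooled = []
    for _ in range(n_perm):
        perm = rng.permutation(b)
        pooled.append(np.abs(sparcev_base(table, perm, pseudo_count).rho))
    pooled = np.concatenate(pooled)
    if percentile == 100:
        return float(pooled.max())
    return float(np.percentile(pooled, percentile))


def permutation_threshold_m(table, b, pseudo_count: float = 1.0,
                            n_perm: int = 100, seed=None):
    """Detection threshold m = max over permutations and features of |rho^Perm|.

    Returns ``(m, detected)`` where ``detected`` flags features of the
    *unpermuted* fit with |rho_i| > m — the candidates for genuinely
    correlated features.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    b = np.asarray(b, dtype=float).ravel()
    m = 0.0
    for _ in range(n_perm):
        perm = rng.permutation(b)
        m = max(m, float(np.abs(sparcev_base(table, perm, pseudo_count).rho).max()))
    observed = sparcev_base(table, b, pseudo_count).rho
    return m, np.abs(observed) > m


def _bca_interval(boot, theta_hat, jack, level):
    """Vectorised BCa interval: boot (B, p), theta_hat (p,), jack (n, p)."""
    B, p = boot.shape
    alpha = (1.0 - level) / 2.0
    z_lo, z_hi = stats.norm.ppf(alpha), stats.norm.ppf(1.0 - alpha)

    prop = (boot < theta_hat).mean(axis=0)
    degenerate = (boot.std(axis=0) == 0) | (prop == 0) | (prop == 1)
    prop = np.clip(prop, 1.0 / (2 * B), 1.0 - 1.0 / (2 * B))
    z0 = stats.norm.ppf(prop)

    jm = jack.mean(axis=0)
    d = jm - jack
    denom = 6.0 * (d ** 2).sum(axis=0) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(denom > 0, (d ** 3).sum(axis=0) / denom, 0.0)

    def adj(z):
        return stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))

    lo_q, hi_q = adj(z_lo), adj(z_hi)
    lower = np.empty(p)
    upper = np.empty(p)
    for i in range(p):
        lower[i] = np.quantile(boot[:, i], lo_q[i])
        upper[i] = np.quantile(boot[:, i], hi_q[i])
    lower[degenerate] = theta_hat[degenerate]
    upper[degenerate] = theta_hat[degenerate]
    return lower, upper, degenerate


def bca_bootstrap_ci(table, b, pseudo_count: float = 1.0, n_boot: int = 1000,
                     level: float = 0.95, seed=None):
    """BCa bootstrap confidence intervals for the base SparCEV estimates.

    Replicates (rows) are resampled with replacement; the bias-correction
    comes from the bootstrap distribution and the acceleration from a
    jackknife over replicates.  Intervals are truncated to [-1, 1], the
    range of a correlation.

    Returns
    -------
    (lower, upper) : each ndarray of shape (p,)
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for stable BCa corrections")
    vals, _, _ = _as_matrix(table)
    n = vals.shape[0]
    b = _validate_b(b, n)
    rng = np.random.default_rng(seed)

    theta_hat = sparcev_base(table, b, pseudo_count).rho
    boot = np.empty((n_boot, theta_hat.shape[0]))
    for r in range(n_boot):
        idx = rng.integers(0, n, size=n)
        while np.ptp(b[idx]) == 0:  # resample hit a constant phenotype
            idx = rng.integers(0, n, size=n)
        boot[r] = sparcev_base(vals[idx], b[idx], pseudo_count).rho
    jack = np.empty((n, theta_hat.shape[0]))
    for r in range(n):
        keep = np.delete(np.arange(n), r)
        jack[r] = sparcev_base(vals[keep], b[keep], pseudo_count).rho

    lower, upper, degenerate = _bca_interval(boot, theta_hat, jack, level)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) had a degenerate bootstrap "
            "distribution; their intervals collapse to the point estimate",
            RuntimeWarning, stacklevel=2,
        )
    return np.clip(lower, -1.0, 1.0), np.clip(upper, -1.0, 1.0)


class SparCEV(BaseEstimator):
    """Sparse correlations between a compositional dataset and a phenotype.

    sklearn-style estimator wrapping the base and iterative SparCEV
    procedures.  ``fit(X, y)`` takes the raw count table X (replicates in
    rows, OTUs in columns) and the phenotype vector y; the estimated
    correlations Corr[log a_i, y] land in ``rho_``.

    Parameters
    ----------
    method : {"iterative", "base"}, default "iterative"
        The iterative variant corrects the compositional bias when some
        features genuinely correlate with the phenotype; prefer "base"
        only for very small p.
    threshold : "auto", float or np.inf
        Iteration threshold t.  "auto" selects it by permutation
        (``select_threshold_case_b``) at ``percentile``.
    percentile : float, default 80
        Percentile of the pooled permutation null used when
        ``threshold="auto"``.
    n_perm : int, default 100
        Permutations for threshold selection.
    pseudo_count : float, default 1.0
    max_iter : int, default 20
    random_state : int or None
        Seeds the permutation scheme; fits are then fully reproducible.

    Attributes
    ----------
    rho_ : ndarray (p,) — estimates clipped to [-1, 1]
    raw_rho_ : ndarray (p,) — unclipped estimates
    clipped_ : boolean ndarray (p,)
    alpha2_ : ndarray (p,) — SparCC basis variances Var[log a_i]
    included_ : ndarray — final reference set R_n
    threshold_ : float — threshold actually used (inf for base)
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, method: str = "iterative", threshold="auto",
                 percentile: float = 80.0, n_perm: int = 100,
                 pseudo_count: float = 1.0, max_iter: int = 20,
                 random_state=None):
        self.method = method
        self.threshold = threshold
        self.percentile = percentile
        self.n_perm = n_perm
        self.pseudo_count = pseudo_count
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        if self.method not in ("base", "iterative"):
            raise ValueError(f"method must be 'base' or 'iterative', got {self.method!r}")
        vals, cols, _ = _as_matrix(X)
        if cols is not None:
            self.feature_names_in_ = np.asarray(cols, dtype=object)
        self.n_features_in_ = vals.shape[1]

        if self.method == "base":
            res = sparcev_base(vals, y, self.pseudo_count)
            self.threshold_ = np.inf
        else:
            if self.threshold == "auto":
                t = select_threshold_case_b(
                    vals, y, self.pseudo_count, n_perm=self.n_perm,
                    percentile=self.percentile, seed=self.random_state,
                )
            else:
                t = float(self.threshold)
            res = sparcev_iterative(vals, y, self.pseudo_count, t=t,
                                    max_iter=self.max_iter)
            self.threshold_ = t

        self.result_ = res
        self.rho_ = res.rho
        self.raw_rho_ = res.raw_rho
        self.clipped_ = res.clipped_to_unit
        self.alpha2_ = res.alpha.values
        self.included_ = res.included_set
        self.n_iter_ = res.n_iterations
        self.converged_ = res.converged
        return self

    def detect(self, X, y, n_perm=None, seed=None):
        """Permutation-threshold detection: returns (m, boolean mask)."""
        vals, _, _ = _as_matrix(X)
        return permutation_threshold_m(
            vals, y, self.pseudo_count,
            n_perm=self.n_perm if n_perm is None else n_perm,
            seed=self.random_state if seed is None else seed,
        )
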