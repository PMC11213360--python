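"""SparCC-style basis variance estimation.

The latent absolute abundance a_i of a feature is never observed; only read
counts x_i of the relative abundance are.  Log-ratios log(x_i/x_j) are,
however, invariant to the library size, and their variances satisfy

    Var[log(x_i/x_j)] = Var[log a_i] + Var[log a_j] - 2 Cov[log a_i, log a_j].

Under the sparsity assumption that average covariances across features are
negligible, the cross term drops and the p(p-1)/2 observed log-ratio
variances become an (over-determined but exactly solvable) linear system in
the p unknown *basis variances* omega_i = Var[log a_i]:

    sum_{j != i} T_ij = (p - 2) * omega_i + sum_j omega_j,

i.e. ((p-2) I + J) omega = t with J the all-ones matrix.  The closed form

    omega_i = (t_i - sum(t) / (2p - 2)) / (p - 2)

is used here (O(p^2) given T); a generic dense solve serves as the oracle in
the test suite.  This is the single shared ingredient of both SparCEV and
SparXCC.  The estimation is single-pass: no iterative exclusion of strongly
correlated pairs is performed (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .transforms import _as_matrix, apply_pseudo_count

__all__ = [
    "BasisVariances",
    "log_ratio_variance_matrix",
    "basis_variances",
    "basis_variances_from_counts",
]

#: negative solved variances are a known pathology of the SparCC system;
#: values below this floor are clipped and flagged.
VARIANCE_FLOOR = 1e-8


@dataclass
class BasisVariances:
    """Estimated Var[log a_i] per feature, with clip flags."""

    values: np.ndarray
    clipped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.clipped is None:
            self.clipped = np.zeros(self.values.shape, dtype=bool)
        self.clipped = np.asarray(self.clipped, dtype=bool)

    @property
    def std(self) -> np.ndarray:
        """alpha_i = sqrt(Var[log a_i])."""
        return np.sqrt(self.values)


def log_cov_matrix(table, pseudo_count: float = 1.0) -> np.ndarray:
    """Covariance matrix (ddof=1) of log pseudo-counted columns."""
    vals, _, _ = _as_matrix(apply_pseudo_count(table, pseudo_count))
    logged = np.log(vals)
    return np.cov(logged, rowvar=False, ddof=1)


def log_ratio_variance_matrix(table, pseudo_count: float = 1.0) -> np.ndarray:
    """Empirical variance of log((x_i+pc)/(x_j+pc)) for every feature pair.

    Computed via Var[log x_i] + Var[log x_j] - 2 Cov[log x_i, log x_j]
    rather than forming each of the p(p-1)/2 log-ratio vectors explicitly.

    Returns
    -------
    ndarray, shape (p, p)
        Symmetric, zero diagonal, non-negative.
    """
    vals, _, _ = _as_matrix(table)
    n, p = vals.shape
    if p < 3:
        raise ValueError("need at least 3 features (the SparCC system is singular below p=3)")
    if n < 3:
        raise ValueError("need at least 3 replicates")
    S = log_cov_matrix(table, pseudo_count)
    d = np.diag(S)
    T = d[:, None] + d[None, :] - 2.0 * S
    np.fill_diagonal(T, 0.0)
    # exact proportionality between columns gives tiny negative float noise
    np.clip(T, 0.0, None, out=T)
    return T


def basis_variances(T: np.ndarray, floor: float = VARIANCE_FLOOR) -> BasisVariances:
    """Solve the SparCC linear system for the basis variances.

    Parameters
    ----------
    T : ndarray, shape (p, p)
        Log-ratio variance matrix (symmetric, zero diagonal).
    floor : float
        Positive floor; solved variances below it are clipped and flagged.

    Returns
    -------
    BasisVariances
    """
    T = np.asarray(T, dtype=float)
    p = T.shape[0]
    if T.shape != (p, p):
        raise ValueError("T must be square")
    if p < 3:
        raise ValueError("basis variance system needs p >= 3")
    t = T.sum(axis=1)  # zero diagonal -> sum over j != i
    omega = (t - t.sum() / (2 * p - 2)) / (p - 2)
    clipped = omega < floor
    if clipped.any():
        warnings.warn(
            f"{int(clipped.sum())} basis variance(s) fell below the floor "
            f"{floor:g} and were clipped (SparCC system pathology)",
            RuntimeWarning,
            stacklevel=2,
        )
        omega = np.where(clipped, floor, omega)
    return BasisVariances(values=omega, clipped=clipped)


def basis_variances_from_counts(table, pseudo_count: float = 1.0,
                                floor: float = VARIANCE_FLOOR) -> BasisVariances:
    """Convenience: counts -> log-ratio variances -> basis variances."""
    return basis_variances(log_ratio_variance_matrix(table, pseudo_count), floor=floor)
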