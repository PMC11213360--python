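"""Baseline transformations of count tables and Pearson cross-correlation.

Sequencing counts carry only relative information: the library size (row sum)
is a technical artifact of sequencing depth, not a biological quantity.  The
three transformations here are the standard competitors for correlation
estimation on such data:

``log``
    Natural log of the (pseudo-counted) read counts.  Ignores the
    compositional structure entirely; library-size variation leaks into
    every variance and covariance.
``log-TSS``
    Log of relative abundances (total-sum scaling).  Removes the library
    size but not the constraint that relative abundances sum to one.
``CLR``
    Centred log-ratio: log counts centred by the per-replicate mean log
    count.  The workhorse transformation of compositional data analysis.

All logs are natural.  Correlations are invariant to the log base; variances
are not, and the SparCC-style machinery in :mod:`compocross.sparcc` assumes
natural logs throughout.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "apply_pseudo_count",
    "log_transform",
    "log_tss_transform",
    "clr_transform",
    "pearson_cross_correlation",
    "CompositionalLogTransform",
]

_TRANSFORMS = ("log", "log-tss", "clr")


def _as_matrix(table):
    """Return (values ndarray, columns or None, index or None)."""
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), table.columns, table.index
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-d table, got shape {arr.shape}")
    return arr, None, None


def _wrap_like(values, columns, index):
    if columns is not None:
        return pd.DataFrame(values, columns=columns, index=index)
    return values


def apply_pseudo_count(table, value: float = 1.0):
    """Add a positive constant to every read count.

    Zeros are ubiquitous in sequencing count tables and the log is undefined
    at zero, so a pseudo-count (default 1) is added before any
    log-transformation.

    Parameters
    ----------
    table : array-like or DataFrame, shape (n_replicates, n_features)
    value : float
        Positive constant to add.
    """
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"pseudo-count must be a positive real, got {value}")
    vals, cols, idx = _as_matrix(table)
    if (vals < 0).any():
        raise ValueError("count table contains negative entries")
    return _wrap_like(vals + value, cols, idx)


def log_transform(table):
    """Elementwise natural log of a strictly positive table."""
    vals, cols, idx = _as_matrix(table)
    if (vals <= 0).any():
        raise ValueError(
            "log transform requires strictly positive entries; "
            "apply a pseudo-count first"
        )
    return _wrap_like(np.log(vals), cols, idx)


def log_tss_transform(table):
    """Log of relative abundances: ``log(x_ij / sum_k x_ik)`` per row."""
    vals, cols, idx = _as_matrix(table)
    if (vals <= 0).any():
        raise ValueError("log-TSS requires strictly positive entries")
    rowsum = vals.sum(axis=1, keepdims=True)
    return _wrap_like(np.log(vals / rowsum), cols, idx)


def clr_transform(table):
    """Centred log-ratio: per row, log values minus their row mean.

    Output rows sum to zero; invariant to per-row rescaling of the input.
    """
    vals, cols, idx = _as_matrix(table)
    if (vals <= 0).any():
        raise ValueError("CLR requires strictly positive entries")
    logged = np.log(vals)
    return _wrap_like(logged - logged.mean(axis=1, keepdims=True), cols, idx)


_TRANSFORM_FUNCS = {
    "log": log_transform,
    "log-tss": log_tss_transform,
    "clr": clr_transform,
}


def pearson_cross_correlation(A, B):
    """Empirical Pearson correlations between columns of A and columns of B.

    Parameters
    ----------
    A : array-like, shape (n, p)
    B : array-like, shape (n, q)

    Returns
    -------
    ndarray, shape (p, q)
        Entry (i, k) is the Pearson correlation of column i of ``A`` with
        column k of ``B``.  Columns with zero variance yield NaN in their
        row/column with a warning rather than aborting the whole run.
    """
    Av, a_cols, _ = _as_matrix(A)
    Bv, b_cols, _ = _as_matrix(B)
    if Bv.ndim == 1:
        Bv = Bv[:, None]
    if Av.shape[0] != Bv.shape[0]:
        raise ValueError("A and B must have the same number of rows")
    n = Av.shape[0]
    if n < 3:
        raise ValueError("need at least 3 replicates for a correlation")

    Ac = Av - Av.mean(axis=0)
    Bc = Bv - Bv.mean(axis=0)
    sa = Ac.std(axis=0, ddof=1)
    sb = Bc.std(axis=0, ddof=1)

    for name, sd, cols in (("A", sa, a_cols), ("B", sb, b_cols)):
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            labels = [str(cols[i]) if cols is not None else str(i) for i in bad]
            warnings.warn(
                f"constant column(s) in {name}: {labels}; "
                "their correlations are undefined and reported as NaN",
                RuntimeWarning,
                stacklevel=2,
            )

    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Ac.T @ Bc) / (n - 1) / np.outer(sa, sb)
    # float noise can push |r| marginally past 1
    np.clip(corr, -1.0, 1.0, out=corr, where=np.isfinite(corr))
    return corr


class CompositionalLogTransform(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer applying one of log / log-TSS / CLR.

    Adds ``pseudo_count`` to the raw counts and applies the chosen
    log-transformation.  ``fit`` only records the input dimension; the
    transform carries no fitted state, so it composes safely inside
    pipelines and cross-validation.

    Parameters
    ----------
    kind : {"log", "log-tss", "clr"}
    pseudo_count : float, default 1.0
    """

    def __init__(self, kind: str = "clr", pseudo_count: float = 1.0):
        self.kind = kind
        self.pseudo_count = pseudo_count

    def fit(self, X, y=None):
        if self.kind not in _TRANSFORMS:
            raise ValueError(f"kind must be one of {_TRANSFORMS}, got {self.kind!r}")
        vals, _, _ = _as_matrix(X)
        self.n_features_in_ = vals.shape[1]
        return self

    def transform(self, X):
        if self.kind not in _TRANSFORMS:
            raise ValueError(f"kind must be one of {_TRANSFORMS}, got {self.kind!r}")
        shifted = apply_pseudo_count(X, self.pseudo_count)
        return _TRANSFORM_FUNCS[self.kind](shifted)
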