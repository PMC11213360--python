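"""Benchmarking machinery: stratified MAE criteria and a replicated study runner.

Estimators are scored only on the cross-block A_pq of the ground-truth
correlation matrix (OTU x phenotype or OTU x gene pairs); within-dataset
correlations are never evaluated.  Two criteria match the two ways the
truth is generated:

* cluster truth has exact zeros, so the mean absolute error is split into
  the pairs whose true correlation is non-zero and the pairs whose true
  correlation is zero (an all-zero estimator scores a deceptively low
  overall MAE of c*rho, hence the split);
* loadings truth has no exact zeros, so the MAE is reported restricted to
  pairs with |Psi_ij| >= u for u = 0, 0.1, ..., 0.8 (u = 0 being the
  overall MAE).

``run_simulation_study`` repeats simulate -> estimate -> score over seeded
datasets and reports per-method means with +/- 1.96 SE envelopes, exactly
the summary the benchmark figures are built from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import sparcev as _sparcev
from . import sparxcc as _sparxcc
from .transforms import CompositionalLogTransform, pearson_cross_correlation

__all__ = [
    "MAEReport",
    "mae_split",
    "mae_thresholded",
    "power_fdr",
    "run_simulation_study",
    "case_b_estimators",
    "case_c_estimators",
    "DEFAULT_THRESHOLDS",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.0, 0.81, 0.1), 1))


@dataclass
class MAEReport:
    """Stratified MAE of one estimate against one truth."""

    mae_correlated: float
    mae_uncorrelated: float
    mae_by_threshold: dict
    n_correlated: int
    n_uncorrelated: int


def _check_shapes(truth, est):
    truth = np.asarray(truth, dtype=float)
    est = np.asarray(est, dtype=float)
    if truth.shape != est.shape:
        raise ValueError(f"truth shape {truth.shape} != estimate shape {est.shape}")
    return truth.ravel(), est.ravel()


def mae_split(truth, est):
    """MAE over truly correlated pairs and over truly uncorrelated pairs.

    NaN estimates (undefined correlations, e.g. constant columns) are
    excluded from the means; an empty stratum is reported as NaN, never 0.
    """
    t, e = _check_shapes(truth, est)
    err = np.abs(t - e)
    corr = t != 0
    with np.errstate(invalid="ignore"):
        mae_c = float(np.nanmean(err[corr])) if corr.any() else float("nan")
        mae_u = float(np.nanmean(err[~corr])) if (~corr).any() else float("nan")
    return mae_c, mae_u


def mae_thresholded(truth, est, thresholds=DEFAULT_THRESHOLDS):
    """MAE restricted to pairs with |truth| >= u, for each threshold u."""
    thresholds = list(thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted ascending")
    t, e = _check_shapes(truth, est)
    err = np.abs(t - e)
    out = {}
    for u in thresholds:
        sel = np.abs(t) >= u
        out[float(u)] = float(np.nanmean(err[sel])) if sel.any() else float("nan")
    return out


def power_fdr(truth_nonzero_mask, detected_mask):
    """Detection power and false discovery rate of a boolean detection mask.

    power = TP / (# truly non-zero); fdr = FP / (# detected), defined as 0
    when nothing is detected.
    """
    t = np.asarray(truth_nonzero_mask, dtype=bool).ravel()
    d = np.asarray(detected_mask, dtype=bool).ravel()
    if t.shape != d.shape:
        raise ValueError("masks differ in shape")
    tp = int((t & d).sum())
    fp = int((~t & d).sum())
    n_true = int(t.sum())
    power = tp / n_true if n_true else float("nan")
    fdr = fp / d.sum() if d.sum() else 0.0
    return power, fdr


def _report(truth, est, thresholds):
    mae_c, mae_u = mae_split(truth, est)
    t = np.asarray(truth).ravel()
    return MAEReport(
        mae_correlated=mae_c, mae_uncorrelated=mae_u,
        mae_by_threshold=mae_thresholded(truth, est, thresholds),
        n_correlated=int((t != 0).sum()), n_uncorrelated=int((t == 0).sum()),
    )


# ---------------------------------------------------------------------------
# standard estimator banks


def _baseline_case_b(kind):
    def estimate(dataset, seed=None):
        tf = CompositionalLogTransform(kind=kind).fit(dataset.X)
        vals = np.asarray(tf.transform(dataset.X))
        return pearson_cross_correlation(vals, np.asarray(dataset.b).reshape(-1, 1))
    return estimate


def _baseline_case_c(kind):
    def estimate(dataset, seed=None):
        tf = CompositionalLogTransform(kind=kind)
        vx = np.asarray(tf.fit(dataset.X).transform(dataset.X))
        vy = np.asarray(tf.fit(dataset.Y).transform(dataset.Y))
        return pearson_cross_correlation(vx, vy)
    return estimate


def case_b_estimators(pseudo_count: float = 1.0, percentile: float = 80.0,
                      n_perm: int = 20, max_iter: int = 20):
    """The standard case B bank: log, log-TSS, CLR, SparCEV base/iterative."""

    def base(dataset, seed=None):
        res = _sparcev.sparcev_base(dataset.X, dataset.b, pseudo_count)
        return res.rho.reshape(-1, 1)

    def iterative(dataset, seed=None):
        t = _sparcev.select_threshold_case_b(
            dataset.X, dataset.b, pseudo_count, n_perm=n_perm,
            percentile=percentile, seed=seed,
        )
        res = _sparcev.sparcev_iterative(dataset.X, dataset.b, pseudo_count,
                                         t=t, max_iter=max_iter)
        return res.rho.reshape(-1, 1)

    return {
        "log": _baseline_case_b("log"),
        "log-TSS": _baseline_case_b("log-tss"),
        "CLR": _baseline_case_b("clr"),
        "SparCEV base": base,
        "SparCEV iterative": iterative,
    }


def case_c_estimators(pseudo_count: float = 1.0, percentile: float = 100.0,
                      n_perm: int = 20, max_iter: int = 20):
    """The standard case C bank: log, log-TSS, CLR, SparXCC base/iterative.

    The iterative thresholds use the max-percentile permutation rule
    (percentile=100): the per-OTU set criterion averages q estimates, so
    its null distribution is tight and any compositional bias — the very
    situation the iteration exists for — lifts every feature above a mere
    80th-percentile null threshold, emptying the reference sets.  Taking
    the maximum of the permutation pool keeps the vast majority of
    uncorrelated features eligible.
    """

    def base(dataset, seed=None):
        return _sparxcc.sparxcc_base(dataset.X, dataset.Y, pseudo_count).rho

    def iterative(dataset, seed=None):
        t1, t2 = _sparxcc.select_thresholds_case_c(
            dataset.X, dataset.Y, pseudo_count, n_perm=n_perm,
            percentile=percentile, seed=seed,
        )
        return _sparxcc.sparxcc_iterative(dataset.X, dataset.Y, pseudo_count,
                                          t1=t1, t2=t2, max_iter=max_iter).rho

    return {
        "log": _baseline_case_c("log"),
        "log-TSS": _baseline_case_c("log-tss"),
        "CLR": _baseline_case_c("clr"),
        "SparXCC base": base,
        "SparXCC iterative": iterative,
    }


# ---------------------------------------------------------------------------
# study runner


def run_simulation_study(simulate, estimators, n_datasets: int, seed=None,
                         thresholds=DEFAULT_THRESHOLDS):
    """Replicated simulation study with standard-error envelopes.

    Parameters
    ----------
    simulate : callable(seed) -> SimulatedDataset
        Seeded dataset generator defining the study conditions.
    estimators : mapping name -> callable(dataset, seed) -> estimate
        Each estimate must match the shape of ``dataset.truth_cross``.
    n_datasets : int (>= 2)
    seed : master seed; per-dataset seeds are spawned from it via
        ``numpy.random.SeedSequence`` so the study is reproducible and
        parallelisable.
    thresholds : thresholds u for the loadings-style MAE criterion.

    Returns
    -------
    (summary, raw) : two DataFrames.  ``summary`` is long-format with one
    row per (method, metric): the mean over datasets, the standard error
    SD/sqrt(n), and the +/- 1.96 SE envelope edges.  ``raw`` holds the
    per-dataset metric values.  Estimator failures are logged, counted in
    ``summary["n_failed"]`` and excluded from the means.
    """
    if n_datasets < 2:
        raise ValueError("n_datasets must be >= 2")
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_datasets)

    rows = []
    failures = {name: 0 for name in estimators}
    for d, child in enumerate(children):
        data_ss, est_ss = child.spawn(2)
        dataset = simulate(data_ss)
        truth = dataset.truth_cross
        for name, fn in estimators.items():
            try:
                est = np.asarray(fn(dataset, est_ss), dtype=float)
                rep = _report(truth, est.reshape(truth.shape), thresholds)
            except Exception:
                logger.exception("estimator %r failed on dataset %d", name, d)
                failures[name] += 1
                continue
            row = {"method": name, "dataset": d,
                   "mae_correlated": rep.mae_correlated,
                   "mae_uncorrelated": rep.mae_uncorrelated}
            for u, v in rep.mae_by_threshold.items():
                row[f"mae_u{u:g}"] = v
            rows.append(row)

    raw = pd.DataFrame(rows)
    metrics = [c for c in raw.columns if c not in ("method", "dataset")]
    summary_rows = []
    for name in estimators:
        sub = raw[raw["method"] == name]
        for metric in metrics:
            vals = sub[metric].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                mean = se = float("nan")
            else:
                mean = float(vals.mean())
                se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
            summary_rows.append({
                "method": name, "metric": metric, "mean": mean, "se": se,
                "lower": mean - 1.96 * se, "upper": mean + 1.96 * se,
                "n_datasets": int(sub.shape[0]), "n_failed": failures[name],
            })
    return pd.DataFrame(summary_rows), raw
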