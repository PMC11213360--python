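"""Count-table readers/writers and result serialisation.

Canonical orientation: replicates in rows, features in columns, header row
of feature ids, first column of replicate ids.  Microbiome tables are often
shipped feature-per-row; pass ``transpose=True`` for that dialect.  Output
tables carry the seed and package version in a leading ``#`` comment line
and print floats at 6 significant digits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import __version__
from .simulation import (LibrarySizeParams, SimulatedDataset,
                         cluster_correlation_matrix,
                         loadings_correlation_matrix, simulate_dataset,
                         study_marginals)

__all__ = [
    "read_count_table",
    "read_phenotype",
    "write_count_table",
    "write_case_b_result",
    "write_case_c_result",
    "make_fixture",
    "FIXTURE_KINDS",
]


def read_count_table(path, transpose: bool = False) -> pd.DataFrame:
    """Read and validate a TSV/CSV count table.

    Rejects ragged rows, non-numeric or negative cells, non-integer counts
    (naming the offending cell) and duplicate identifiers.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    # pandas silently renames duplicate header fields; check them raw first
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split(sep)[1:]
                break
        else:
            raise ValueError(f"empty table file {path}")
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        kind = "replicate" if transpose else "feature"
        raise ValueError(f"duplicate {kind} ids: {dupes}")
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    if transpose:
        df = df.T
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate replicate ids: {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dupes}")
    try:
        vals = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric entries in count table {path}: {exc}") from None
    if np.isnan(vals).any():
        r, c = np.argwhere(np.isnan(vals))[0]
        raise ValueError(
            f"missing/non-numeric value at replicate {df.index[r]!r}, "
            f"feature {df.columns[c]!r}"
        )
    if (vals < 0).any():
        r, c = np.argwhere(vals < 0)[0]
        raise ValueError(
            f"negative count at replicate {df.index[r]!r}, feature {df.columns[c]!r}"
        )
    if not np.array_equal(vals, np.round(vals)):
        r, c = np.argwhere(vals != np.round(vals))[0]
        raise ValueError(
            f"non-integer count at replicate {df.index[r]!r}, "
            f"feature {df.columns[c]!r}"
        )
    return df.astype(np.int64)


def read_phenotype(path) -> pd.Series:
    """Read a phenotype vector: one value per replicate.

    Accepts a one-column file (values only) or a two-column file
    (replicate id, value), with or without a header.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#", header=None)
    # drop a header row if the last column is not numeric there
    try:
        float(df.iloc[0, -1])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    if df.shape[1] == 1:
        s = pd.Series(df.iloc[:, 0].astype(float).to_numpy())
    elif df.shape[1] == 2:
        s = pd.Series(df.iloc[:, 1].astype(float).to_numpy(),
                      index=df.iloc[:, 0].astype(str).to_numpy())
    else:
        raise ValueError("phenotype file must have 1 or 2 columns")
    if not np.all(np.isfinite(s.to_numpy())):
        raise ValueError("phenotype contains non-finite values")
    return s


def _header_line(seed) -> str:
    return f"# compocross v{__version__} seed={seed}\n"


def write_count_table(df: pd.DataFrame, path, transpose: bool = False) -> None:
    out = df.T if transpose else df
    out.to_csv(path, sep="\t")


def _fmt(x) -> str:
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    if isinstance(x, (float, np.floating)):
        return "nan" if not np.isfinite(x) else f"{x:.6g}"
    return str(x)


def _write_tsv(path, header_comment, columns, rows) -> None:
    lines = [header_comment, "\t".join(columns) + "\n"]
    for row in rows:
        lines.append("\t".join(_fmt(v) for v in row) + "\n")
    with open(path, "w") as fh:  # built fully in memory: no partial files
        fh.writelines(lines)


def write_case_b_result(result, feature_ids, path, seed=None, detected=None,
                        ci=None) -> None:
    """Serialise a SparCEV result: one row per feature."""
    p = result.rho.shape[0]
    in_r = np.zeros(p, dtype=bool)
    in_r[result.included_set] = True
    cols = ["feature", "rho", "clipped", "in_R"]
    if detected is not None:
        cols.append("detected")
    if ci is not None:
        cols += ["ci_lower", "ci_upper"]
    rows = []
    for i in range(p):
        row = [feature_ids[i], result.rho[i], result.clipped_to_unit[i], in_r[i]]
        if detected is not None:
            row.append(detected[i])
        if ci is not None:
            row += [ci[0][i], ci[1][i]]
        rows.append(row)
    _write_tsv(path, _header_line(seed), cols, rows)


def write_case_c_result(result, x_ids, y_ids, path, seed=None, detected=None) -> None:
    """Serialise a SparXCC result in long format: one row per (x, y) pair."""
    p, q = result.rho.shape
    cols = ["feature_x", "feature_y", "rho", "clipped"]
    if detected is not None:
        cols.append("detected")
    rows = []
    for i in range(p):
        for k in range(q):
            row = [x_ids[i], y_ids[k], result.rho[i, k], result.clipped_to_unit[i, k]]
            if detected is not None:
                row.append(detected[i, k])
            rows.append(row)
    _write_tsv(path, _header_line(seed), cols, rows)


FIXTURE_KINDS = ("caseB_cluster", "caseB_loadings", "caseC_cluster",
                 "caseC_loadings", "null")

_FIXTURE_N = 20
_FIXTURE_P = 15
_FIXTURE_Q = 10


def make_fixture(kind: str, seed: int = 0) -> SimulatedDataset:
    """Deterministic miniature dataset (n=20, p,q <= 20) for tests and docs."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    p, q, n = _FIXTURE_P, _FIXTURE_Q, _FIXTURE_N
    if kind.startswith("caseB") or kind == "null":
        case, q_eff = "B", 1
    else:
        case, q_eff = "C", q
    if kind == "null":
        psi = np.eye(p + q_eff)
    elif kind.endswith("cluster"):
        psi = cluster_correlation_matrix(p, q_eff, c=0.2, rho=0.75, case=case)
    else:
        psi = loadings_correlation_matrix(p + q_eff, k=3, seed=seed)
    marg = study_marginals(p, q_eff, case=case)
    libs = LibrarySizeParams(mu_a=np.log(5e3), sigma2_a=0.5,
                             mu_b=np.log(5e3) if case == "C" else None,
                             sigma2_b=0.5 if case == "C" else None)
    return simulate_dataset(psi, marg, libs, n=n, case=case, q=q_eff, seed=seed)
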