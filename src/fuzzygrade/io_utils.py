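"""Tabular I/O and preprocessing for the grading pipeline.

File conventions: tab-separated expression tables (probes × samples, header
row of sample ids, first column of probe ids, '.' decimal, 'NA' for
missing), comma-separated sample annotations, JSON signatures and
tab-separated call tables.  Housekeeping normalization subtracts, per
sample, the mean log-expression of a set of reference probes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"
ORIENTATIONS = ("probes_by_samples", "samples_by_probes")
CALL_COLUMNS = ["sample_id", "gad1", "gad3", "score", "label", "equivocal"]


def read_expression(path, orientation: str = "probes_by_samples") -> pd.DataFrame:
    """Read a numeric expression TSV into a probes × samples DataFrame.

    Duplicate probe ids and non-numeric cells are rejected with the
    offending line number; missing cells ('NA' or empty) are kept as NaN.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str,
        na_values=[MISSING_TOKEN], keep_default_na=False,
    )
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()].unique()
        lines = [int(np.flatnonzero(raw.index == d)[1]) + 2 for d in dup[:5]]
        raise ValueError(
            f"duplicate row ids {dup[:5].tolist()} (e.g. at lines {lines})"
        )
    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell {raw.iat[r, c]!r} at line {r + 2}, "
            f"column {raw.columns[c]!r}"
        )
    mat = numeric if orientation == "probes_by_samples" else numeric.T
    mat.index.name = "probe_id"
    return mat


def write_expression(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index_label="probe_id")


def read_labels(path) -> pd.DataFrame:
    """Read sample annotations (sample_id, grade, er[, time, event]).

    Grades are validated at parse time; ER defaults to 'unknown'.
    """
    df = pd.read_csv(path, dtype=str, na_values=[MISSING_TOKEN], keep_default_na=True)
    if "sample_id" not in df.columns or "grade" not in df.columns:
        raise ValueError("labels file needs 'sample_id' and 'grade' columns")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise ValueError(f"duplicate sample ids {dup[:5]}")
    df = df.set_index("sample_id")
    grade = df["grade"].fillna("unknown").astype(str).str.strip().str.lower()
    valid = {"1", "2", "3", "unknown"}
    bad = sorted(set(grade.unique()) - valid)
    if bad:
        raise ValueError(f"invalid grade values {bad}; expected {sorted(valid)}")
    df["grade"] = grade
    if "er" in df.columns:
        er = df["er"].fillna("unknown").astype(str).str.strip().str.lower()
        bad = sorted(set(er.unique()) - {"pos", "neg", "unknown"})
        if bad:
            raise ValueError(f"invalid er values {bad}; expected pos/neg/unknown")
        df["er"] = er
    else:
        df["er"] = "unknown"
    for col in ("time", "event"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_calls(calls: pd.DataFrame, path) -> None:
    """Write classification calls with the fixed column order."""
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"calls table is missing columns {missing}")
    calls[CALL_COLUMNS].to_csv(path, sep="\t", index=False)


def housekeeping_normalize(mat: pd.DataFrame, reference_probe_ids) -> pd.DataFrame:
    """Subtract each sample's mean reference-probe (log) expression."""
    ref = [str(r) for r in reference_probe_ids]
    missing = [r for r in ref if r not in mat.index]
    if missing:
        raise ValueError(f"reference probes absent from the matrix: {missing}")
    offsets = mat.loc[ref].mean(axis=0)
    return mat - offsets


def select_reference_probes(mat: pd.DataFrame, candidate_ids, k: int) -> list:
    """Pick the k most stable candidates (lowest across-sample variance)."""
    cand = [str(c) for c in candidate_ids]
    missing = [c for c in cand if c not in mat.index]
    if missing:
        raise ValueError(f"candidate probes absent from the matrix: {missing}")
    if not 1 <= k <= len(cand):
        raise ValueError(f"k must be in [1, {len(cand)}]")
    var = mat.loc[cand].var(axis=1, ddof=1)
    order = var.sort_values(kind="stable").index
    return list(order[:k])


def rowstandardize_for_heatmap(mat: pd.DataFrame) -> pd.DataFrame:
    """Z-score each probe row for heatmap export.

    Uses the population SD (ddof=0) so every output row has mean 0 and
    standard deviation exactly 1.
    """
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=0)
    constant = sd.fillna(0.0) == 0.0
    if constant.any():
        bad = mat.index[constant][:5].tolist()
        raise ValueError(f"constant rows cannot be standardized: {bad}")
    return mat.sub(mean, axis=0).div(sd, axis=0)
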