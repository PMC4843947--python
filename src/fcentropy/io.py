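"""Reading and writing the pipeline's on-disk artifacts.

All matrices are plain delimited text with no header; region order is
positional and shared across a subject's files. Subject metadata is a
single CSV with a header row and ``subject_id`` as the join key; missing
fields (duration, symptom score for controls) are empty cells.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

COHORT_COLUMNS = ("subject_id", "group", "age", "sex", "dose", "duration", "symptom_score")
GROUPS = ("patient", "control")


def _load_text_matrix(path: str | Path) -> np.ndarray:
    """Parse a delimited numeric table (tab, comma or whitespace)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    first = ""
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                first = line
                break
    delimiter = "," if "," in first else None  # None = any whitespace
    try:
        arr = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: could not parse as numeric table: {exc}") from exc
    return arr


def read_streamline_matrix(path: str | Path, n: int | None = None) -> np.ndarray:
    """Read and validate an N x N streamline-count matrix.

    The matrix must be square, symmetric (exact equality), with
    nonnegative integer entries and a zero diagonal.
    """
    arr = _load_text_matrix(path)
    if arr.shape[0] != arr.shape[1]:
        raise FormatError(f"{path}: streamline matrix is not square ({arr.shape})")
    if n is not None and arr.shape[0] != n:
        raise FormatError(f"{path}: expected {n} regions, found {arr.shape[0]}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{path}: non-finite streamline count")
    if np.any(arr < 0):
        i, j = np.argwhere(arr < 0)[0]
        raise ValidationError(f"{path}: negative count at ({i}, {j})")
    if not np.all(arr == np.round(arr)):
        i, j = np.argwhere(arr != np.round(arr))[0]
        raise ValidationError(f"{path}: non-integer count at ({i}, {j})")
    if np.any(np.diag(arr) != 0):
        raise ValidationError(f"{path}: nonzero diagonal entry")
    asym = np.argwhere(arr != arr.T)
    if asym.size:
        i, j = asym[0]
        raise ValidationError(
            f"{path}: asymmetric at pair ({i}, {j}): {arr[i, j]} vs {arr[j, i]}"
        )
    return arr.astype(np.int64)


def read_timeseries(path: str | Path, n: int | None = None) -> np.ndarray:
    """Read a T x N regional time-series table (T time points, N regions)."""
    arr = _load_text_matrix(path)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{path}: time series contains NaN/inf")
    if arr.shape[0] < 2:
        raise ValidationError(f"{path}: need at least 2 time points, found {arr.shape[0]}")
    if n is not None and arr.shape[1] != n:
        raise FormatError(f"{path}: expected {n} regions, found {arr.shape[1]}")
    return arr.astype(np.float64)


def write_matrix(path: str | Path, matrix: np.ndarray, integer: bool = False) -> None:
    """Write a matrix as tab-delimited text, full precision for reals."""
    fmt = "%d" if integer else "%.17g"
    np.savetxt(path, np.atleast_2d(matrix), fmt=fmt, delimiter="\t")


def read_class_matrix(path: str | Path) -> np.ndarray:
    """Read an integer-coded path-class matrix (see :mod:`.structural`)."""
    arr = _load_text_matrix(path)
    if arr.shape[0] != arr.shape[1]:
        raise FormatError(f"{path}: class matrix is not square ({arr.shape})")
    if not np.all(arr == np.round(arr)):
        raise ValidationError(f"{path}: non-integer class code")
    return arr.astype(np.int8)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate the subject-metadata table.

    Columns: subject_id, group (patient/control), age, sex (M/F), dose
    (CPZ-equivalent mg/day), duration (years, patients only),
    symptom_score (total SSPI, patients only). An optional
    ``control_subset`` column ({early, late, both}) marks which
    duration stratum each control is matched to.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: cohort table missing columns {missing}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate subject_id {dup!r}")
    bad_group = set(df["group"]) - set(GROUPS)
    if bad_group:
        raise ValidationError(f"{path}: unknown group labels {sorted(bad_group)}")
    if (df["age"] <= 0).any():
        raise ValidationError(f"{path}: non-positive age")
    if (df["dose"].fillna(0) < 0).any():
        raise ValidationError(f"{path}: negative dose")
    if (df["duration"].dropna() < 0).any():
        raise ValidationError(f"{path}: negative illness duration")
    bad_sex = set(df["sex"]) - {"M", "F"}
    if bad_sex:
        raise ValidationError(f"{path}: sex must be M or F, found {sorted(bad_sex)}")
    return df


def write_cohort(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)
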