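"""Reading, validation and normalization of label-free quantification tables.

LFQ intensity tables follow the MaxQuant ``proteinGroups.txt`` dialect: one
tab-separated row per protein group, a protein-identifier column, and one
``LFQ intensity <run>`` column per MS run.  A raw intensity of 0 means the
protein was not quantified in that run (missing), not that the signal was
zero; missingness is therefore carried explicitly as NaN throughout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LfqMatrix",
    "SampleMeta",
    "read_lfq_table",
    "write_lfq_table",
    "read_sample_meta",
    "log_normalize",
    "make_log_matrix",
    "zscore_columns",
    "zscore_by_subject",
]

DEFAULT_INTENSITY_PREFIX = "LFQ intensity "
DEFAULT_ID_COLUMN = "Majority protein IDs"

#: metadata columns every sample table must provide
META_COLUMNS = ("run_id", "subject_id", "group", "daynight", "time_of_death")


@dataclass
class LfqMatrix:
    """Proteins x runs intensity matrix with explicit missingness.

    ``intensity`` is a float DataFrame indexed by protein id with one column
    per run; NaN marks a missing (not-quantified) cell.  All non-missing
    values are non-negative.
    """

    intensity: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.intensity
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dup[:5]}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate run ids: {dup[:5]}")
        vals = df.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            raise ValueError("negative intensities are not allowed")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensity.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.intensity.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the cell is missing."""
        return self.intensity.isna()


@dataclass
class SampleMeta:
    """Per-run sample annotations: subject, diagnosis group, day/night label
    and time of death (hour-of-day in [0, 24)).

    Day/night labels are taken as given and never derived from
    ``time_of_death``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in META_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"metadata lacks required columns: {missing}")
        if t["run_id"].duplicated().any():
            dup = t.loc[t["run_id"].duplicated(), "run_id"].tolist()
            raise ValueError(f"run assigned to more than one row: {dup[:5]}")
        tod = t["time_of_death"].to_numpy(dtype=float)
        if np.any((tod < 0) | (tod >= 24)):
            raise ValueError("time_of_death must lie in [0, 24)")
        for col in ("group", "daynight"):
            if t[col].isna().any() or (t[col].astype(str).str.len() == 0).any():
                raise ValueError(f"empty values in metadata column {col!r}")
        # a subject's annotations must agree across its replicate runs
        per_subj = t.groupby("subject_id")[["group", "daynight", "time_of_death"]].nunique()
        bad = per_subj[(per_subj > 1).any(axis=1)].index.tolist()
        if bad:
            raise ValueError(f"inconsistent annotations within subjects: {bad[:5]}")
        self.table = t.reset_index(drop=True)

    @property
    def run_ids(self) -> list[str]:
        return list(self.table["run_id"])

    @property
    def subject_ids(self) -> list[str]:
        return list(self.table["subject_id"].drop_duplicates())

    def replicate_runs(self, subject_id: str) -> list[str]:
        rows = self.table[self.table["subject_id"] == subject_id]
        if rows.empty:
            raise KeyError(subject_id)
        return list(rows["run_id"])

    def subject_table(self) -> pd.DataFrame:
        """One row per subject (group, daynight, time_of_death)."""
        return (
            self.table.groupby("subject_id", sort=False)[
                ["group", "daynight", "time_of_death"]
            ]
            .first()
            .reset_index()
        )

    def subject_label(self, subject_id: str, on: str) -> str:
        rows = self.table[self.table["subject_id"] == subject_id]
        return str(rows[on].iloc[0])

    def select(self, **conditions: str) -> "SampleMeta":
        """Subset runs, e.g. ``meta.select(group="control")``."""
        keep = pd.Series(True, index=self.table.index)
        for col, val in conditions.items():
            keep &= self.table[col] == val
        return SampleMeta(self.table[keep].reset_index(drop=True))


def read_lfq_table(
    path,
    column_prefix: str = DEFAULT_INTENSITY_PREFIX,
    id_column: str = DEFAULT_ID_COLUMN,
) -> LfqMatrix:
    """Read a MaxQuant-style tab-delimited LFQ table.

    Intensity columns are those whose header starts with ``column_prefix``;
    the run id is the remainder of the header.  Zeros, empty cells and the
    string ``NaN`` all encode missing.  Row order is preserved.
    """
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter="\t"))
    runs = [h[len(column_prefix):] for h in header if h.startswith(column_prefix)]
    seen: set[str] = set()
    for r in runs:
        if r in seen:
            raise ValueError(f"duplicate run column {column_prefix + r!r}")
        seen.add(r)
    if id_column not in header:
        raise ValueError(f"protein identifier column {id_column!r} not found")
    if not runs:
        raise ValueError(f"no intensity columns with prefix {column_prefix!r}")

    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    intensity = pd.DataFrame(index=raw[id_column])
    for r in runs:
        col = raw[column_prefix + r]
        parsed = pd.to_numeric(col.replace({"": np.nan, "NaN": np.nan, "nan": np.nan}),
                               errors="coerce")
        bad = parsed.isna() & ~col.isin(["", "NaN", "nan"])
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric intensity {col.iloc[i]!r} at row {i} "
                f"column {column_prefix + r!r}"
            )
        vals = parsed.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            raise ValueError(f"negative intensity in column {column_prefix + r!r}")
        vals[vals == 0] = np.nan  # MaxQuant writes 0 for not-quantified
        intensity[r] = vals
    intensity.index.name = "protein_id"
    return LfqMatrix(intensity)


def write_lfq_table(
    matrix: LfqMatrix,
    path,
    column_prefix: str = DEFAULT_INTENSITY_PREFIX,
    id_column: str = DEFAULT_ID_COLUMN,
) -> None:
    """Write the MaxQuant dialect ``read_lfq_table`` consumes (missing -> 0)."""
    out = pd.DataFrame({id_column: matrix.protein_ids})
    filled = matrix.intensity.fillna(0.0)
    for r in matrix.run_ids:
        out[column_prefix + r] = filled[r].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_sample_meta(path) -> SampleMeta:
    """Read a TSV/CSV sample table (delimiter sniffed from the extension)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    return SampleMeta(pd.read_csv(path, sep=sep, dtype={"run_id": str, "subject_id": str}))


def log_normalize(matrix: LfqMatrix, base: float = 2.0) -> LfqMatrix:
    """log-transform intensities (base 2 by default); missing preserved.

    Non-missing zeros or negatives are a contract violation (zero must have
    been mapped to missing at read time) and raise.
    """
    vals = matrix.intensity.to_numpy(dtype=float)
    nonmissing = ~np.isnan(vals)
    if np.any(vals[nonmissing] <= 0):
        raise ValueError("non-missing values must be strictly positive for log transform")
    out = np.full_like(vals, np.nan)
    out[nonmissing] = np.log(vals[nonmissing]) / np.log(base)
    return make_log_matrix(pd.DataFrame(out, index=matrix.intensity.index,
                                        columns=matrix.intensity.columns))


def make_log_matrix(values: pd.DataFrame) -> LfqMatrix:
    """Wrap an already log-scale DataFrame (values may be negative)."""
    m = LfqMatrix.__new__(LfqMatrix)  # skip the raw-scale non-negativity check
    m.intensity = values
    return m


def zscore_columns(df: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Column-wise standardization over non-missing entries.

    Raises for any column with fewer than 2 non-missing values or zero
    standard deviation.
    """
    vals = df.to_numpy(dtype=float)
    n = np.sum(~np.isnan(vals), axis=0)
    if np.any(n < 2):
        bad = df.columns[n < 2].tolist()
        raise ValueError(f"columns with < 2 non-missing values: {bad[:5]}")
    mean = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0, ddof=ddof)
    if np.any(sd == 0):
        bad = df.columns[sd == 0].tolist()
        raise ValueError(f"zero standard deviation in columns: {bad[:5]}")
    return pd.DataFrame((vals - mean) / sd, index=df.index, columns=df.columns)


def zscore_by_subject(norm: LfqMatrix, meta: SampleMeta | None = None,
                      ddof: int = 1) -> pd.DataFrame:
    """Per-subject Z-scores across proteins.

    If ``meta`` is given the matrix columns are replicate runs: observed
    replicates are averaged per subject first (no imputation here — the
    Monte-Carlo machinery lives in :mod:`dielprot.presence`), then each
    subject column is standardized over its non-missing proteins.  Without
    ``meta`` the columns are taken to be subject-level already.
    """
    df = norm.intensity
    if meta is not None:
        cols = {}
        for subj in meta.subject_ids:
            runs = meta.replicate_runs(subj)
            cols[subj] = df[runs].mean(axis=1, skipna=True)
        df = pd.DataFrame(cols, index=df.index)
    return zscore_columns(df, ddof=ddof)
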