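"""Reading, reshaping and describing repeated-measures tables.

Longitudinal cohort data usually arrive *wide* — one row per individual with
repeated age and outcome columns (``age_t1..age_tk``, ``score_t1..score_tk``)
— while mixed-model fitting wants *long* data, one row per measurement
occasion within each individual.  This module parses delimited text tables,
validates a wide-format specification, performs the wide-to-long pivot,
computes per-occasion descriptive statistics, and writes long data back out.

Missing values are ``"NA"`` (exact, case-sensitive) or empty cells on input
and are always written back as ``"NA"``.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "WideSpec",
    "LongDataset",
    "ParseError",
    "ValidationError",
    "parse_table",
    "validate_wide_spec",
    "reshape_wide_to_long",
    "describe_by_occasion",
    "write_long",
]

#: tokens interpreted as missing on input; "NA" is also the output sentinel
NA_TOKENS = ("NA", "")


class ParseError(ValueError):
    """Raised for malformed input tables (e.g. ragged rows)."""


class ValidationError(ValueError):
    """Raised when a wide-format specification does not match the table."""

    def __init__(self, issues: list[str]):
        self.issues = list(issues)
        super().__init__("; ".join(issues))


@dataclass(frozen=True)
class WideSpec:
    """Mapping from wide columns to the long layout.

    ``age_cols[j]`` and ``outcome_cols[j]`` together define occasion ``j+1``.
    The three ``*_name`` fields name the new long-format columns.
    """

    subject_col: str
    age_cols: tuple[str, ...]
    outcome_cols: tuple[str, ...]
    occasion_name: str = "time_point"
    outcome_name: str = "score"
    age_name: str = "age"

    def __post_init__(self):
        object.__setattr__(self, "age_cols", tuple(self.age_cols))
        object.__setattr__(self, "outcome_cols", tuple(self.outcome_cols))


@dataclass
class LongDataset:
    """A tidy repeated-measures table plus the roles of its columns.

    ``data`` holds one row per (subject, occasion); missing values are NaN.
    ``occasion_levels`` fixes the declared occasion order for summaries.
    """

    data: pd.DataFrame
    subject_col: str
    occasion_col: str
    time_col: str
    outcome_col: str
    covariate_cols: tuple[str, ...] = ()
    weight_col: str | None = None
    occasion_levels: tuple = ()

    def __post_init__(self):
        if not self.occasion_levels:
            levels = pd.unique(self.data[self.occasion_col].dropna())
            self.occasion_levels = tuple(levels)

    @property
    def n_subjects(self) -> int:
        return self.data[self.subject_col].nunique()

    def subset(self, mask) -> "LongDataset":
        return replace(self, data=self.data.loc[mask].reset_index(drop=True))


def _infer_dialect(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".csv":
        return "csv"
    if ext in (".tsv", ".txt"):
        return "tsv"
    return "csv"


def parse_table(path, dialect: str | None = None) -> pd.DataFrame:
    """Read a delimited text table into a DataFrame.

    ``dialect`` is ``"csv"`` or ``"tsv"``; when omitted it is inferred from
    the file extension (``.csv`` → comma; ``.txt``/``.tsv`` → tab).  Cells
    equal to ``"NA"`` (exact) or empty become missing (NaN); numeric-looking
    columns are parsed as numbers; header names are preserved verbatim.

    Raises :class:`ParseError` for ragged rows, naming the offending line.
    """
    if dialect is None:
        dialect = _infer_dialect(path)
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'")
    sep = "," if dialect == "csv" else "\t"

    with open(path, "r", encoding="utf-8", newline="") as fh:
        text = fh.read()

    reader = csv.reader(io.StringIO(text), delimiter=sep)
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError(f"{path}: empty file (no header row)") from None
    ncol = len(header)
    for lineno, row in enumerate(reader, start=2):
        if not row:  # trailing blank line
            continue
        if len(row) != ncol:
            raise ParseError(
                f"{path}: line {lineno} has {len(row)} cells, expected {ncol}"
            )

    df = pd.read_csv(
        io.StringIO(text),
        sep=sep,
        na_values=list(NA_TOKENS),
        keep_default_na=False,
        float_precision="round_trip",
    )
    df.attrs["source_dialect"] = dialect
    return df


def validate_wide_spec(raw: pd.DataFrame, spec: WideSpec) -> list[str]:
    """Check a :class:`WideSpec` against a wide table; return a list of issues.

    An empty list means the spec is valid.  Never raises on well-formed
    inputs: every violation becomes one human-readable issue string.
    """
    issues: list[str] = []
    if len(spec.age_cols) != len(spec.outcome_cols):
        issues.append(
            "unequal number of occasions and outcomes: "
            f"{len(spec.age_cols)} age columns but {len(spec.outcome_cols)} outcome columns"
        )
    if len(spec.age_cols) < 2 or len(spec.outcome_cols) < 2:
        issues.append("at least 2 repeated occasions are required")

    for col in (spec.subject_col, *spec.age_cols, *spec.outcome_cols):
        if col not in raw.columns:
            issues.append(f"column {col!r} not found in table")

    new_names = (spec.occasion_name, spec.outcome_name, spec.age_name)
    if len(set(new_names)) != 3 or spec.subject_col in new_names:
        issues.append(
            "occasion/outcome/age names must be mutually distinct and "
            "distinct from the subject column"
        )

    if spec.subject_col in raw.columns:
        dup = raw[spec.subject_col][raw[spec.subject_col].duplicated()]
        if len(dup):
            issues.append(
                f"duplicate subject ids in wide input (wide format promises one "
                f"row per individual): e.g. {dup.iloc[0]!r}"
            )
    return issues


def reshape_wide_to_long(raw: pd.DataFrame, spec: WideSpec) -> LongDataset:
    """Pivot a wide table to one row per (subject, occasion).

    Occasion ``j`` (1-based, in column order) takes ``spec.age_cols[j-1]`` as
    its time and ``spec.outcome_cols[j-1]`` as its outcome.  Rows where both
    time and outcome are missing are retained — they are dropped at fit time,
    not here.  Columns not named in the spec are carried through unchanged as
    subject-level covariates.
    """
    issues = validate_wide_spec(raw, spec)
    if issues:
        raise ValidationError(issues)

    k = len(spec.age_cols)
    repeated = set(spec.age_cols) | set(spec.outcome_cols)
    covariates = [
        c for c in raw.columns if c != spec.subject_col and c not in repeated
    ]

    pieces = []
    for j in range(k):
        piece = pd.DataFrame(
            {
                spec.subject_col: raw[spec.subject_col].to_numpy(),
                spec.occasion_name: j + 1,
                spec.age_name: raw[spec.age_cols[j]].to_numpy(),
                spec.outcome_name: raw[spec.outcome_cols[j]].to_numpy(),
            }
        )
        for c in covariates:
            piece[c] = raw[c].to_numpy()
        pieces.append(piece)
    # occasion-major then subject order mirrors the wide row order per block;
    # sort by subject (stable) so each individual's occasions are contiguous
    long_df = pd.concat(pieces, ignore_index=True)
    long_df = long_df.sort_values(
        [spec.subject_col, spec.occasion_name], kind="stable"
    ).reset_index(drop=True)

    return LongDataset(
        data=long_df,
        subject_col=spec.subject_col,
        occasion_col=spec.occasion_name,
        time_col=spec.age_name,
        outcome_col=spec.outcome_name,
        covariate_cols=tuple(covariates),
        occasion_levels=tuple(range(1, k + 1)),
    )


def describe_by_occasion(ds: LongDataset) -> pd.DataFrame:
    """Per-occasion descriptive statistics of the outcome.

    Returns one row per declared occasion, in declared order, with the number
    of non-missing outcomes, their mean, sample standard deviation (n-1),
    median and interquartile range (linear interpolation between order
    statistics), and the mean observed time at that occasion.  Occasions with
    no observed outcome get ``n=0`` and missing statistics.
    """
    if ds.data.empty:
        raise ValueError("dataset is empty")
    rows = []
    for occ in ds.occasion_levels:
        sub = ds.data[ds.data[ds.occasion_col] == occ]
        y = pd.to_numeric(sub[ds.outcome_col], errors="coerce").dropna().to_numpy(float)
        t = pd.to_numeric(sub[ds.time_col], errors="coerce").dropna().to_numpy(float)
        n = y.size
        if n == 0:
            stats = dict(mean=np.nan, sd=np.nan, median=np.nan, iqr=np.nan)
        else:
            q75, q25 = np.percentile(y, [75, 25])
            stats = dict(
                mean=float(np.mean(y)),
                sd=float(np.std(y, ddof=1)) if n > 1 else np.nan,
                median=float(np.median(y)),
                iqr=float(q75 - q25),
            )
        rows.append(
            {
                "occasion": occ,
                "n": n,
                **stats,
                "mean_time": float(np.mean(t)) if t.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def write_long(ds: LongDataset, path) -> None:
    """Write a long dataset as CSV, missing cells as the literal ``NA``.

    ``parse_table(write_long(ds))`` reproduces the values exactly: text
    fields verbatim, reals via shortest round-trip float representation.
    """
    ds.data.to_csv(path, index=False, na_rep="NA")
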