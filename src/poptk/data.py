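"""Event-record dataset model and CSV I/O.

Datasets follow the pharmacometrics event-record convention: one row per
dose or observation, identified by EVID (1 = dose, 0 = observation), with
MDV flagging observation rows excluded from the likelihood.  Units are fixed
throughout the package: time in hours, amounts in mg, infusion rate in mg/h,
concentration in mg/L, weight in kg, creatinine clearance in mL/min.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = (
    "ID",
    "TIME",
    "AMT",
    "RATE",
    "EVID",
    "MDV",
    "DV",
    "WT",
    "INDUCER",
    "AGE",
    "SEX",
    "CRCL",
)

COVARIATE_COLUMNS = ("WT", "INDUCER", "AGE", "SEX", "CRCL")


class DatasetFormatError(ValueError):
    """Malformed file: missing columns or unparseable cells."""


class DatasetValidationError(ValueError):
    """Structurally valid file that violates dataset invariants."""


@dataclass(frozen=True)
class EventRecord:
    """A single dose or observation row."""

    subject_id: object
    time: float
    evid: int
    mdv: int
    amt: float = 0.0
    rate: float = 0.0
    dv: float = float("nan")
    wt: float = float("nan")
    inducer: int = 0
    age: float = float("nan")
    sex: int = 0
    crcl: float = float("nan")


@dataclass(frozen=True)
class PKDataset:
    """Validated event-record dataset wrapping a pandas DataFrame.

    Rows are ordered by subject then time.  Extra columns are preserved but
    ignored by all computations.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        validate_dataframe(self.df)

    @property
    def subject_ids(self) -> list:
        return list(self.df["ID"].drop_duplicates())

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    @property
    def n_obs(self) -> int:
        d = self.df
        return int(((d["EVID"] == 0) & (d["MDV"] == 0)).sum())

    @property
    def observations(self) -> pd.DataFrame:
        d = self.df
        return d[(d["EVID"] == 0) & (d["MDV"] == 0)]

    def subject(self, subject_id) -> pd.DataFrame:
        return self.df[self.df["ID"] == subject_id]

    def iter_subjects(self) -> Iterator[tuple[object, pd.DataFrame]]:
        for sid, grp in self.df.groupby("ID", sort=False):
            yield sid, grp

    def covariates(self) -> pd.DataFrame:
        """One row per subject with the (time-constant) covariate columns."""
        return (
            self.df.groupby("ID", sort=False)[list(COVARIATE_COLUMNS)]
            .first()
            .reset_index()
        )

    def records(self) -> list[EventRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            out.append(
                EventRecord(
                    subject_id=row.ID,
                    time=float(row.TIME),
                    evid=int(row.EVID),
                    mdv=int(row.MDV),
                    amt=0.0 if pd.isna(row.AMT) else float(row.AMT),
                    rate=0.0 if pd.isna(row.RATE) else float(row.RATE),
                    dv=float("nan") if pd.isna(row.DV) else float(row.DV),
                    wt=float(row.WT),
                    inducer=int(row.INDUCER),
                    age=float(row.AGE),
                    sex=int(row.SEX),
                    crcl=float(row.CRCL),
                )
            )
        return out


def validate_dataframe(df: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise DatasetFormatError(f"missing required column {col!r}")
    if len(df) == 0:
        raise DatasetValidationError("dataset has no rows")
    if (df["TIME"] < 0).any():
        raise DatasetValidationError("negative TIME values")
    if (df["WT"] <= 0).any():
        raise DatasetValidationError("non-positive WT values")
    if not df["INDUCER"].isin([0, 1]).all():
        raise DatasetValidationError("INDUCER must be 0/1")
    if not df["EVID"].isin([0, 1]).all():
        raise DatasetValidationError("EVID must be 0/1")
    doses = df[df["EVID"] == 1]
    if (doses["AMT"].fillna(0) <= 0).any() or (doses["RATE"].fillna(0) <= 0).any():
        raise DatasetValidationError("dose rows must carry AMT > 0 and RATE > 0")
    obs = df[df["EVID"] == 0]
    if (obs["AMT"].fillna(0) != 0).any():
        raise DatasetValidationError("observation rows must not carry AMT")
    for sid, grp in df.groupby("ID", sort=False):
        if not (grp["EVID"] == 1).any():
            raise DatasetValidationError(f"subject {sid!r} has no dose row")
        if not (grp["EVID"] == 0).any():
            raise DatasetValidationError(f"subject {sid!r} has no observation row")
        t = grp["TIME"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise DatasetValidationError(f"subject {sid!r} has decreasing times")


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    mapping = {}
    for col in df.columns:
        up = str(col).strip().upper()
        mapping[col] = up if up in REQUIRED_COLUMNS else col
    return df.rename(columns=mapping)


def read_dataset(path: str | Path) -> PKDataset:
    """Read an event-record CSV (comma-separated, '.' decimal, header row).

    '.' or empty cells are parsed as missing; column names are matched
    case-insensitively; rows are re-ordered by subject then time (stable, so
    within-subject dose-before-observation ordering at equal times is kept).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, na_values=["."], skipinitialspace=True)
    df = _normalize_columns(df)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise DatasetFormatError(f"missing required column {col!r}")
    for col in ("TIME", "AMT", "RATE", "DV", "WT", "AGE", "CRCL"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in ("EVID", "MDV", "INDUCER", "SEX"):
        df[col] = pd.to_numeric(df[col], errors="raise").fillna(0).astype(int)
    order = {sid: i for i, sid in enumerate(df["ID"].drop_duplicates())}
    df = df.sort_values(
        by=["ID", "TIME"],
        key=lambda s: s.map(order) if s.name == "ID" else s,
        kind="stable",
    ).reset_index(drop=True)
    return PKDataset(df)


def write_dataset(dataset: PKDataset, path: str | Path) -> None:
    """Write the dataset in the CSV dialect :func:`read_dataset` accepts.

    Field order is fixed (required columns first, extras after) so output is
    bit-stable for identical inputs.  No rows are filtered: MDV=1 predose
    rows survive a round trip verbatim.
    """
    if len(dataset.df) == 0:
        raise DatasetValidationError("refusing to write an empty dataset")
    cols = list(REQUIRED_COLUMNS) + [
        c for c in dataset.df.columns if c not in REQUIRED_COLUMNS
    ]
    dataset.df[cols].to_csv(path, index=False, na_rep=".")


def crcl_cockcroft_gault(age: float, wt: float, scr: float, sex: int) -> float:
    """Cockcroft–Gault creatinine clearance (mL/min).

    ``sex``: 0 = male, 1 = female (0.85 factor).  ``scr`` in mg/dL.
    """
    if age <= 0 or wt <= 0:
        raise ValueError("age and weight must be positive")
    if scr <= 0:
        raise ValueError("serum creatinine must be positive")
    val = (140.0 - age) * wt / (72.0 * scr)
    return val * (0.85 if sex == 1 else 1.0)
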