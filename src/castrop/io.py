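"""Dataset ingestion and serialization.

Canonical on-disk format is CSV with the canonical column names (AL, ACD,
LT, RCA, RCP, DC, R1, R2, PIOL, sphere, cylinder, SE, VA, id, eye); XLSX is
supported read-only.  A :class:`DatasetSchema` maps arbitrary source column
names and unit declarations onto the canonical schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import SchemaError

__all__ = ["DatasetSchema", "ValidationReport", "read_dataset", "write_dataset",
           "load_schema"]

CANONICAL_COLUMNS = (
    "AL", "ACD", "LT", "RCA", "RCP", "DC", "R1", "R2",
    "PIOL", "sphere", "cylinder", "SE", "VA", "id", "eye",
)
_VALID_UNITS = {"mm", "dpt", "decimal", "logmar", "none"}

#: Columns any formula under test could need; presence is checked when
#: ``required`` is requested at read time.
_DEFAULT_REQUIRED = ("AL", "ACD", "LT", "RCA")


@dataclass
class DatasetSchema:
    """Column-name mapping (canonical -> source) and unit declarations."""

    columns: dict[str, str] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        bad_units = set(self.units.values()) - _VALID_UNITS
        if bad_units:
            raise SchemaError(f"invalid unit declarations: {sorted(bad_units)}")
        unknown = set(self.columns) - set(CANONICAL_COLUMNS)
        if unknown:
            raise SchemaError(f"unknown canonical columns: {sorted(unknown)}")

    def source_name(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


@dataclass
class ValidationReport:
    n_rows: int = 0
    n_valid: int = 0
    issues: list[str] = field(default_factory=list)
    flagged_rows: list[int] = field(default_factory=list)


def load_schema(path) -> DatasetSchema:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return DatasetSchema(columns=raw.get("columns", {}), units=raw.get("units", {}))


def _validate(df: pd.DataFrame) -> ValidationReport:
    report = ValidationReport(n_rows=len(df))
    flagged = np.zeros(len(df), dtype=bool)
    for col in _DEFAULT_REQUIRED:
        if col not in df.columns:
            continue
        vals = df[col].to_numpy(dtype=float)
        bad = ~np.isfinite(vals)
        for i in np.flatnonzero(bad):
            report.issues.append(f"row {i}: missing {col}")
        if col in ("AL", "ACD", "LT", "RCA"):
            neg = np.isfinite(vals) & (vals <= 0)
            for i in np.flatnonzero(neg):
                report.issues.append(f"row {i}: non-positive {col}")
            bad |= neg
        flagged |= bad
    if {"ACD", "AL"} <= set(df.columns):
        acd = df["ACD"].to_numpy(dtype=float)
        al = df["AL"].to_numpy(dtype=float)
        impossible = np.isfinite(acd) & np.isfinite(al) & (acd >= al)
        for i in np.flatnonzero(impossible):
            report.issues.append(f"row {i}: ACD not smaller than AL")
        flagged |= impossible
    report.flagged_rows = [int(i) for i in np.flatnonzero(flagged)]
    report.n_valid = int((~flagged).sum())
    return report


def read_dataset(path, schema: DatasetSchema | None = None,
                 required=_DEFAULT_REQUIRED):
    """Read a CSV/XLSX biometry dataset.

    Returns ``(DataFrame, ValidationReport)``: columns renamed to the
    canonical schema, numeric columns coerced, rows violating the record
    invariants flagged (not dropped).  Raises :class:`SchemaError` if a
    required column cannot be mapped.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    schema = schema or DatasetSchema()

    rename = {}
    for canonical in CANONICAL_COLUMNS:
        src = schema.source_name(canonical)
        if src in df.columns:
            rename[src] = canonical
    df = df.rename(columns=rename)

    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"required columns not mapped: {missing}")

    for col in df.columns:
        if col in ("id", "eye"):
            continue
        df[col] = pd.to_numeric(df[col], errors="coerce")

    # unit conversions at ingest: only VA may arrive on a logMAR scale
    if schema.units.get("VA") == "logmar" and "VA" in df.columns:
        df["VA"] = np.power(10.0, -df["VA"].to_numpy(dtype=float))

    return df, _validate(df)


def write_dataset(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
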