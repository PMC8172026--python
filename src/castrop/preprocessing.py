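"""Derived quantities and record filtering for biometry outcome datasets.

Mirrors the standard preprocessing of an IOL-constant optimization study:
spherical equivalent from sphere/cylinder, mean keratometry from the flat
and steep meridians, the Cooke sum-of-segments axial-length correction, and
quality filtering (visual-acuity threshold, completeness per formula).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import BiometryDomainError

__all__ = [
    "spherical_equivalent",
    "mean_corneal_radius",
    "cooke_axial_length_correction",
    "DEFAULT_COOKE_COEFFICIENTS",
    "filter_records",
    "FilterReport",
    "preprocess",
]

#: Cooke & Cooke (2019) modified axial length (CMAL) regression: an affine
#: map of the traditionally composed optical axial length and the lens
#: thickness approximating a sum-of-segments measurement.  Kept in config
#: form so alternative coefficient sets can be supplied.
DEFAULT_COOKE_COEFFICIENTS = {"intercept": 1.23853, "al": 0.95855, "lt": -0.05467}


def spherical_equivalent(sphere, cylinder):
    """SE = sphere + cylinder/2 (dpt)."""
    return np.asarray(sphere, dtype=float) + np.asarray(cylinder, dtype=float) / 2.0


def mean_corneal_radius(r1, r2):
    """Mean anterior corneal radius R_CA = (R1 + R2)/2 in mm."""
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any(r1 <= 0) or np.any(r2 <= 0):
        raise BiometryDomainError("corneal radii must be positive")
    out = (r1 + r2) / 2.0
    return out.item() if out.ndim == 0 else out


def cooke_axial_length_correction(al, lt, coefficients=None, enabled=True):
    """Cooke-corrected (modified) axial length in mm.

    ``CMAL = c0 + c1*AL + c2*LT`` with c1 > 0 and c2 < 0: the correction is
    strictly increasing in the measured axial length and decreasing in lens
    thickness.  ``enabled=False`` returns the input unchanged.
    """
    al = np.asarray(al, dtype=float)
    if not enabled:
        return al.item() if al.ndim == 0 else al.copy()
    c = DEFAULT_COOKE_COEFFICIENTS if coefficients is None else coefficients
    out = c["intercept"] + c["al"] * al + c["lt"] * np.asarray(lt, dtype=float)
    return out.item() if out.ndim == 0 else out


@dataclass
class FilterReport:
    """Counts of removed records by (single, first-matching) reason."""

    n_input: int = 0
    n_retained: int = 0
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


def filter_records(
    df: pd.DataFrame,
    va_min: float = 0.6,
    require_complete: bool = True,
    required_columns: tuple[str, ...] = ("AL", "ACD", "LT", "RCA", "PIOL", "SE"),
) -> tuple[pd.DataFrame, FilterReport]:
    """Retain records suitable for constant optimization.

    A record is removed when its decimal visual acuity is below ``va_min``
    (unreliable postoperative refraction) or, with ``require_complete``,
    when any field needed by the formulae under test is missing.  Each
    removed record is charged to exactly one reason (VA first, then the
    first missing field), so the reasons partition the removed set.  An
    empty result warns rather than raises.
    """
    report = FilterReport(n_input=len(df))
    keep = np.ones(len(df), dtype=bool)
    reasons = pd.Series([""] * len(df), index=df.index)

    if "VA" in df.columns and va_min > 0:
        va_bad = df["VA"].to_numpy(dtype=float) < va_min
        va_bad = va_bad & keep
        reasons[va_bad] = "VA below minimum"
        keep &= ~va_bad

    if require_complete:
        for col in required_columns:
            if col not in df.columns:
                missing = keep.copy()
            else:
                missing = keep & ~np.isfinite(df[col].to_numpy(dtype=float))
            reasons[missing] = f"missing {col}"
            keep &= ~missing

    removed = reasons[~keep]
    report.removed = removed.value_counts().to_dict()
    report.n_retained = int(keep.sum())
    if report.n_retained == 0:
        import warnings

        warnings.warn("all records removed by filtering", stacklevel=2)
    return df.loc[keep].copy(), report


def preprocess(
    df: pd.DataFrame,
    va_min: float = 0.6,
    apply_cooke: bool = True,
    cooke_coefficients=None,
    require_complete: bool = True,
) -> tuple[pd.DataFrame, FilterReport]:
    """Full preprocessing chain on a raw dataset.

    Computes SE from sphere/cylinder and RCA from R1/R2 where absent,
    applies the Cooke axial-length correction (globally, i.e. the corrected
    AL feeds every formula) and filters unreliable/incomplete records.
    """
    df = df.copy()
    if "SE" not in df.columns and {"sphere", "cylinder"} <= set(df.columns):
        df["SE"] = spherical_equivalent(df["sphere"], df["cylinder"])
    if "RCA" not in df.columns and {"R1", "R2"} <= set(df.columns):
        df["RCA"] = mean_corneal_radius(df["R1"], df["R2"])
    if apply_cooke and "LT" in df.columns:
        df["AL"] = cooke_axial_length_correction(
            df["AL"], df["LT"], coefficients=cooke_coefficients
        )
    return filter_records(df, va_min=va_min, require_complete=require_complete)
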