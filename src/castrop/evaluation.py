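"""Cross-validated formula benchmarking.

Protocol: split the dataset into a training part (constant optimization)
and a test part (validation); for each formula report descriptive
statistics of the prediction error PE = SE - predSE and of |PE|, the
fraction of eyes within standard absolute-error limits, a composite
formula performance index, and paired signed-rank comparisons of |PE|
against a reference formula with Bonferroni correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .formulas import IOLFormula, make_formula
from .optimize import prediction_error, rms_pe

__all__ = [
    "train_test_split",
    "SummaryStats",
    "PEReport",
    "summarize",
    "summarize_pe",
    "within_limits",
    "cumulative_curve",
    "robust_slope_pe_vs_al",
    "formula_performance_index",
    "paired_wilcoxon_abspe",
    "evaluate_formulas",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (0.25, 0.5, 1.0, 2.0)

#: Weights of the formula performance index terms (spread of PE, median
#: absolute PE, |axial-length bias slope|, shortfall of the within-0.5 dpt
#: fraction).  The index is the reciprocal of the weighted sum, so smaller
#: error components score higher.
FPI_WEIGHTS = {"sd": 1.0, "medae": 1.0, "slope": 1.0, "frac_shortfall": 0.1}


def train_test_split(df: pd.DataFrame, train_fraction: float = 0.7, seed=None):
    """Random disjoint, exhaustive split; reproducible per seed.

    The test size is ``floor((1 - fraction) * N)`` and the training set the
    remainder (e.g. N = 1452 at 70% gives 1017 / 435).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(df)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_test = math.floor((1.0 - train_fraction) * n)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return df.iloc[train_idx].copy(), df.iloc[test_idx].copy()


@dataclass
class SummaryStats:
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    q05: float
    q95: float


def summarize(values) -> SummaryStats:
    """Descriptive statistics with type-7 (linear-interpolation) quantiles."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty vector")
    return SummaryStats(
        n=int(v.size),
        mean=float(np.mean(v)),
        sd=float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
        median=float(np.median(v)),
        min=float(np.min(v)),
        max=float(np.max(v)),
        q05=float(np.quantile(v, 0.05)),
        q95=float(np.quantile(v, 0.95)),
    )


@dataclass
class PEReport:
    """Prediction-error report for one formula on one dataset."""

    formula: str
    pe: SummaryStats
    abs_pe: SummaryStats
    fractions: dict[float, float]
    rms_pe: float
    fpi: float | None = None
    wilcoxon_p: float | None = None
    wilcoxon_p_bonferroni: float | None = None
    constants: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {"formula": self.formula, "n": self.pe.n, "rmsPE": self.rms_pe}
        for tag, s in (("PE", self.pe), ("absPE", self.abs_pe)):
            for f in ("mean", "sd", "median", "min", "max", "q05", "q95"):
                row[f"{tag}_{f}"] = getattr(s, f)
        for t, frac in self.fractions.items():
            row[f"within_{t}"] = frac
        row["FPI"] = self.fpi
        row["p_vs_reference"] = self.wilcoxon_p
        row["p_vs_reference_bonferroni"] = self.wilcoxon_p_bonferroni
        for k, v in self.constants.items():
            row[f"const_{k}"] = v
        return row


def summarize_pe(pe, formula: str = "", thresholds=DEFAULT_THRESHOLDS) -> PEReport:
    pe = np.asarray(pe, dtype=float)
    abspe = np.abs(pe)
    return PEReport(
        formula=formula,
        pe=summarize(pe),
        abs_pe=summarize(abspe),
        fractions=within_limits(abspe, thresholds),
        rms_pe=rms_pe(pe),
    )


def within_limits(abs_pe, thresholds=DEFAULT_THRESHOLDS) -> dict[float, float]:
    """Fraction of cases with |PE| <= each threshold (dpt)."""
    abspe = np.asarray(abs_pe, dtype=float)
    return {float(t): float(np.mean(abspe <= t)) for t in thresholds}


def cumulative_curve(abs_pe):
    """Empirical CDF of |PE|: sorted values and cumulative fractions."""
    x = np.sort(np.asarray(abs_pe, dtype=float))
    y = np.arange(1, x.size + 1) / x.size
    return x, y


def robust_slope_pe_vs_al(pe, al, cutoff: float = 2.0) -> float:
    """Slope (dpt/mm) of PE on axial length, robust to gross outliers.

    An ordinary least-squares line is fitted, points whose externally
    Studentized residual exceeds ``cutoff`` in magnitude are discarded, and
    the line is refitted on the retained points.
    """
    pe = np.asarray(pe, dtype=float)
    al = np.asarray(al, dtype=float)
    if pe.size != al.size or pe.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.ptp(al) == 0:
        raise ValueError("degenerate axial-length variance")
    X = sm.add_constant(al)
    fit = sm.OLS(pe, X).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        student = fit.get_influence().resid_studentized_external
    # a perfect fit has zero residual variance; treat those points as inliers
    keep = ~(np.abs(np.nan_to_num(student)) > cutoff)
    if keep.sum() < 3 or np.ptp(al[keep]) == 0:
        keep = np.ones_like(keep, dtype=bool)
    refit = sm.OLS(pe[keep], sm.add_constant(al[keep])).fit()
    return float(refit.params[1])


def formula_performance_index(pe, al, cutoff: float = 2.0, weights=None) -> float:
    """Composite formula performance index (higher is better).

    Reciprocal of the weighted sum of four error components: sd(PE), the
    median |PE|, the magnitude of the robust PE-vs-AL slope, and one tenth
    of the shortfall of the within-±0.5 dpt fraction.
    """
    w = FPI_WEIGHTS if weights is None else weights
    pe = np.asarray(pe, dtype=float)
    abspe = np.abs(pe)
    sd = float(np.std(pe, ddof=1))
    medae = float(np.median(abspe))
    slope = abs(robust_slope_pe_vs_al(pe, al, cutoff=cutoff))
    frac05 = float(np.mean(abspe <= 0.5))
    denom = (
        w["sd"] * sd
        + w["medae"] * medae
        + w["slope"] * slope
        + w["frac_shortfall"] * (1.0 - frac05)
    )
    return 1.0 / denom


def paired_wilcoxon_abspe(a, b, m_comparisons: int = 1):
    """Two-sided Wilcoxon signed-rank test on paired |PE| vectors.

    Zero differences are discarded (classic convention); the exact null
    distribution is used for n <= 25 without ties, the normal approximation
    with continuity correction otherwise.  Returns (statistic, p,
    Bonferroni-adjusted p = min(1, m*p)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        return 0.0, 1.0, 1.0
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not has_ties) else "approx"
    res = scipy.stats.wilcoxon(
        a, b, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    p = float(res.pvalue)
    return float(res.statistic), p, min(1.0, m_comparisons * p)


def evaluate_formulas(
    df: pd.DataFrame,
    formulas: dict[str, IOLFormula] | list[str] | None = None,
    train_fraction: float = 0.7,
    seed=None,
    thresholds=DEFAULT_THRESHOLDS,
    reference: str = "castrop",
) -> tuple[pd.DataFrame, dict[str, PEReport]]:
    """Run the full cross-validated comparison protocol.

    Splits ``df``, optimises every formula's constants on the training
    part, computes PE on the test part, and assembles per-formula reports
    including the performance index and signed-rank comparisons of |PE|
    against the reference formula (Bonferroni-corrected over the number of
    comparisons).  Returns (summary table, reports by tag).
    """
    if formulas is None:
        formulas = ["srkt", "hofferq", "holladay1", "haigis", "haigis3", "castrop"]
    if isinstance(formulas, list):
        formulas = {tag: make_formula(tag) for tag in formulas}

    train, test = train_test_split(df, train_fraction=train_fraction, seed=seed)
    y_train = train["SE"].to_numpy(dtype=float)
    y_test = test["SE"].to_numpy(dtype=float)
    al_test = test["AL"].to_numpy(dtype=float)

    pes: dict[str, np.ndarray] = {}
    reports: dict[str, PEReport] = {}
    for tag, est in formulas.items():
        est.fit(train, y_train)
        pe = prediction_error(y_test, est.predict(test))
        pes[tag] = pe
        report = summarize_pe(pe, formula=tag, thresholds=thresholds)
        report.fpi = formula_performance_index(pe, al_test)
        report.constants = {
            name: float(getattr(est, f"{name}_")) for name in est._free_params
        }
        reports[tag] = report

    if reference in pes:
        m = len(pes) - 1
        for tag, pe in pes.items():
            if tag == reference:
                continue
            _, p, p_adj = paired_wilcoxon_abspe(
                np.abs(pe), np.abs(pes[reference]), m_comparisons=m
            )
            reports[tag].wilcoxon_p = p
            reports[tag].wilcoxon_p_bonferroni = p_adj

    table = pd.DataFrame([reports[tag].as_row() for tag in formulas])
    return table, reports
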