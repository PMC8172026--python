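"""Synthetic biometry and outcome datasets for a cataract population.

The generator emulates the descriptive structure of a routine cataract
cohort measured with a swept-source biometer: correlated axial length,
anterior chamber depth, lens thickness and mean corneal radius drawn from a
box-truncated multivariate Gaussian, keratometry split into flat/steep
meridians, pachymetry, and a decimal visual acuity.  Outcomes close the
loop through the Castrop forward model: each eye receives the exact power
for its target refraction computed with a known true constant triplet,
rounded to the manufacturing power step, and its achieved refraction is the
model prediction for the rounded power plus measurement noise (optionally
quantized to clinical 0.25 dpt refraction steps).

Because the generating constants are known, parameter-recovery experiments
have a ground truth: with zero noise and no rounding, the prediction error
of the true constants is identically zero on the generated data.

The latent Gaussian is calibrated per variable so that the *truncated*
marginal reproduces the requested mean and SD (plain truncation of the
nominal moments would bias both); see :func:`_calibrate_truncnorm`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from . import optics
from .model_eye import DEFAULT_EYE, CastropConstants, ModelEye

__all__ = ["GeneratorSpec", "generate_biometry", "assign_iol_and_refraction",
           "generate_dataset", "TABLE_MOMENTS"]

#: Default population moments and ranges per biometric variable (mm):
#: a routine European cataract cohort (N ~ 1450) measured with an
#: IOLMaster 700, axial length Cooke-corrected.
TABLE_MOMENTS = {
    "AL": {"mean": 23.497, "sd": 1.082, "min": 20.635, "max": 29.041},
    "ACD": {"mean": 3.099, "sd": 0.389, "min": 2.000, "max": 4.354},
    "LT": {"mean": 4.608, "sd": 0.422, "min": 3.345, "max": 5.794},
    "RCA": {"mean": 7.668, "sd": 0.271, "min": 6.671, "max": 8.676},
}

_VARS = ("AL", "ACD", "LT", "RCA")

#: Plausible biometric correlation structure (longer eyes have deeper
#: chambers, flatter corneas and thinner lenses; deeper chambers thinner
#: lenses).  Configurable; the true population values are unknown.
DEFAULT_CORRELATIONS = {
    ("AL", "ACD"): 0.45,
    ("AL", "RCA"): 0.35,
    ("AL", "LT"): -0.25,
    ("ACD", "LT"): -0.45,
}


@dataclass
class GeneratorSpec:
    """Configuration of the synthetic-population generator."""

    n: int = 1452
    seed: int | None = None
    moments: dict = field(default_factory=lambda: {k: dict(v) for k, v in TABLE_MOMENTS.items()})
    correlations: dict = field(default_factory=lambda: dict(DEFAULT_CORRELATIONS))
    true_constants: CastropConstants = CastropConstants(0.424, -0.312, 0.077)
    refraction_noise_sd: float = 0.45
    iol_power_step: float = 0.5
    #: (weight, mean, sd) components of the target-refraction mixture:
    #: mostly near-emmetropia targets with a minority of ~-2 dpt myopic
    #: targets, giving the negatively skewed outcome distribution typical
    #: of cataract cohorts.
    target_mixture: tuple = ((0.8, -0.25, 0.25), (0.2, -2.0, 0.35))
    quantize_refraction: bool = True
    refraction_step: float = 0.25
    astigmatism_mean: float = 0.12  # mm radius difference R1 - R2
    astigmatism_sd: float = 0.08
    dc_mean: float = 0.55
    dc_sd: float = 0.035
    va_mean: float = 0.95
    va_sd: float = 0.2
    eye: ModelEye = DEFAULT_EYE

    def correlation_matrix(self) -> np.ndarray:
        m = np.eye(len(_VARS))
        for (a, b), rho in self.correlations.items():
            i, j = _VARS.index(a), _VARS.index(b)
            m[i, j] = m[j, i] = rho
        return m


def _calibrate_truncnorm(mean, sd, lo, hi):
    """Latent (mu, sigma) whose [lo, hi]-truncated normal has the target moments.

    Solved with a Newton-type root finder on the analytic truncated-normal
    mean/SD; truncation both shifts the mean (asymmetric bounds) and
    shrinks the SD, so the latent parameters differ slightly from the
    targets.
    """

    def moments(params):
        mu, sig = params
        sig = abs(sig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = scipy.stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return np.array([m - mean, np.sqrt(v) - sd])

    sol = scipy.optimize.fsolve(moments, x0=np.array([mean, sd]), full_output=False)
    mu, sig = float(sol[0]), abs(float(sol[1]))
    return mu, sig


def generate_biometry(spec: GeneratorSpec) -> pd.DataFrame:
    """Draw ``spec.n`` biometry records from the truncated Gaussian model.

    Returns a DataFrame with columns AL, ACD, LT, RCA, R1, R2, DC, VA (mm /
    decimal).  The posterior corneal radius is left unmeasured (the
    model-eye fallback applies downstream).  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    mus, sigs, los, his = [], [], [], []
    for v in _VARS:
        m = spec.moments[v]
        if not m["min"] < m["max"]:
            raise ValueError(f"empty truncation region for {v}")
        mu, sig = _calibrate_truncnorm(m["mean"], m["sd"], m["min"], m["max"])
        mus.append(mu)
        sigs.append(sig)
        los.append(m["min"])
        his.append(m["max"])
    mus = np.array(mus)
    sigs = np.array(sigs)
    los = np.array(los)
    his = np.array(his)
    corr = spec.correlation_matrix()
    # require positive definiteness up front rather than failing in Cholesky
    if np.min(np.linalg.eigvalsh(corr)) <= 0:
        raise ValueError("correlation matrix is not positive definite")
    cov = corr * np.outer(sigs, sigs)
    chol = np.linalg.cholesky(cov)

    rows = np.empty((0, len(_VARS)))
    attempts = 0
    while rows.shape[0] < spec.n:
        attempts += 1
        if attempts > 1000:
            raise ValueError("truncation region rejects essentially all draws")
        z = rng.standard_normal((max(2 * spec.n, 1000), len(_VARS)))
        draw = mus + z @ chol.T
        ok = np.all((draw >= los) & (draw <= his), axis=1)
        rows = np.vstack([rows, draw[ok]])
    rows = rows[: spec.n]

    df = pd.DataFrame(rows, columns=list(_VARS))
    # flat/steep meridian split around the mean radius
    astig = np.abs(rng.normal(spec.astigmatism_mean, spec.astigmatism_sd, spec.n))
    df["R1"] = df["RCA"] + astig / 2.0
    df["R2"] = df["RCA"] - astig / 2.0
    df["DC"] = np.clip(rng.normal(spec.dc_mean, spec.dc_sd, spec.n), 0.4, 0.7)
    df["VA"] = np.clip(
        np.round(rng.normal(spec.va_mean, spec.va_sd, spec.n), 1), 0.1, 1.6
    )
    return df


def _draw_targets(rng, mixture, n):
    weights = np.array([w for w, _, _ in mixture], dtype=float)
    weights = weights / weights.sum()
    comp = rng.choice(len(mixture), size=n, p=weights)
    means = np.array([m for _, m, _ in mixture])
    sds = np.array([s for _, _, s in mixture])
    return rng.normal(means[comp], sds[comp])


def assign_iol_and_refraction(df: pd.DataFrame, spec: GeneratorSpec) -> pd.DataFrame:
    """Close the loop: implanted power and achieved refraction per record.

    The exact Castrop power for each eye's target refraction (true
    constants) is rounded to the labelled power step; the achieved SE is
    the model's prediction for the rounded power plus Gaussian refraction
    noise, optionally quantized to 0.25 dpt via sphere/cylinder components.
    """
    # independent stream so biometry draws are unchanged by outcome settings
    rng = np.random.default_rng(None if spec.seed is None else spec.seed + 1)
    df = df.copy()
    n = len(df)
    k = spec.true_constants
    target = _draw_targets(rng, spec.target_mixture, n)

    p_exact = optics.castrop_iol_power(
        df["AL"], df["ACD"], df["LT"], df["RCA"], k, spec.eye,
        dc=df["DC"] if "DC" in df else None, target_se=target,
    )
    if spec.iol_power_step > 0:
        p_iol = np.round(p_exact / spec.iol_power_step) * spec.iol_power_step
    else:
        p_iol = np.asarray(p_exact, dtype=float)
    df["PIOL"] = p_iol
    df["target_SE"] = target

    achieved = optics.castrop_predicted_refraction(
        df["AL"], df["ACD"], df["LT"], df["RCA"], k, spec.eye,
        dc=df["DC"] if "DC" in df else None, p_iol=p_iol,
    )
    achieved = achieved + rng.normal(0.0, spec.refraction_noise_sd, n)

    if spec.quantize_refraction:
        step = spec.refraction_step
        cylinder = -np.round(np.abs(rng.normal(0.0, 0.3, n)) / step) * step
        sphere = np.round((achieved - cylinder / 2.0) / step) * step
    else:
        cylinder = np.zeros(n)
        sphere = achieved
    df["cylinder"] = cylinder
    df["sphere"] = sphere
    df["SE"] = df["sphere"] + df["cylinder"] / 2.0
    return df


def generate_dataset(spec: GeneratorSpec | None = None, **overrides) -> pd.DataFrame:
    """Biometry plus outcomes in one call; ``overrides`` patch the spec."""
    spec = GeneratorSpec() if spec is None else spec
    if overrides:
        spec = replace(spec, **overrides)
    return assign_iol_and_refraction(generate_biometry(spec), spec)
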