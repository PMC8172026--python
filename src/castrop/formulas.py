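"""IOL power formulae as scikit-learn style estimators.

Six formulae share one interface: the Castrop thick-cornea vergence formula
and five classical comparators (SRK/T, Hoffer Q, Holladay 1, simplified
Haigis with one constant, Haigis with the full triplet).  Each estimator

* predicts the postoperative spherical-equivalent refraction for an
  implanted power (``predict`` / ``predict_refraction``),
* computes the power for a target refraction (``iol_power``), the exact
  algebraic inverse of the refraction form, and
* optimises its formula constants on outcome data (``fit``) by minimising
  the root-mean-squared refraction prediction error with a projected
  Levenberg-Marquardt solver (see :mod:`castrop.optimize`).

Input is a DataFrame with the canonical biometry columns (mm / dioptres):
``AL`` axial length, ``ACD`` external anterior chamber depth, ``LT`` lens
thickness, ``RCA`` mean anterior corneal radius, optionally ``RCP`` and
``DC`` (posterior radius / pachymetry, Castrop only), and ``PIOL`` the
implanted power when predicting refraction.

Keratometric conventions are deliberately per-formula and not shared:
formula constants are only transferable together with their native
keratometry index.  SRK/T and Hoffer Q read keratometry as K = 337.5/r
(index 1.3375), Holladay 1 works on the radius with a corneal index of 4/3,
Haigis uses 331.5/r (index 1.3315), and Castrop models the cornea as a
thick meniscus with physical indices 1.376/1.336.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from . import optics
from .exceptions import BiometryDomainError
from .model_eye import (
    C_BOUNDS,
    DEFAULT_EYE,
    H_BOUNDS,
    R_BOUNDS,
    CastropConstants,
    ModelEye,
)

__all__ = [
    "IOLFormula",
    "CastropFormula",
    "SRKTFormula",
    "HofferQFormula",
    "Holladay1Formula",
    "HaigisFormula",
    "FORMULA_REGISTRY",
    "make_formula",
    "haigis_elp",
    "srkt_predicted_refraction",
    "hofferq_predicted_refraction",
    "holladay1_predicted_refraction",
    "haigis_predicted_refraction",
    "predicted_refraction",
    "iol_power",
]

_VERTEX_MM = 12.0  # spectacle vertex distance used by the classical formulae


def _col(X, name):
    try:
        return np.asarray(X[name], dtype=float)
    except KeyError as exc:
        raise BiometryDomainError(f"missing required biometry column {name!r}") from exc


def _spectacle_to_cornea(rx, vertex_mm=_VERTEX_MM):
    """Refraction at the corneal plane from the spectacle-plane value."""
    return rx / (1.0 - vertex_mm * 1e-3 * rx)


def _cornea_to_spectacle(rc, vertex_mm=_VERTEX_MM):
    return rc / (1.0 + vertex_mm * 1e-3 * rc)


# ---------------------------------------------------------------------------
# Shared thin-IOL vergence solution used by SRK/T and Holladay 1.
#
# With optical axial length L, predicted lens plane C, corneal radius r (all
# mm), aqueous index na and reduced corneal index ncm1 = nc - 1, both
# publications write the refraction for an implanted power P as the ratio of
# two expressions linear in P:
#
#   REF(P) = (A - P*B) / (D - 0.001*P*E)
#
#   A = 1000*na*(na*r - ncm1*L)
#   B = (L - C)*(na*r - ncm1*C)
#   D = na*(V*(na*r - ncm1*L) + L*r)
#   E = (L - C)*(V*(na*r - ncm1*C) + C*r)
#
# which inverts in closed form to P(REF) = (A - REF*D) / (B - 0.001*REF*E).
# ---------------------------------------------------------------------------


def _thin_iol_terms(L, C, r, na, ncm1, vertex=_VERTEX_MM):
    A = 1000.0 * na * (na * r - ncm1 * L)
    B = (L - C) * (na * r - ncm1 * C)
    D = na * (vertex * (na * r - ncm1 * L) + L * r)
    E = (L - C) * (vertex * (na * r - ncm1 * C) + C * r)
    return A, B, D, E


def _thin_iol_refraction(p_iol, L, C, r, na, ncm1):
    A, B, D, E = _thin_iol_terms(L, C, r, na, ncm1)
    return (A - p_iol * B) / (D - 0.001 * p_iol * E)


def _thin_iol_power(ref, L, C, r, na, ncm1):
    A, B, D, E = _thin_iol_terms(L, C, r, na, ncm1)
    return (A - ref * D) / (B - 0.001 * ref * E)


# ---------------------------------------------------------------------------
# SRK/T
# ---------------------------------------------------------------------------


def _srkt_elp_and_lopt(al, rca, a_constant):
    """SRK/T predicted lens plane and retina-corrected axial length."""
    al = np.asarray(al, dtype=float)
    rca = np.asarray(rca, dtype=float)
    k = 337.5 / rca
    # Long-eye correction of the axial length used in the corneal-width fit.
    lcor = np.where(al > 24.2, -3.446 + 1.716 * al - 0.0237 * al**2, al)
    cw = -5.41 + 0.58412 * lcor + 0.098 * k
    sq = rca**2 - cw**2 / 4.0
    if np.any(sq < 0):
        raise BiometryDomainError(
            "SRK/T corneal height: corneal width exceeds corneal diameter "
            "(negative square-root argument)"
        )
    h_cornea = rca - np.sqrt(sq)
    acd_const = 0.62467 * a_constant - 68.747
    elp = h_cornea + (acd_const - 3.336)
    rethick = 0.65696 - 0.02029 * al
    lopt = al + rethick
    return elp, lopt


def srkt_predicted_refraction(al, rca, p_iol, a_constant):
    """SRK/T refraction prediction (A-constant; retinal thickness and
    corneal height per the original regression sub-formulae)."""
    elp, lopt = _srkt_elp_and_lopt(al, rca, a_constant)
    return _thin_iol_refraction(p_iol, lopt, elp, np.asarray(rca, float), 1.336, 0.333)


def srkt_iol_power(al, rca, target_se, a_constant):
    elp, lopt = _srkt_elp_and_lopt(al, rca, a_constant)
    return _thin_iol_power(target_se, lopt, elp, np.asarray(rca, float), 1.336, 0.333)


# ---------------------------------------------------------------------------
# Hoffer Q
# ---------------------------------------------------------------------------


def _hofferq_elp(al, rca, pacd):
    """Hoffer Q personalised ACD with the errata-corrected tangent terms.

    Axial length is clamped to 18.5-31 mm inside the ACD prediction; the
    tangent arguments are in degrees.
    """
    al = np.asarray(al, dtype=float)
    k = 337.5 / np.asarray(rca, dtype=float)
    m = np.where(al <= 23.0, 1.0, -1.0)
    g = np.where(al <= 23.0, 28.0, 23.5)
    alc = np.clip(al, 18.5, 31.0)
    tan = lambda deg: np.tan(np.deg2rad(deg))  # noqa: E731
    acd = (
        pacd
        + 0.3 * (alc - 23.5)
        + tan(k) ** 2
        + 0.1 * m * (23.5 - alc) ** 2 * tan(0.1 * (g - alc) ** 2)
        - 0.99166
    )
    return acd, k


def hofferq_predicted_refraction(al, acd_unused, rca, p_iol, pacd):
    """Hoffer Q refraction prediction.

    The formula predicts its own chamber depth from AL and K; the measured
    ACD is not used (kept in the signature for interface symmetry).
    """
    al = np.asarray(al, dtype=float)
    elp, k = _hofferq_elp(al, rca, pacd)
    # 1336/(AL - ACD - 0.05) is the required corneal-plane system vergence.
    with np.errstate(divide="ignore"):
        rc = 1.336 / ((elp + 0.05) / 1000.0 + 1.336 / (1336.0 / (al - elp - 0.05) - p_iol)) - k
    return _cornea_to_spectacle(rc)


def hofferq_iol_power(al, rca, target_se, pacd):
    al = np.asarray(al, dtype=float)
    elp, k = _hofferq_elp(al, rca, pacd)
    rc = _spectacle_to_cornea(np.asarray(target_se, dtype=float))
    return 1336.0 / (al - elp - 0.05) - 1.336 / (
        1.336 / (k + rc) - (elp + 0.05) / 1000.0
    )


# ---------------------------------------------------------------------------
# Holladay 1
# ---------------------------------------------------------------------------


def _holladay1_elp(al, rca, sf):
    """Holladay 1 anatomical ACD (corneal height + 0.56) plus surgeon factor."""
    al = np.asarray(al, dtype=float)
    rag = np.maximum(np.asarray(rca, dtype=float), 7.0)
    ag = np.minimum(al * 12.5 / 23.45, 13.5)
    sq = rag**2 - ag**2 / 4.0
    if np.any(sq < 0):
        raise BiometryDomainError(
            "Holladay 1 corneal height: negative square-root argument"
        )
    acd_anat = 0.56 + rag - np.sqrt(sq)
    return acd_anat + sf


def holladay1_predicted_refraction(al, rca, p_iol, sf):
    elp = _holladay1_elp(al, rca, sf)
    alm = np.asarray(al, dtype=float) + 0.2
    return _thin_iol_refraction(p_iol, alm, elp, np.asarray(rca, float), 1.336, 1.0 / 3.0)


def holladay1_iol_power(al, rca, target_se, sf):
    elp = _holladay1_elp(al, rca, sf)
    alm = np.asarray(al, dtype=float) + 0.2
    return _thin_iol_power(target_se, alm, elp, np.asarray(rca, float), 1.336, 1.0 / 3.0)


# ---------------------------------------------------------------------------
# Haigis
# ---------------------------------------------------------------------------


def haigis_elp(acd, al, a0, a1=0.4, a2=0.1):
    """Haigis lens position ``d = a0 + a1*ACD + a2*AL`` in mm.

    The simplified single-constant mode fixes a1 = 0.4 and a2 = 0.1 and
    optimises a0 only; the triplet mode optimises all three.
    """
    acd = np.asarray(acd, dtype=float)
    al = np.asarray(al, dtype=float)
    if np.any(acd <= 0) or np.any(al <= 0):
        raise BiometryDomainError("ACD and AL must be positive")
    d = a0 + a1 * acd + a2 * al
    if np.any(d >= al):
        raise BiometryDomainError("Haigis lens position reaches the retina")
    out = np.asarray(d)
    return out.item() if out.ndim == 0 else out


def haigis_predicted_refraction(al, acd, rca, p_iol, a0, a1=0.4, a2=0.1):
    """Haigis thin-cornea vergence prediction (corneal index 1.3315)."""
    al = np.asarray(al, dtype=float)
    d = haigis_elp(acd, al, a0, a1, a2)
    dc_power = 331.5 / np.asarray(rca, dtype=float)
    with np.errstate(divide="ignore"):
        z = 1336.0 / (d + 1336.0 / (1336.0 / (al - d) - p_iol))
    rc = z - dc_power
    return _cornea_to_spectacle(rc)


def haigis_iol_power(al, acd, rca, target_se, a0, a1=0.4, a2=0.1):
    al = np.asarray(al, dtype=float)
    d = haigis_elp(acd, al, a0, a1, a2)
    dc_power = 331.5 / np.asarray(rca, dtype=float)
    z = dc_power + _spectacle_to_cornea(np.asarray(target_se, dtype=float))
    return 1336.0 / (al - d) - 1336.0 / (1336.0 / z - d)


# ---------------------------------------------------------------------------
# Estimator classes
# ---------------------------------------------------------------------------


class IOLFormula(RegressorMixin, BaseEstimator):
    """Base class for IOL power formula estimators.

    Subclasses declare their tunable constants (``_free_params`` with box
    bounds ``_param_bounds``) and implement ``_refraction`` and ``_power``
    in terms of those constants.  ``fit(X, y)`` optimises the constants on
    a training set (X: biometry + implanted ``PIOL``; y: achieved
    postoperative spherical equivalent) by minimising the rmsPE; fitted
    values are exposed as ``constants_`` and per-constant ``<name>_``
    attributes, and ``predict`` uses them once present.
    """

    _free_params: tuple[str, ...] = ()
    _param_bounds: dict[str, tuple[float, float]] = {}
    required_columns: tuple[str, ...] = ("AL", "RCA")

    # -- constant bookkeeping -------------------------------------------------

    def _constant_values(self) -> dict[str, float]:
        """Current constants: fitted if available, else constructor values."""
        out = {}
        for name in self._free_params:
            out[name] = getattr(self, f"{name}_", getattr(self, name))
        return out

    # -- subclass hooks -------------------------------------------------------

    def _refraction(self, X: pd.DataFrame, consts: dict) -> np.ndarray:
        raise NotImplementedError

    def _power(self, X: pd.DataFrame, target_se, consts: dict) -> np.ndarray:
        raise NotImplementedError

    # -- public API -----------------------------------------------------------

    def predict_refraction(self, X) -> np.ndarray:
        """Predicted spherical equivalent (dpt) for the implanted ``PIOL``."""
        return np.asarray(self._refraction(X, self._constant_values()), dtype=float)

    def predict(self, X) -> np.ndarray:
        return self.predict_refraction(X)

    def iol_power(self, X, target_se=0.0) -> np.ndarray:
        """IOL power (dpt) for a target spectacle refraction."""
        return np.asarray(
            self._power(X, target_se, self._constant_values()), dtype=float
        )

    def fit(self, X, y, config=None):
        """Optimise the formula constants on outcome data.

        Parameters
        ----------
        X : DataFrame
            Biometry with the implanted power column ``PIOL``.
        y : array-like
            Achieved postoperative spherical equivalent (dpt).
        config : LMConfig, optional
            Optimizer settings; defaults to the standard configuration
            (lambda0 = 1e-2, max 100 iterations, step tol 1e-14, rmsPE
            improvement tol 1e-16).
        """
        from .optimize import LMConfig, levenberg_marquardt

        y = np.asarray(y, dtype=float)
        if isinstance(X, pd.DataFrame):
            X = X.reset_index(drop=True)
        names = self._free_params
        init = np.array([getattr(self, n) for n in names], dtype=float)
        lower = np.array([self._param_bounds[n][0] for n in names])
        upper = np.array([self._param_bounds[n][1] for n in names])
        if config is None:
            config = LMConfig(init=init, lower=lower, upper=upper)
        self._check_identifiability(X)

        def residuals(theta):
            consts = dict(zip(names, theta))
            pred = np.asarray(self._refraction(X, consts), dtype=float)
            return y - pred  # PE = SE - predSE

        result = levenberg_marquardt(residuals, config)
        self.constants_ = np.asarray(result.constants, dtype=float)
        for name, value in zip(names, self.constants_):
            setattr(self, f"{name}_", float(value))
        self.n_iter_ = result.iterations
        self.converged_by_ = result.converged_by
        self.optimization_result_ = result
        self.rms_pe_ = result.rms_pe
        return self

    def _check_identifiability(self, X) -> None:  # pragma: no cover - hook
        pass


class CastropFormula(IOLFormula):
    """Castrop thick-cornea vergence formula with constants (C, H, R).

    C places the IOL at a fraction of the crystalline lens thickness,
    H shifts the lens plane axially (mm), R offsets the predicted
    refraction (dpt).  Measured posterior corneal radius (``RCP``) and
    pachymetry (``DC``) are used when present; otherwise the model-eye
    fallbacks apply (fixed 6.4/7.77 radius ratio, 500 um thickness).
    """

    _free_params = ("c", "h", "r")
    _param_bounds = {"c": C_BOUNDS, "h": H_BOUNDS, "r": R_BOUNDS}
    required_columns = ("AL", "ACD", "LT", "RCA")

    def __init__(self, c=0.4, h=0.0, r=0.0, eye: ModelEye = DEFAULT_EYE):
        self.c = c
        self.h = h
        self.r = r
        self.eye = eye

    def _geometry(self, X):
        rcp = np.asarray(X["RCP"], dtype=float) if "RCP" in X else None
        dc = np.asarray(X["DC"], dtype=float) if "DC" in X else None
        return rcp, dc

    def _refraction(self, X, consts):
        k = CastropConstants(**consts)
        rcp, dc = self._geometry(X)
        return optics.castrop_predicted_refraction(
            _col(X, "AL"), _col(X, "ACD"), _col(X, "LT"), _col(X, "RCA"),
            k, self.eye, rcp=rcp, dc=dc, p_iol=_col(X, "PIOL"),
        )

    def _power(self, X, target_se, consts):
        k = CastropConstants(**consts)
        rcp, dc = self._geometry(X)
        return optics.castrop_iol_power(
            _col(X, "AL"), _col(X, "ACD"), _col(X, "LT"), _col(X, "RCA"),
            k, self.eye, rcp=rcp, dc=dc, target_se=target_se,
        )

    def _check_identifiability(self, X) -> None:
        # C and H act on the ELP through C*LT + H; without spread in LT the
        # pair is a ridge and only the sum is determined.
        lt = np.asarray(X["LT"], dtype=float)
        if lt.size > 1 and np.std(lt) < 0.05:
            warnings.warn(
                "lens thickness spread below 0.05 mm: C and H are poorly "
                "identifiable; consider fixing one of them",
                stacklevel=3,
            )

    @property
    def castrop_constants_(self) -> CastropConstants:
        return CastropConstants(self.c_, self.h_, self.r_)


class SRKTFormula(IOLFormula):
    """SRK/T formula, tuned by its A-constant."""

    _free_params = ("a_constant",)
    _param_bounds = {"a_constant": (110.0, 125.0)}
    required_columns = ("AL", "RCA")

    def __init__(self, a_constant=119.0):
        self.a_constant = a_constant

    def _refraction(self, X, consts):
        return srkt_predicted_refraction(
            _col(X, "AL"), _col(X, "RCA"), _col(X, "PIOL"), consts["a_constant"]
        )

    def _power(self, X, target_se, consts):
        return srkt_iol_power(
            _col(X, "AL"), _col(X, "RCA"), target_se, consts["a_constant"]
        )


class HofferQFormula(IOLFormula):
    """Hoffer Q formula, tuned by its personalised ACD (pACD, mm)."""

    _free_params = ("pacd",)
    _param_bounds = {"pacd": (2.0, 9.0)}
    required_columns = ("AL", "RCA")

    def __init__(self, pacd=5.6):
        self.pacd = pacd

    def _refraction(self, X, consts):
        return hofferq_predicted_refraction(
            _col(X, "AL"), None, _col(X, "RCA"), _col(X, "PIOL"), consts["pacd"]
        )

    def _power(self, X, target_se, consts):
        return hofferq_iol_power(
            _col(X, "AL"), _col(X, "RCA"), target_se, consts["pacd"]
        )


class Holladay1Formula(IOLFormula):
    """Holladay 1 formula, tuned by its surgeon factor (SF, mm)."""

    _free_params = ("sf",)
    _param_bounds = {"sf": (-2.0, 5.0)}
    required_columns = ("AL", "RCA")

    def __init__(self, sf=1.8):
        self.sf = sf

    def _refraction(self, X, consts):
        return holladay1_predicted_refraction(
            _col(X, "AL"), _col(X, "RCA"), _col(X, "PIOL"), consts["sf"]
        )

    def _power(self, X, target_se, consts):
        return holladay1_iol_power(
            _col(X, "AL"), _col(X, "RCA"), target_se, consts["sf"]
        )


class HaigisFormula(IOLFormula):
    """Haigis formula, ``d = a0 + a1*ACD + a2*AL``.

    ``mode='simple'`` fixes (a1, a2) = (0.4, 0.1) and optimises a0 only;
    ``mode='triplet'`` optimises all three constants.
    """

    required_columns = ("AL", "ACD", "RCA")
    _param_bounds = {"a0": (-5.0, 5.0), "a1": (-1.0, 2.0), "a2": (-0.5, 0.5)}

    def __init__(self, a0=1.45, a1=0.4, a2=0.1, mode="simple"):
        self.a0 = a0
        self.a1 = a1
        self.a2 = a2
        self.mode = mode

    @property
    def _free_params(self):
        if self.mode == "triplet":
            return ("a0", "a1", "a2")
        if self.mode == "simple":
            return ("a0",)
        raise ValueError(f"unknown Haigis mode {self.mode!r}")

    def _constants_full(self, consts):
        merged = {"a0": self.a0, "a1": self.a1, "a2": self.a2}
        merged.update({k: v for k, v in consts.items()})
        # fitted a1_/a2_ only exist in triplet mode; simple mode keeps the
        # constructor's standard values.
        return merged["a0"], merged["a1"], merged["a2"]

    def _refraction(self, X, consts):
        a0, a1, a2 = self._constants_full(consts)
        return haigis_predicted_refraction(
            _col(X, "AL"), _col(X, "ACD"), _col(X, "RCA"), _col(X, "PIOL"),
            a0, a1, a2,
        )

    def _power(self, X, target_se, consts):
        a0, a1, a2 = self._constants_full(consts)
        return haigis_iol_power(
            _col(X, "AL"), _col(X, "ACD"), _col(X, "RCA"), target_se, a0, a1, a2
        )


#: Formula tag -> constructor, as used by the CLI and the evaluation protocol.
FORMULA_REGISTRY = {
    "srkt": SRKTFormula,
    "hofferq": HofferQFormula,
    "holladay1": Holladay1Formula,
    "haigis": lambda **kw: HaigisFormula(mode="simple", **kw),
    "haigis3": lambda **kw: HaigisFormula(mode="triplet", **kw),
    "castrop": CastropFormula,
}


def make_formula(tag: str, **kwargs) -> IOLFormula:
    try:
        return FORMULA_REGISTRY[tag](**kwargs)
    except KeyError as exc:
        raise ValueError(
            f"unknown formula {tag!r}; choose from {sorted(FORMULA_REGISTRY)}"
        ) from exc


def predicted_refraction(X, formula: IOLFormula | str, **kwargs) -> np.ndarray:
    """Functional dispatch: predicted SE for a formula tag or estimator."""
    if isinstance(formula, str):
        formula = make_formula(formula, **kwargs)
    return formula.predict_refraction(X)


def iol_power(X, formula: IOLFormula | str, target_se=0.0, **kwargs) -> np.ndarray:
    """Functional dispatch: IOL power for a formula tag or estimator."""
    if isinstance(formula, str):
        formula = make_formula(formula, **kwargs)
    return formula.iol_power(X, target_se=target_se)
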