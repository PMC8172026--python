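"""Paraxial vergence optics of the Castrop pseudophakic model eye.

The Castrop formula is a vergence formula on a model eye with four
refractive surfaces: the spectacle correction at vertex distance ``dVD``, a
thick cornea (front surface power ``P_CA = (nC - 1)/R_CA``, back surface
power ``P_CP = (n - nC)/R_CP``, central thickness ``dC``), and a thin IOL at
the effective lens position

    ELP = ACD + C * LT + H,

measured from the corneal front vertex.  ``ACD`` is the external phakic
anterior chamber depth, ``LT`` the crystalline lens thickness, and
``(C, H, R)`` the three formula constants: the fractional lens-equator
position, an axial offset in mm, and an additive refraction offset in
dioptres.

Forward direction (``castrop_iol_power``): the target spherical-equivalent
refraction minus ``R`` is propagated from the spectacle plane through the
cornea down to the IOL plane; the IOL power is the difference between the
vergence required to focus on the retina, ``n / (AL - ELP)``, and the
arriving vergence.  The inverse (``castrop_predicted_refraction``) is the
exact algebraic back-propagation and returns the refraction a given
implanted power produces.

Conventions
-----------
* Public interface: distances in mm, powers and vergences in dioptres.
  Internally all distances are converted to metres.
* A vergence translation ``V' = V / (1 - V*d/n)`` has a pole where the beam
  focuses exactly at the target plane; denominators within 1e-12 of zero
  raise :class:`~castrop.exceptions.VergenceSingularityError`.
* All functions are vectorised over NumPy arrays; scalars in, scalar out.
"""

from __future__ import annotations

import numpy as np

from .exceptions import BiometryDomainError, VergenceSingularityError
from .model_eye import DEFAULT_EYE, CastropConstants, ModelEye

__all__ = [
    "derive_posterior_corneal_radius",
    "corneal_surface_powers",
    "effective_lens_position",
    "vergence_refract",
    "vergence_translate",
    "castrop_iol_power",
    "castrop_predicted_refraction",
    "paraxial_trace_refraction",
]

_SINGULARITY_TOL = 1e-12
_MM = 1e-3  # mm -> m


def derive_posterior_corneal_radius(rca, eye: ModelEye = DEFAULT_EYE):
    """Posterior corneal radius from keratometry via the fixed model-eye ratio.

    ``R_CP = R_CA * 6.4 / 7.77`` (Liou-Brennan anterior/posterior ratio).
    Used when no tomographic measurement of the corneal back surface is
    available.

    Parameters
    ----------
    rca : float or array
        Mean anterior corneal radius in mm, > 0.
    """
    rca = np.asarray(rca, dtype=float)
    if np.any(rca <= 0):
        raise BiometryDomainError("anterior corneal radius must be positive")
    out = rca * eye.posterior_anterior_ratio
    return out.item() if out.ndim == 0 else out


def corneal_surface_powers(rca, rcp, eye: ModelEye = DEFAULT_EYE):
    """Front and back corneal surface powers in dioptres.

    ``P_CA = (nC - 1) / R_CA`` and ``P_CP = (n - nC) / R_CP`` with the radii
    in metres.  The back surface power is negative since the aqueous index
    is below the corneal index.  An infinite radius (flat surface) yields
    zero power.
    """
    rca = np.asarray(rca, dtype=float)
    rcp = np.asarray(rcp, dtype=float)
    if np.any(rca <= 0) or np.any(rcp <= 0):
        raise BiometryDomainError("corneal radii must be positive")
    pca = (eye.n_cornea - 1.0) / (rca * _MM)
    pcp = (eye.n_aqueous - eye.n_cornea) / (rcp * _MM)
    if pca.ndim == 0:
        return pca.item(), pcp.item()
    return pca, pcp


def effective_lens_position(acd, lt, constants: CastropConstants):
    """Effective lens position ``ELP = ACD + C*LT + H`` in mm.

    Distance from the corneal front vertex to the thin-IOL plane; the IOL is
    assumed to sit within the envelope of the removed crystalline lens, at
    the fraction ``C`` of its thickness, shifted by the axial offset ``H``.
    """
    acd = np.asarray(acd, dtype=float)
    lt = np.asarray(lt, dtype=float)
    if np.any(acd <= 0) or np.any(lt < 0):
        raise BiometryDomainError("ACD must be positive and LT non-negative")
    elp = acd + constants.c * lt + constants.h
    if np.any(elp <= 0):
        raise BiometryDomainError(
            "effective lens position is non-positive: constants place the "
            "IOL in front of the cornea"
        )
    return elp.item() if elp.ndim == 0 else elp


def vergence_refract(v, power):
    """Refraction at a thin surface: the surface power adds to the vergence."""
    return v + power


def vergence_translate(v, d_mm, n_medium=1.0):
    """Translate a reduced vergence over a homogeneous gap.

    ``V' = V / (1 - V * d / n)`` with ``d`` in metres (input in mm);
    equivalently ``1/V' = 1/V - d/n``.  A zero vergence (parallel rays)
    stays zero over any distance.

    Raises
    ------
    VergenceSingularityError
        If the vergence focuses within 1e-12 of the target plane.
    """
    v = np.asarray(v, dtype=float)
    den = 1.0 - v * (np.asarray(d_mm, dtype=float) * _MM) / n_medium
    if np.any(np.abs(den) < _SINGULARITY_TOL):
        raise VergenceSingularityError(
            "vergence focuses at the translation target plane"
        )
    out = v / den
    return out.item() if out.ndim == 0 else out


def _resolve_corneal_geometry(rca, rcp, dc, eye: ModelEye):
    """Fill posterior radius / pachymetry from the model eye where missing.

    Missing values may be ``None`` or NaN; a boolean 'derived' mask per
    record is returned alongside, so downstream reports can distinguish
    measured from model-derived corneal geometry.
    """
    rca = np.asarray(rca, dtype=float)
    if rcp is None:
        rcp = np.full_like(rca, np.nan)
    rcp = np.broadcast_to(np.asarray(rcp, dtype=float), rca.shape).copy()
    if dc is None:
        dc = np.full_like(rca, np.nan)
    dc = np.broadcast_to(np.asarray(dc, dtype=float), rca.shape).copy()

    rcp_derived = ~np.isfinite(rcp)
    dc_derived = ~np.isfinite(dc)
    if np.any(rcp_derived):
        rcp[rcp_derived] = rca[rcp_derived] * eye.posterior_anterior_ratio
    dc[dc_derived] = eye.corneal_thickness_default
    return rcp, dc, rcp_derived | dc_derived


def _prepare(al, acd, lt, rca, constants, eye, rcp, dc):
    """Common validation and unit conversion for the closed forms."""
    al = np.asarray(al, dtype=float)
    acd = np.asarray(acd, dtype=float)
    lt = np.asarray(lt, dtype=float)
    rca = np.asarray(rca, dtype=float)
    al, acd, lt, rca = np.broadcast_arrays(al, acd, lt, rca)
    if np.any(al <= 0):
        raise BiometryDomainError("axial length must be positive")
    rcp, dc, _ = _resolve_corneal_geometry(rca, rcp, dc, eye)
    pca, pcp = corneal_surface_powers(rca, rcp, eye)
    elp = np.asarray(effective_lens_position(acd, lt, constants))
    if np.any(al <= elp):
        raise BiometryDomainError(
            "axial length must exceed the effective lens position"
        )
    return al * _MM, elp * _MM, np.asarray(dc) * _MM, pca, pcp


def _check_den(den):
    if np.any(np.abs(den) < _SINGULARITY_TOL):
        raise VergenceSingularityError("intermediate vergence singularity")
    return den


def castrop_iol_power(
    al,
    acd,
    lt,
    rca,
    constants: CastropConstants,
    eye: ModelEye = DEFAULT_EYE,
    *,
    rcp=None,
    dc=None,
    target_se=0.0,
):
    """IOL power (dioptres) achieving a target refraction in the Castrop eye.

    The target spherical equivalent minus the refraction offset ``R`` is
    propagated from the spectacle plane over the vertex distance, refracted
    at the corneal front surface, translated through the corneal thickness,
    refracted at the back surface, and translated to the IOL plane.  The
    required power is ``P_IOL = n / (AL - ELP) - V_IOL``.

    Parameters
    ----------
    al, acd, lt, rca : float or array
        Axial length, external anterior chamber depth, lens thickness and
        mean anterior corneal radius, all in mm.
    constants : CastropConstants
        The (C, H, R) triplet.
    rcp, dc : float, array or None
        Measured posterior corneal radius / pachymetry in mm; ``None`` or
        NaN entries are filled from the model eye.
    target_se : float or array
        Target spherical-equivalent refraction at the spectacle plane (dpt).
    """
    al_m, elp_m, dc_m, pca, pcp = _prepare(al, acd, lt, rca, constants, eye, rcp, dc)
    n = eye.n_aqueous
    nc = eye.n_cornea
    dvd_m = eye.vertex_distance * _MM

    v = np.asarray(target_se, dtype=float) - constants.r
    v = v / _check_den(1.0 - v * dvd_m)              # spectacle -> cornea (air)
    v = v + pca                                      # corneal front surface
    v = v / _check_den(1.0 - v * dc_m / nc)          # through the cornea
    v = v + pcp                                      # corneal back surface
    v = v / _check_den(1.0 - v * (elp_m - dc_m) / n)  # aqueous to IOL plane
    p_iol = n / (al_m - elp_m) - v
    return p_iol.item() if np.ndim(p_iol) == 0 else p_iol


def castrop_predicted_refraction(
    al,
    acd,
    lt,
    rca,
    constants: CastropConstants,
    eye: ModelEye = DEFAULT_EYE,
    *,
    rcp=None,
    dc=None,
    p_iol=0.0,
):
    """Predicted spherical-equivalent refraction for an implanted power.

    Exact algebraic inverse of :func:`castrop_iol_power`: the retinal
    vergence requirement ``n / (AL - ELP)`` minus the implanted power is
    back-propagated through the cornea to the spectacle plane, and the
    refraction offset ``R`` is added.
    """
    al_m, elp_m, dc_m, pca, pcp = _prepare(al, acd, lt, rca, constants, eye, rcp, dc)
    n = eye.n_aqueous
    nc = eye.n_cornea
    dvd_m = eye.vertex_distance * _MM

    v = n / (al_m - elp_m) - np.asarray(p_iol, dtype=float)
    v = v / _check_den(1.0 + v * (elp_m - dc_m) / n)  # IOL plane -> corneal back
    v = v - pcp
    v = v / _check_den(1.0 + v * dc_m / nc)           # corneal back -> front
    v = v - pca
    v = v / _check_den(1.0 + v * dvd_m)               # cornea -> spectacle plane
    pred = v + constants.r
    return float(pred) if np.ndim(pred) == 0 else pred


def paraxial_trace_refraction(
    al,
    acd,
    lt,
    rca,
    constants: CastropConstants,
    eye: ModelEye = DEFAULT_EYE,
    *,
    rcp=None,
    dc=None,
    p_iol=0.0,
):
    """Predicted refraction by an explicit surface-by-surface vergence trace.

    Independent verification path for :func:`castrop_predicted_refraction`:
    instead of the inlined closed form, the eye is represented as an ordered
    list of (gap, surface) elements and the retinal vergence requirement is
    back-propagated step by step with the :func:`vergence_refract` /
    :func:`vergence_translate` primitives (negated distances and powers
    reverse each step).  Intended for cross-checks and tests.
    """
    al = np.asarray(al, dtype=float)
    acd = np.asarray(acd, dtype=float)
    lt = np.asarray(lt, dtype=float)
    rca = np.asarray(rca, dtype=float)
    al, acd, lt, rca = np.broadcast_arrays(al, acd, lt, rca)
    rcp_arr, dc_arr, _ = _resolve_corneal_geometry(rca, rcp, dc, eye)
    pca, pcp = corneal_surface_powers(rca, rcp_arr, eye)
    elp = np.asarray(effective_lens_position(acd, lt, constants))
    if np.any(al <= elp):
        raise BiometryDomainError(
            "axial length must exceed the effective lens position"
        )

    # Forward element order, spectacle plane -> IOL plane:
    #   gap dVD in air | front surface P_CA | gap dC in nC |
    #   back surface P_CP | gap (ELP - dC) in n
    elements = [
        ("gap", eye.vertex_distance, 1.0),
        ("surface", pca, None),
        ("gap", dc_arr, eye.n_cornea),
        ("surface", pcp, None),
        ("gap", elp - dc_arr, eye.n_aqueous),
    ]

    v = eye.n_aqueous / ((al - elp) * _MM) - np.asarray(p_iol, dtype=float)
    for kind, a, b in reversed(elements):
        if kind == "surface":
            v = vergence_refract(v, -a)
        else:
            v = vergence_translate(v, -a, b)
    pred = v + constants.r
    return float(pred) if np.ndim(pred) == 0 else pred
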