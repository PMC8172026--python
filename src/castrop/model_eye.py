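"""Schematic pseudophakic model eye and the Castrop constant triplet.

The Castrop formula propagates vergences through four refractive surfaces:
the spectacle correction, the corneal front and back surfaces (a thick
meniscus cornea), and a thin intraocular lens.  The refractive indices and
fallback geometry of that model eye live in :class:`ModelEye`; the three
tunable formula constants live in :class:`CastropConstants`.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ModelEye", "CastropConstants", "DEFAULT_EYE"]


@dataclass(frozen=True)
class ModelEye:
    """Refractive indices and fallback geometry of the pseudophakic eye.

    Parameters
    ----------
    n_cornea : float
        Corneal refractive index (default 1.376, schematic-eye value).
    n_aqueous : float
        Refractive index of aqueous and vitreous humour (default 1.336).
    vertex_distance : float
        Spectacle plane to corneal front vertex, in mm.  Standard
        refraction-lane convention is 12 mm.
    corneal_thickness_default : float
        Fallback central corneal thickness in mm (500 um) used when no
        pachymetry is available.
    posterior_anterior_ratio : float
        Fixed ratio of corneal back to front surface radius, 6.4/7.77
        (Liou-Brennan model eye), used to derive the posterior radius from
        keratometry when tomography is unavailable.
    """

    n_cornea: float = 1.376
    n_aqueous: float = 1.336
    vertex_distance: float = 12.0
    corneal_thickness_default: float = 0.5
    posterior_anterior_ratio: float = 6.4 / 7.77

    def __post_init__(self) -> None:
        if not self.n_cornea > 1:
            raise ValueError("corneal refractive index must exceed 1")
        if not self.n_aqueous > 1:
            raise ValueError("aqueous refractive index must exceed 1")
        if self.vertex_distance < 0:
            raise ValueError("vertex distance must be non-negative")
        if not self.corneal_thickness_default > 0:
            raise ValueError("fallback corneal thickness must be positive")
        if not 0 < self.posterior_anterior_ratio < 1:
            raise ValueError("posterior/anterior radius ratio must lie in (0, 1)")


#: Default schematic eye shared by all Castrop computations.
DEFAULT_EYE = ModelEye()


# Optimizer box for the constant triplet; C is typically 0.36-0.44.
C_BOUNDS = (0.35, 0.45)
H_BOUNDS = (-0.8, 0.8)
R_BOUNDS = (-0.8, 0.8)


@dataclass(frozen=True)
class CastropConstants:
    """The Castrop formula constant triplet (C, H, R).

    C is the fractional anterior portion of the crystalline lens thickness
    at which the IOL is assumed to sit (dimensionless), H an axial offset of
    the lens plane in mm (haptic/optic design), and R an additive offset on
    the predicted refraction in dioptres (lane distance / systematic
    refraction error).
    """

    c: float = 0.4
    h: float = 0.0
    r: float = 0.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.c, self.h, self.r)
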