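"""Errors raised by the vergence model and formula implementations."""


class BiometryDomainError(ValueError):
    """Biometric input outside the physical/model domain of a formula.

    Raised e.g. for a non-positive corneal radius, an effective lens
    position in front of the cornea, or an axial length shorter than the
    predicted lens plane.
    """


class VergenceSingularityError(ArithmeticError):
    """A vergence focuses exactly at the plane it is translated to.

    The translation V' = V / (1 - V*d/n) has a pole where the beam's focal
    point coincides with the target plane; intermediate denominators within
    1e-12 of zero raise this error instead of returning +/-inf.
    """


class SchemaError(ValueError):
    """A required dataset column is unmapped or a unit declaration is invalid."""
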