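"""Age-dependent CYP enzyme maturation (ontogeny) functions.

Hepatic cytochrome P450 activity in children is a fraction of the adult
level that rises with age following an Emax-type (Hill) maturation curve.
For five isoforms the fractional activity relative to adults,
``Z_ontogeny``, is modeled as

    Z(age) = (A - B) * age**h / (age50**h + age**h) + B

where ``B`` is the fraction already present at birth, ``A`` the adult
asymptote, ``age50`` the age (in years) at half-maturation and ``h`` the
Hill coefficient.  The CYP3A4/5 curve has no birth offset and an asymptote
slightly above 1 (1.061), which is the global maximum of Z across the five
supported isoforms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

from .errors import DomainError, UnsupportedEnzymeError

logger = logging.getLogger(__name__)

__all__ = [
    "CypIsoform",
    "OntogenyFraction",
    "z_ontogeny",
    "Z_MAX",
]


class CypIsoform(Enum):
    """The five CYP isoforms with a supported ontogeny function.

    ``CYP3A4`` stands for the combined CYP3A4/5 maturation curve; the labels
    ``"CYP3A4/5"`` and ``"CYP3A5"`` parse to this member.  Any other enzyme
    label is rejected: the framework deliberately refuses to assume mature
    (Z = 1) behavior for enzymes whose ontogeny it does not model.
    """

    CYP1A2 = "CYP1A2"
    CYP2B6 = "CYP2B6"
    CYP2C9 = "CYP2C9"
    CYP2C19 = "CYP2C19"
    CYP3A4 = "CYP3A4"

    @classmethod
    def parse(cls, label: "str | CypIsoform") -> "CypIsoform":
        """Case-insensitive parsing of an isoform label.

        Raises
        ------
        UnsupportedEnzymeError
            If the label is not one of the five supported isoforms.
        """
        if isinstance(label, cls):
            return label
        if not isinstance(label, str):
            raise UnsupportedEnzymeError(f"not an isoform label: {label!r}")
        norm = label.strip().upper()
        if norm in ("CYP3A4/5", "CYP3A5"):
            norm = "CYP3A4"
        try:
            return cls(norm)
        except ValueError:
            supported = ", ".join(m.value for m in cls)
            raise UnsupportedEnzymeError(
                f"no ontogeny function for {label!r}; supported: {supported}"
            ) from None


@dataclass(frozen=True)
class _MaturationParams:
    """Hill-curve parameters of one isoform's maturation function."""

    adult_asymptote: float
    birth_fraction: float
    age50_years: float
    hill: float

    def __call__(self, age_years: float) -> float:
        # span computed at call time from asymptote and birth level
        span = self.adult_asymptote - self.birth_fraction
        hill_term = age_years**self.hill / (
            self.age50_years**self.hill + age_years**self.hill
        )
        return span * hill_term + self.birth_fraction


_MATURATION: dict[CypIsoform, _MaturationParams] = {
    CypIsoform.CYP1A2: _MaturationParams(1.05, 0.08, 1.69, 1.1),
    CypIsoform.CYP2B6: _MaturationParams(1.0, 0.1, 1.0, 1.0),
    CypIsoform.CYP2C9: _MaturationParams(1.0, 0.17, 0.016, 0.53),
    CypIsoform.CYP2C19: _MaturationParams(1.0, 0.3, 0.28, 2.44),
    CypIsoform.CYP3A4: _MaturationParams(1.061, 0.0, 0.66, 0.78),
}

#: Global maximum of Z over all isoforms and ages (the CYP3A4/5 asymptote).
Z_MAX = max(p.adult_asymptote for p in _MATURATION.values())

#: Above this age the curves are extrapolated well past the pediatric range.
_EXTRAPOLATION_AGE_YEARS = 25.0


@dataclass(frozen=True)
class OntogenyFraction:
    """Fractional enzyme activity relative to adults at a given age.

    Attributes
    ----------
    z : float
        Z_ontogeny, dimensionless, in [0, 1.061].
    age_years : float
        Age in decimal years at which the function was evaluated.
    isoform : CypIsoform
        The enzyme whose maturation curve was used.
    """

    z: float
    age_years: float
    isoform: CypIsoform

    def __post_init__(self) -> None:
        if self.z < 0:
            raise DomainError(f"ontogeny fraction must be >= 0, got {self.z}")
        if self.z > Z_MAX + 1e-12:
            raise DomainError(
                f"ontogeny fraction {self.z} exceeds the maximum asymptote {Z_MAX}"
            )

    def __float__(self) -> float:
        return self.z


def z_ontogeny(isoform: "str | CypIsoform", age_years: float) -> OntogenyFraction:
    """Evaluate the fractional ontogeny of ``isoform`` at ``age_years``.

    Parameters
    ----------
    isoform : str or CypIsoform
        One of CYP1A2, CYP2B6, CYP2C9, CYP2C19, CYP3A4 (alias CYP3A4/5,
        CYP3A5).
    age_years : float
        Postnatal age in decimal years, >= 0 and finite.

    Returns
    -------
    OntogenyFraction
        The value Z_ontogeny of the isoform's maturation function, together
        with the age and isoform for provenance.

    Raises
    ------
    DomainError
        If the age is negative or non-finite.
    UnsupportedEnzymeError
        If the isoform label is not supported.

    Examples
    --------
    >>> z_ontogeny("CYP3A4", 0).z
    0.0
    >>> round(z_ontogeny("CYP3A4", 6).z, 4)
    0.9001
    """
    iso = CypIsoform.parse(isoform)
    age = float(age_years)
    if not math.isfinite(age) or age < 0:
        raise DomainError(f"age must be finite and >= 0 years, got {age_years!r}")
    if age > _EXTRAPOLATION_AGE_YEARS:
        logger.warning(
            "age %.3g y is beyond the pediatric range; the %s maturation "
            "curve is being extrapolated",
            age,
            iso.value,
        )
    return OntogenyFraction(z=_MATURATION[iso](age), age_years=age, isoform=iso)
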