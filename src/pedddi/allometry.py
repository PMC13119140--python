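"""Body-size scaling: pediatric weight from age and the allometric factor.

Total (hepatic) clearance scales with body size approximately as
weight**0.75, so the size correction applied to an adult clearance when
moving to a pediatric body is W_allometry = (WT_ped / WT_adult)**0.75.
Pediatric weight, when not observed, is approximated from age by the
Luscombe rule WT = 3*age + 7 kg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

__all__ = [
    "BodyWeight",
    "pediatric_weight",
    "w_allometry",
    "DEFAULT_ADULT_WEIGHT_KG",
    "DEFAULT_ALLOMETRIC_EXPONENT",
]

#: Conventional reference adult body weight.
DEFAULT_ADULT_WEIGHT_KG = 70.0

#: Allometric exponent for clearance-like quantities.
DEFAULT_ALLOMETRIC_EXPONENT = 0.75

# Luscombe weight-for-age rule: WT[kg] = slope*age[y] + intercept
_LUSCOMBE_SLOPE_KG_PER_Y = 3.0
_LUSCOMBE_INTERCEPT_KG = 7.0


@dataclass(frozen=True)
class BodyWeight:
    """A body weight in kilograms, tagged with its provenance."""

    kg: float
    source: str  # "luscombe_formula" | "user_supplied"
    age_years: float | None = None

    def __post_init__(self) -> None:
        if not (self.kg > 0) or not math.isfinite(self.kg):
            raise DomainError(f"body weight must be a positive finite number of kg, got {self.kg!r}")
        if self.source not in ("luscombe_formula", "user_supplied"):
            raise DomainError(f"unknown body-weight source {self.source!r}")

    def __float__(self) -> float:
        return self.kg


def pediatric_weight(age_years: float) -> BodyWeight:
    """Pediatric body weight from age via the Luscombe rule, WT = 3*age + 7.

    Parameters
    ----------
    age_years : float
        Age in decimal years, >= 0.

    Returns
    -------
    BodyWeight
        Weight in kg with ``source="luscombe_formula"``.

    Examples
    --------
    >>> pediatric_weight(6).kg
    25.0
    """
    age = float(age_years)
    if not math.isfinite(age) or age < 0:
        raise DomainError(f"age must be finite and >= 0 years, got {age_years!r}")
    kg = _LUSCOMBE_SLOPE_KG_PER_Y * age + _LUSCOMBE_INTERCEPT_KG
    return BodyWeight(kg=kg, source="luscombe_formula", age_years=age)


def w_allometry(
    weight_pediatric_kg: float,
    weight_adult_kg: float = DEFAULT_ADULT_WEIGHT_KG,
    exponent: float = DEFAULT_ALLOMETRIC_EXPONENT,
) -> float:
    """Allometric body-size correction (WT_ped / WT_adult)**exponent.

    Equals 1 when the weights are equal and lies in (0, 1] whenever the
    pediatric weight does not exceed the adult weight.  Scale-invariant:
    only the weight ratio matters.

    Raises
    ------
    DomainError
        If either weight is not a positive finite number.
    """
    wp = float(weight_pediatric_kg)
    wa = float(weight_adult_kg)
    for name, w in (("pediatric", wp), ("adult", wa)):
        if not math.isfinite(w) or w <= 0:
            raise DomainError(f"{name} weight must be finite and > 0 kg, got {w!r}")
    return (wp / wa) ** float(exponent)
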