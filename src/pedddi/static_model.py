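"""Static drug-drug interaction model and adult-to-pediatric extrapolation.

The adult static model expresses the victim drug's AUC ratio (AUCR, exposure
with perpetrator over exposure alone) in closed form from two scalars: CR,
the fraction of the victim's oral clearance carried by the affected CYP, and
the perpetrator's potency -- IR (inhibition ratio, 0..1) for inhibitors or
IC (its induction analogue, >= 0) for inducers:

    inhibition:  AUCR = 1 / (1 - CR*IR)
    induction:   AUCR = 1 / (1 + CR*IC)

Extrapolation to a pediatric age corrects only CR: the affected pathway is
scaled by the enzyme's ontogeny fraction Z, and total clearance by the
allometric body-size factor W, so CR_ped = (Z/W) * CR_adult.  Substituting
back and eliminating CR*IR (or CR*IC) yields a formula that needs only the
*adult AUCR*, not CR or IR themselves:

    AUCR_ped = 1 / (1 - (Z/W) * (1 - 1/AUCR_adult))

The inhibition and induction forms of this pediatric equation are
algebraically identical, so a single function implements both; the
perpetrator's potency (IR/IC) is assumed age-invariant.  The three
extrapolation approaches differ only in the correction factors:

    Approach A: Z = 1, W = 1           (pediatric AUCR = adult AUCR)
    Approach B: Z = ontogeny, W = 1    (ontogeny correction only)
    Approach C: Z = ontogeny, W = allometry   (both corrections)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .allometry import (
    DEFAULT_ADULT_WEIGHT_KG,
    DEFAULT_ALLOMETRIC_EXPONENT,
    BodyWeight,
    pediatric_weight,
    w_allometry,
)
from .errors import (
    DomainError,
    ModelDomainError,
    NotInvertibleError,
    OutOfFractionWarning,
)
from .ontogeny import CypIsoform, z_ontogeny

__all__ = [
    "APPROACHES",
    "StaticModelInputs",
    "CorrectionFactors",
    "PredictionResult",
    "adult_aucr_inhibition",
    "adult_aucr_induction",
    "correct_cr",
    "pediatric_aucr",
    "invert_to_adult",
    "predict",
]

APPROACHES = ("A", "B", "C")


def _check_positive_finite(x: float, name: str) -> float:
    x = float(x)
    if not math.isfinite(x) or x <= 0:
        raise DomainError(f"{name} must be finite and > 0, got {x!r}")
    return x


def _check_fraction(x: float, name: str) -> float:
    x = float(x)
    if not math.isfinite(x) or not (0.0 <= x <= 1.0):
        raise DomainError(f"{name} must lie in [0, 1], got {x!r}")
    return x


@dataclass(frozen=True)
class StaticModelInputs:
    """Scalar inputs of the adult static model.

    Exactly one of ``ir`` (inhibition) or ``ic`` (induction) may be set.
    """

    cr: float
    ir: float | None = None
    ic: float | None = None

    def __post_init__(self) -> None:
        _check_fraction(self.cr, "CR")
        if (self.ir is None) == (self.ic is None):
            raise DomainError("exactly one of IR (inhibition) or IC (induction) must be given")
        if self.ir is not None:
            _check_fraction(self.ir, "IR")
        if self.ic is not None:
            ic = float(self.ic)
            if not math.isfinite(ic) or ic < 0:
                raise DomainError(f"IC must be finite and >= 0, got {self.ic!r}")

    def adult_aucr(self) -> float:
        if self.ir is not None:
            return adult_aucr_inhibition(self.cr, self.ir)
        return adult_aucr_induction(self.cr, self.ic)  # type: ignore[arg-type]


@dataclass(frozen=True)
class CorrectionFactors:
    """The (Z_ontogeny, W_allometry) pair used by an extrapolation approach."""

    z: float
    w: float
    approach: str

    def __post_init__(self) -> None:
        if self.approach not in APPROACHES:
            raise DomainError(f"approach must be one of {APPROACHES}, got {self.approach!r}")
        if not math.isfinite(self.z) or self.z < 0:
            raise DomainError(f"Z_ontogeny must be finite and >= 0, got {self.z!r}")
        if not math.isfinite(self.w) or self.w <= 0:
            raise DomainError(f"W_allometry must be finite and > 0, got {self.w!r}")
        if self.approach == "A" and not (self.z == 1.0 and self.w == 1.0):
            raise DomainError("Approach A requires Z = W = 1")
        if self.approach == "B" and self.w != 1.0:
            raise DomainError("Approach B requires W = 1")

    @property
    def ratio(self) -> float:
        """Z/W, the scalar multiplying the adult interaction term."""
        return self.z / self.w


@dataclass(frozen=True)
class PredictionResult:
    """A pediatric AUCR prediction with full provenance."""

    aucr_pediatric: float
    aucr_adult: float
    factors: CorrectionFactors
    direction: str  # "inhibition" | "induction" | "none"
    age_years: float | None = None
    isoform: CypIsoform | None = None
    weight: BodyWeight | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.aucr_pediatric) or self.aucr_pediatric <= 0:
            raise DomainError(f"pediatric AUCR must be finite and > 0, got {self.aucr_pediatric!r}")
        expected = (
            "inhibition" if self.aucr_adult > 1 else "induction" if self.aucr_adult < 1 else "none"
        )
        if self.direction != expected:
            raise DomainError(
                f"direction {self.direction!r} inconsistent with adult AUCR {self.aucr_adult}"
            )


def adult_aucr_inhibition(cr: float, ir: float) -> float:
    """Adult AUC ratio under competitive pathway inhibition, 1/(1 - CR*IR).

    Raises
    ------
    ModelDomainError
        If CR*IR >= 1 (complete inhibition of total clearance: the static
        model predicts unbounded exposure).
    """
    cr = _check_fraction(cr, "CR")
    ir = _check_fraction(ir, "IR")
    term = cr * ir
    if term >= 1.0:
        raise ModelDomainError(
            f"CR*IR = {term} >= 1: complete inhibition of total clearance"
        )
    return 1.0 / (1.0 - term)


def adult_aucr_induction(cr: float, ic: float) -> float:
    """Adult AUC ratio under pathway induction, 1/(1 + CR*IC), in (0, 1]."""
    cr = _check_fraction(cr, "CR")
    ic = float(ic)
    if not math.isfinite(ic) or ic < 0:
        raise DomainError(f"IC must be finite and >= 0, got {ic!r}")
    return 1.0 / (1.0 + cr * ic)


def correct_cr(cr_adult: float, z: float, w: float) -> float:
    """Ontogeny/allometry-corrected clearance ratio, CR_ped = Z*CR_adult/W.

    The result is returned unclamped; if it exceeds 1 it is no longer
    interpretable as a clearance fraction and an :class:`OutOfFractionWarning`
    is emitted.
    """
    cr_adult = _check_fraction(cr_adult, "CR")
    z = float(z)
    if not math.isfinite(z) or z < 0:
        raise DomainError(f"Z_ontogeny must be finite and >= 0, got {z!r}")
    w = _check_positive_finite(w, "W_allometry")
    cr_ped = z * cr_adult / w
    if cr_ped > 1.0:
        warnings.warn(
            f"corrected CR = {cr_ped:.4g} exceeds 1 and is not interpretable "
            "as a clearance fraction",
            OutOfFractionWarning,
            stacklevel=2,
        )
    return cr_ped


def pediatric_aucr(aucr_adult: float, z: float, w: float) -> float:
    """Pediatric AUCR from the adult AUCR and correction factors Z, W.

    Implements ``1 / (1 - (Z/W) * (1 - 1/AUCR_adult))``.  The inhibition and
    induction forms of the pediatric extrapolation are the same algebraic
    function, so this single implementation covers both directions: an adult
    AUCR > 1 (inhibition) maps to a pediatric AUCR > 1, an adult AUCR < 1
    (induction) to one < 1, and 1 to 1 for any factors.

    Raises
    ------
    ModelDomainError
        If ``(Z/W)*(1 - 1/AUCR_adult) >= 1``, where the corrected interaction
        term would predict a non-positive pediatric clearance.
    """
    aucr_adult = _check_positive_finite(aucr_adult, "adult AUCR")
    z = float(z)
    if not math.isfinite(z) or z < 0:
        raise DomainError(f"Z_ontogeny must be finite and >= 0, got {z!r}")
    w = _check_positive_finite(w, "W_allometry")
    term = (z / w) * (1.0 - 1.0 / aucr_adult)
    if term >= 1.0:
        raise ModelDomainError(
            f"(Z/W)*(1 - 1/AUCR_adult) = {term:.4g} >= 1: corrected "
            "interaction term predicts non-positive clearance"
        )
    return 1.0 / (1.0 - term)


def invert_to_adult(aucr_pediatric: float, z: float, w: float) -> float:
    """Back-calculate the adult AUCR from a pediatric one (inverse mapping).

    Solves ``pediatric_aucr(a, z, w) == aucr_pediatric`` for ``a``:
    ``a = 1 / (1 - (W/Z) * (1 - 1/AUCR_ped))``.

    Raises
    ------
    NotInvertibleError
        If ``z == 0`` (the forward map is constant at 1).
    """
    aucr_pediatric = _check_positive_finite(aucr_pediatric, "pediatric AUCR")
    w = _check_positive_finite(w, "W_allometry")
    z = float(z)
    if z == 0:
        raise NotInvertibleError("Z_ontogeny = 0: the pediatric AUCR carries no information")
    if not math.isfinite(z) or z < 0:
        raise DomainError(f"Z_ontogeny must be finite and >= 0, got {z!r}")
    term = (w / z) * (1.0 - 1.0 / aucr_pediatric)
    if term >= 1.0:
        raise ModelDomainError(
            f"(W/Z)*(1 - 1/AUCR_ped) = {term:.4g} >= 1: no adult AUCR maps "
            "to this pediatric value under the given factors"
        )
    return 1.0 / (1.0 - term)


def correction_factors(
    approach: str,
    isoform: "str | CypIsoform | None" = None,
    age_years: float | None = None,
    adult_weight_kg: float = DEFAULT_ADULT_WEIGHT_KG,
    allometric_exponent: float = DEFAULT_ALLOMETRIC_EXPONENT,
    pediatric_weight_kg: float | None = None,
) -> tuple[CorrectionFactors, BodyWeight | None]:
    """Resolve the (Z, W) pair for one approach at one age.

    Approach A needs neither isoform nor age.  Approaches B and C require
    both; Approach C additionally uses the pediatric body weight, taken from
    the Luscombe rule unless ``pediatric_weight_kg`` overrides it.
    """
    approach = str(approach).strip().upper()
    if approach not in APPROACHES:
        raise DomainError(f"approach must be one of {APPROACHES}, got {approach!r}")
    if approach == "A":
        return CorrectionFactors(z=1.0, w=1.0, approach="A"), None
    if isoform is None or age_years is None:
        raise DomainError(f"approach {approach} requires both a CYP isoform and an age")
    z = z_ontogeny(isoform, age_years).z
    if approach == "B":
        return CorrectionFactors(z=z, w=1.0, approach="B"), None
    if pediatric_weight_kg is not None:
        weight = BodyWeight(kg=float(pediatric_weight_kg), source="user_supplied",
                            age_years=float(age_years))
    else:
        weight = pediatric_weight(age_years)
    w = w_allometry(weight.kg, adult_weight_kg, allometric_exponent)
    return CorrectionFactors(z=z, w=w, approach="C"), weight


def predict(
    aucr_adult: float,
    isoform: "str | CypIsoform | None" = None,
    age_years: float | None = None,
    approach: str = "C",
    adult_weight_kg: float = DEFAULT_ADULT_WEIGHT_KG,
    allometric_exponent: float = DEFAULT_ALLOMETRIC_EXPONENT,
    pediatric_weight_kg: float | None = None,
) -> PredictionResult:
    """Predict the pediatric AUCR from an adult AUCR with one approach.

    Parameters
    ----------
    aucr_adult : float
        Observed (or static-model-predicted) adult AUC ratio, > 0.
    isoform : str or CypIsoform, optional
        Affected CYP; required for approaches B and C.
    age_years : float, optional
        Pediatric age in decimal years; required for approaches B and C.
    approach : {"A", "B", "C"}
        A: identity; B: ontogeny correction; C: ontogeny + allometry.
    adult_weight_kg, allometric_exponent :
        Reference adult weight (default 70 kg) and allometric exponent
        (default 0.75) entering W_allometry for approach C.
    pediatric_weight_kg : float, optional
        Observed pediatric weight overriding the Luscombe weight-for-age rule.

    Returns
    -------
    PredictionResult
        The predicted pediatric AUCR plus the factors and inputs used.

    Examples
    --------
    >>> round(predict(1.49, "CYP3A4", 6, approach="C").aucr_pediatric, 2)
    2.78
    """
    aucr_adult = _check_positive_finite(aucr_adult, "adult AUCR")
    factors, weight = correction_factors(
        approach,
        isoform=isoform,
        age_years=age_years,
        adult_weight_kg=adult_weight_kg,
        allometric_exponent=allometric_exponent,
        pediatric_weight_kg=pediatric_weight_kg,
    )
    value = pediatric_aucr(aucr_adult, factors.z, factors.w)
    direction = (
        "inhibition" if aucr_adult > 1 else "induction" if aucr_adult < 1 else "none"
    )
    iso = CypIsoform.parse(isoform) if isoform is not None else None
    return PredictionResult(
        aucr_pediatric=value,
        aucr_adult=aucr_adult,
        factors=factors,
        direction=direction,
        age_years=None if age_years is None else float(age_years),
        isoform=iso,
        weight=weight,
    )
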