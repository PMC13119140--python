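"""Run configuration shared by the library evaluation routines and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .errors import DomainError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Knobs of an evaluation run.

    adult_weight_kg : reference adult body weight (kg) in W_allometry.
    allometric_exponent : exponent of the body-weight ratio (default 0.75).
    guest_delta : tightness parameter of the Guest acceptance interval;
        1.25 is the variability-allowing variant, 1 the strict one.
    rounding_decimals : decimals used when comparing against printed values.
    mode : "recompute" (predictions regenerated from the model) or
        "printed" (use the predictions stored in the case table).
    approaches : subset of {"A", "B", "C"} to evaluate.
    """

    adult_weight_kg: float = 70.0
    allometric_exponent: float = 0.75
    guest_delta: float = 1.25
    rounding_decimals: int = 2
    mode: str = "recompute"
    approaches: tuple[str, ...] = ("A", "B", "C")

    def __post_init__(self) -> None:
        for name in ("adult_weight_kg", "allometric_exponent", "guest_delta"):
            if not (getattr(self, name) > 0):
                raise DomainError(f"{name} must be > 0")
        if self.guest_delta < 1:
            raise DomainError("guest_delta must be >= 1")
        if self.rounding_decimals < 0:
            raise DomainError("rounding_decimals must be >= 0")
        if self.mode not in ("recompute", "printed"):
            raise DomainError(f"mode must be 'recompute' or 'printed', got {self.mode!r}")
        self.approaches = tuple(str(a).upper() for a in self.approaches)
        if not self.approaches or any(a not in ("A", "B", "C") for a in self.approaches):
            raise DomainError(f"approaches must be a non-empty subset of A/B/C, got {self.approaches!r}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise DomainError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)
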