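"""Exception hierarchy.

All package-specific errors derive from :class:`PedddiError` so callers can
catch the whole family with one clause; the leaves distinguish usage errors
(bad input) from model-domain errors (inputs outside the region where the
static equations are physically meaningful).
"""


class PedddiError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(PedddiError, ValueError):
    """An input violates a precondition (negative age, non-positive weight...)."""


class UnsupportedEnzymeError(PedddiError, ValueError):
    """The CYP isoform has no ontogeny function in this framework."""


class ModelDomainError(PedddiError, ArithmeticError):
    """The static model is evaluated outside its valid region.

    Raised e.g. when CR*IR >= 1 (complete inhibition of total clearance) or
    when the ontogeny/allometry-corrected interaction term predicts a
    non-positive pediatric clearance.
    """


class NotInvertibleError(PedddiError, ValueError):
    """The pediatric AUCR equation cannot be inverted (Z_ontogeny = 0)."""


class AgeParseError(PedddiError, ValueError):
    """An age expression does not match the supported grammar."""

    def __init__(self, text: str, reason: str = "unparseable age expression"):
        self.text = text
        super().__init__(f"{reason}: {text!r}")


class SchemaError(PedddiError, ValueError):
    """A case table violates the CSV schema; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class OutOfFractionWarning(UserWarning):
    """A corrected clearance ratio exceeds 1 and is no longer a fraction."""
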