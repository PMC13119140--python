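"""Validation dataset and CSV I/O for pediatric DDI case tables.

The package ships a 25-case clinical validation set of victim-perpetrator
drug pairs with observed pediatric and adult AUC ratios, the affected CYP
isoform, the study cohort's age (point or range, in years/months/weeks) and
the originally published predictions of the three extrapolation approaches.
User-supplied case tables use the same CSV schema:

    victim, perpetrator, cyp, age_text, observed_aucr_pediatric,
    aucr_adult, printed_pred_a, printed_pred_b, printed_pred_c,
    age_override_years

(the last four columns optional, empty allowed).  Age expressions follow the
grammar ``NUMBER [unit]`` or ``NUMBER [unit] - NUMBER [unit]`` with units
``y`` (years, the default), ``m`` (months) and ``w`` (weeks).  For age
ranges the canonical age used for prediction is the midpoint of the range,
unless ``age_override_years`` supplies e.g. the cohort mean age.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import AgeParseError, PedddiError, SchemaError
from .ontogeny import CypIsoform

__all__ = [
    "AgeSpec",
    "DdiRecord",
    "parse_age",
    "load_validation_table",
    "read_cases",
    "write_cases",
    "CSV_COLUMNS",
]

_PACKAGED_CSV = "ddi_validation_cases.csv"

CSV_COLUMNS = (
    "victim",
    "perpetrator",
    "cyp",
    "age_text",
    "observed_aucr_pediatric",
    "aucr_adult",
    "printed_pred_a",
    "printed_pred_b",
    "printed_pred_c",
    "age_override_years",
)
_REQUIRED_COLUMNS = CSV_COLUMNS[:6]
_OPTIONAL_COLUMNS = CSV_COLUMNS[6:]

# years per unit; weeks use 52 weeks/year (data carry two significant figures)
_UNIT_YEARS = {"y": 1.0, "m": 1.0 / 12.0, "w": 1.0 / 52.0}

_DASHES = "‐‑‒–—―−"  # unicode dashes -> "-"
_BOUND_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*([ymw])?\s*$", re.IGNORECASE)


@dataclass(frozen=True)
class AgeSpec:
    """An age expression: raw text, bounds in years and a canonical point.

    For a single value the point equals the value; for a range the point is
    the midpoint ``(low + high)/2`` in years.
    """

    raw_text: str
    low_years: float
    high_years: float
    point_years: float

    def __post_init__(self) -> None:
        if self.low_years < 0 or self.high_years < 0 or self.point_years < 0:
            raise AgeParseError(self.raw_text, "negative age")
        if self.low_years > self.high_years:
            raise AgeParseError(self.raw_text, "lower bound exceeds upper bound")

    @property
    def is_range(self) -> bool:
        return self.low_years != self.high_years


def _parse_bound(text: str, raw: str) -> tuple[float, str | None]:
    m = _BOUND_RE.match(text)
    if not m:
        raise AgeParseError(raw)
    return float(m.group(1)), (m.group(2).lower() if m.group(2) else None)


def parse_age(text: str) -> AgeSpec:
    """Parse an age expression into bounds and a canonical age in years.

    Units: ``y`` years (default), ``m`` months (/12), ``w`` weeks (/52).
    In a range, each bound may carry its own unit ("2 w-7.8 y"); a unit
    trailing the range with none on the first bound applies to both bounds
    ("10-108 m").  Ranges resolve to the midpoint.

    Examples
    --------
    >>> parse_age("2-10").point_years
    6.0
    >>> round(parse_age("19 m").point_years, 4)
    1.5833
    """
    if not isinstance(text, str) or not text.strip():
        raise AgeParseError(repr(text), "empty age expression")
    raw = text.strip()
    norm = raw
    for d in _DASHES:
        norm = norm.replace(d, "-")
    parts = norm.split("-")
    if len(parts) == 1:
        value, unit = _parse_bound(parts[0], raw)
        years = value * _UNIT_YEARS[unit or "y"]
        return AgeSpec(raw_text=raw, low_years=years, high_years=years, point_years=years)
    if len(parts) != 2:
        raise AgeParseError(raw)
    low_v, low_u = _parse_bound(parts[0], raw)
    high_v, high_u = _parse_bound(parts[1], raw)
    if low_u is None:
        low_u = high_u or "y"  # trailing unit governs the whole range
    if high_u is None:
        high_u = "y"
    low = low_v * _UNIT_YEARS[low_u]
    high = high_v * _UNIT_YEARS[high_u]
    return AgeSpec(raw_text=raw, low_years=low, high_years=high,
                   point_years=(low + high) / 2.0)


@dataclass(frozen=True)
class DdiRecord:
    """One victim-perpetrator pediatric DDI validation case."""

    victim: str
    perpetrator: str
    isoform: CypIsoform
    age: AgeSpec
    observed_aucr_pediatric: float
    aucr_adult: float
    printed_pred_a: float | None = None
    printed_pred_b: float | None = None
    printed_pred_c: float | None = None
    age_override_years: float | None = None

    def __post_init__(self) -> None:
        for name in ("observed_aucr_pediatric", "aucr_adult"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise SchemaError(f"{name} must be finite and > 0, got {v!r}")
        for name in ("printed_pred_a", "printed_pred_b", "printed_pred_c"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v <= 0):
                raise SchemaError(f"{name} must be finite and > 0 when present, got {v!r}")
        if self.printed_pred_a is not None and not math.isclose(
            self.printed_pred_a, self.aucr_adult, rel_tol=0, abs_tol=1e-9
        ):
            raise SchemaError(
                "printed_pred_a must equal aucr_adult (the identity approach), "
                f"got {self.printed_pred_a} vs {self.aucr_adult}"
            )
        if self.age_override_years is not None and self.age_override_years < 0:
            raise SchemaError(f"age_override_years must be >= 0, got {self.age_override_years!r}")

    @property
    def prediction_age_years(self) -> float:
        """Canonical age used for prediction (midpoint unless overridden)."""
        if self.age_override_years is not None:
            return self.age_override_years
        return self.age.point_years

    def printed_prediction(self, approach: str) -> float | None:
        return {"A": self.printed_pred_a, "B": self.printed_pred_b,
                "C": self.printed_pred_c}[approach.upper()]


def _opt_float(value, *, row: int, column: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if not s:
        return None
    try:
        return float(s)
    except ValueError:
        raise SchemaError(f"column {column!r}: not a number: {value!r}", row=row) from None


def _records_from_frame(df: pd.DataFrame, source: str) -> list[DdiRecord]:
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required columns {missing}")
    records: list[DdiRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            rec = DdiRecord(
                victim=str(row["victim"]).strip(),
                perpetrator=str(row["perpetrator"]).strip(),
                isoform=CypIsoform.parse(str(row["cyp"])),
                age=parse_age(str(row["age_text"])),
                observed_aucr_pediatric=float(row["observed_aucr_pediatric"]),
                aucr_adult=float(row["aucr_adult"]),
                printed_pred_a=_opt_float(row.get("printed_pred_a"), row=i, column="printed_pred_a"),
                printed_pred_b=_opt_float(row.get("printed_pred_b"), row=i, column="printed_pred_b"),
                printed_pred_c=_opt_float(row.get("printed_pred_c"), row=i, column="printed_pred_c"),
                age_override_years=_opt_float(
                    row.get("age_override_years"), row=i, column="age_override_years"
                ),
            )
        except SchemaError as exc:
            if exc.row is None:
                raise SchemaError(str(exc), row=i) from None
            raise
        except (PedddiError, ValueError, TypeError) as exc:
            raise SchemaError(str(exc), row=i) from None
        records.append(rec)
    return records


def read_cases(path: "str | Path") -> list[DdiRecord]:
    """Read a DDI case table from CSV (schema in the module docstring)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"cannot read case table {path}: {exc}") from exc
    return _records_from_frame(df, source=str(path))


def write_cases(records: list[DdiRecord], path: "str | Path") -> None:
    """Write records to CSV; ``read_cases(write_cases(x))`` round-trips."""
    rows = []
    for rec in records:
        rows.append(
            {
                "victim": rec.victim,
                "perpetrator": rec.perpetrator,
                "cyp": rec.isoform.value,
                "age_text": rec.age.raw_text,
                "observed_aucr_pediatric": rec.observed_aucr_pediatric,
                "aucr_adult": rec.aucr_adult,
                "printed_pred_a": rec.printed_pred_a,
                "printed_pred_b": rec.printed_pred_b,
                "printed_pred_c": rec.printed_pred_c,
                "age_override_years": rec.age_override_years,
            }
        )
    df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    df.to_csv(path, index=False, encoding="utf-8")


def load_validation_table() -> list[DdiRecord]:
    """Load the packaged 25-case pediatric DDI validation dataset.

    The records preserve the published row order and the originally printed
    predictions for the three approaches (``printed_pred_a/b/c``); the
    Approach A column doubles as the observed adult AUCR.
    """
    try:
        ref = resources.files(__package__).joinpath("data", _PACKAGED_CSV)
        with resources.as_file(ref) as p:
            records = read_cases(p)
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise PedddiError(f"packaged validation table missing: {exc}") from exc
    if len(records) != 25:
        raise PedddiError(
            f"packaged validation table corrupt: expected 25 records, found {len(records)}"
        )
    return records
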