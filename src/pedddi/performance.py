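"""Prediction-performance metrics for predicted-vs-observed AUC ratios.

Metrics follow the conventions of the PK prediction literature:

* **GMFE** (geometric mean fold error): ``exp(mean(|ln(pred/obs)|))``;
  1 means perfect agreement, 2 an average two-fold error.
* **MAPE**: ``100 * mean(|pred - obs| / obs)`` in percent.
* **Two-fold criterion**: a prediction is acceptable if ``pred/obs`` lies in
  [0.5, 2.0] (boundaries inclusive).
* **Guest limits**: an observation-magnitude-dependent acceptance interval
  that tightens toward the strict ``delta``-fold band as the observed ratio
  approaches 1: with ``R = max(obs, 1/obs)`` the limit is
  ``L = (delta + 2*(R - 1)) / R`` and the prediction is acceptable iff
  ``1/L <= pred/obs <= L``.
* **OLS fit** of predicted on observed (slope, intercept), as drawn on
  predicted-vs-observed scatter plots.

:func:`evaluate` applies these to a list of validation cases for one
extrapolation approach, either recomputing predictions from the model
("recompute" mode) or taking the predictions stored in the case table
("printed" mode), and always includes a reproducibility audit comparing the
two wherever stored predictions exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._rounding import round_half_away
from .config import RunConfig
from .errors import DomainError
from .static_model import predict
from .validation_data import DdiRecord

__all__ = [
    "PairedPrediction",
    "PerformanceSummary",
    "fold_error",
    "gmfe",
    "mape",
    "within_twofold",
    "guest_limit",
    "within_guest",
    "ols_fit",
    "evaluate",
]


@dataclass(frozen=True)
class PairedPrediction:
    """One predicted/observed AUCR pair with its ratio and bias."""

    predicted: float
    observed: float

    def __post_init__(self) -> None:
        for name, v in (("predicted", self.predicted), ("observed", self.observed)):
            if not math.isfinite(v) or v <= 0:
                raise DomainError(f"{name} AUCR must be finite and > 0, got {v!r}")

    @property
    def ratio(self) -> float:
        """predicted / observed."""
        return self.predicted / self.observed

    @property
    def bias(self) -> float:
        """predicted - observed."""
        return self.predicted - self.observed


def _pairs(pairs: "list[PairedPrediction]") -> "list[PairedPrediction]":
    if not pairs:
        raise DomainError("empty list of predicted/observed pairs")
    return pairs


def fold_error(predicted: float, observed: float) -> float:
    """Symmetric fold error max(p/o, o/p), always >= 1."""
    r = PairedPrediction(predicted, observed).ratio
    return max(r, 1.0 / r)


def gmfe(pairs: "list[PairedPrediction]") -> float:
    """Geometric mean fold error, exp(mean(|ln(pred/obs)|))."""
    logs = [abs(math.log(p.ratio)) for p in _pairs(pairs)]
    return math.exp(sum(logs) / len(logs))


def mape(pairs: "list[PairedPrediction]") -> float:
    """Mean absolute prediction error in percent, 100*mean(|p-o|/o)."""
    errs = [abs(p.bias) / p.observed for p in _pairs(pairs)]
    return 100.0 * sum(errs) / len(errs)


def within_twofold(predicted: float, observed: float) -> bool:
    """True iff predicted/observed lies within [0.5, 2.0], inclusive."""
    r = PairedPrediction(predicted, observed).ratio
    return 0.5 <= r <= 2.0


def guest_limit(observed_aucr: float, delta: float = 1.25) -> float:
    """Upper acceptance limit L for pred/obs at a given observed AUCR.

    ``L = (delta + 2*(R - 1)) / R`` with ``R = max(obs, 1/obs)``; L >= 1 and
    decreases toward ``delta`` as the observed ratio approaches 1, widening
    toward the two-fold limit for large interactions.  Reciprocal observed
    values yield the same limit.
    """
    if not math.isfinite(observed_aucr) or observed_aucr <= 0:
        raise DomainError(f"observed AUCR must be finite and > 0, got {observed_aucr!r}")
    if delta < 1:
        raise DomainError(f"Guest delta must be >= 1, got {delta!r}")
    r = max(observed_aucr, 1.0 / observed_aucr)
    return (delta + 2.0 * (r - 1.0)) / r


def within_guest(predicted: float, observed: float, delta: float = 1.25) -> bool:
    """True iff pred/obs lies within [1/L, L] for the Guest limit L."""
    limit = guest_limit(observed, delta)
    r = PairedPrediction(predicted, observed).ratio
    return 1.0 / limit <= r <= limit


def ols_fit(pairs: "list[PairedPrediction]") -> tuple[float, float]:
    """Ordinary least squares of predicted on observed: (slope, intercept)."""
    pairs = _pairs(pairs)
    if len(pairs) < 2:
        raise DomainError("OLS needs at least two pairs")
    x = np.array([p.observed for p in pairs], dtype=float)
    y = np.array([p.predicted for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise DomainError("OLS needs non-degenerate observed values")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


@dataclass(frozen=True)
class AuditRow:
    """A recompute-vs-printed residual exceeding the audit threshold."""

    index: int
    victim: str
    perpetrator: str
    isoform: str
    approach: str
    printed: float
    recomputed: float

    @property
    def residual(self) -> float:
        return self.recomputed - self.printed


@dataclass(frozen=True)
class PerformanceSummary:
    """Per-approach performance metrics over a set of DDI cases."""

    approach: str
    n: int
    gmfe: float
    mape_percent: float
    ols_slope: float
    ols_intercept: float
    n_outside_twofold: int
    n_outside_guest: int
    guest_delta: float
    per_record: tuple[PairedPrediction, ...]
    audit: tuple[AuditRow, ...] = field(default_factory=tuple)
    mode: str = "recompute"

    def __post_init__(self) -> None:
        if not (0 <= self.n_outside_twofold <= self.n):
            raise DomainError("n_outside_twofold out of range")
        if not (0 <= self.n_outside_guest <= self.n):
            raise DomainError("n_outside_guest out of range")
        if self.gmfe < 1:
            raise DomainError("GMFE is a folded error and cannot be below 1")

    def to_dict(self) -> dict:
        return {
            "approach": self.approach,
            "mode": self.mode,
            "n": self.n,
            "gmfe": self.gmfe,
            "mape_percent": self.mape_percent,
            "ols_slope": self.ols_slope,
            "ols_intercept": self.ols_intercept,
            "n_outside_twofold": self.n_outside_twofold,
            "n_outside_guest": self.n_outside_guest,
            "guest_delta": self.guest_delta,
            "per_record": [
                {"predicted": p.predicted, "observed": p.observed,
                 "ratio": p.ratio, "bias": p.bias}
                for p in self.per_record
            ],
            "audit": [
                {"index": a.index, "victim": a.victim, "perpetrator": a.perpetrator,
                 "isoform": a.isoform, "approach": a.approach,
                 "printed": a.printed, "recomputed": a.recomputed,
                 "residual": a.residual}
                for a in self.audit
            ],
        }


# residual magnitude above which a recomputed prediction is flagged as not
# reproducing the stored (printed) one
_AUDIT_THRESHOLD = 0.01


def _recompute(record: DdiRecord, approach: str, config: RunConfig) -> float:
    return predict(
        record.aucr_adult,
        isoform=record.isoform,
        age_years=record.prediction_age_years,
        approach=approach,
        adult_weight_kg=config.adult_weight_kg,
        allometric_exponent=config.allometric_exponent,
    ).aucr_pediatric


def evaluate(
    records: "list[DdiRecord]",
    approach: str,
    mode: str | None = None,
    config: RunConfig | None = None,
) -> PerformanceSummary:
    """Evaluate one extrapolation approach over a set of DDI cases.

    Parameters
    ----------
    records : list of DdiRecord
        Non-empty case table.
    approach : {"A", "B", "C"}
    mode : {"recompute", "printed"}, optional
        "recompute" regenerates each prediction from the adult AUCR, the
        CYP isoform and the canonical age; "printed" evaluates the
        predictions stored in the table (requires the corresponding
        printed-prediction column).  Defaults to ``config.mode``.
    config : RunConfig, optional

    Returns
    -------
    PerformanceSummary
        GMFE, MAPE, OLS slope/intercept, counts outside the two-fold and
        Guest limits, the per-record pairs, and the reproducibility audit:
        every row whose recomputed prediction differs from the stored one by
        more than 0.01.
    """
    if not records:
        raise DomainError("empty case table")
    config = config or RunConfig()
    approach = str(approach).strip().upper()
    mode = mode or config.mode
    if mode not in ("recompute", "printed"):
        raise DomainError(f"mode must be 'recompute' or 'printed', got {mode!r}")

    pairs: list[PairedPrediction] = []
    audit: list[AuditRow] = []
    for i, rec in enumerate(records, start=1):
        recomputed = _recompute(rec, approach, config)
        printed = rec.printed_prediction(approach)
        if mode == "printed":
            if printed is None:
                raise DomainError(
                    f"printed mode requires printed_pred_{approach.lower()} "
                    f"(missing at row {i}: {rec.victim}-{rec.perpetrator})"
                )
            predicted = printed
        else:
            predicted = recomputed
        pairs.append(PairedPrediction(predicted=predicted, observed=rec.observed_aucr_pediatric))
        residual = (
            None
            if printed is None
            else abs(round_half_away(recomputed, config.rounding_decimals) - printed)
        )
        if residual is not None and residual > _AUDIT_THRESHOLD + 1e-9:
            audit.append(
                AuditRow(
                    index=i,
                    victim=rec.victim,
                    perpetrator=rec.perpetrator,
                    isoform=rec.isoform.value,
                    approach=approach,
                    printed=printed,
                    recomputed=recomputed,
                )
            )

    slope, intercept = ols_fit(pairs) if len(pairs) >= 2 else (float("nan"), float("nan"))
    return PerformanceSummary(
        approach=approach,
        n=len(pairs),
        gmfe=gmfe(pairs),
        mape_percent=mape(pairs),
        ols_slope=slope,
        ols_intercept=intercept,
        n_outside_twofold=sum(not within_twofold(p.predicted, p.observed) for p in pairs),
        n_outside_guest=sum(
            not within_guest(p.predicted, p.observed, config.guest_delta) for p in pairs
        ),
        guest_delta=config.guest_delta,
        per_record=tuple(pairs),
        audit=tuple(audit),
        mode=mode,
    )
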