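"""Validation of pipeline output against chart-review gold labels.

Computes the standard computable-phenotype validation statistics — positive
predictive value, sensitivity and specificity, expressed as percentages —
from a 2x2 cross-tabulation of algorithm predictions against adjudicated
gold labels, per target (PTL visit, fFN test, TVUS procedure, CL measure).

Cervical-length accounting has a third outcome besides yes/no: a predicted
measurement confirmed to exist but with a *different* value.  Such a record
counts against precision (an fp for PPV and specificity) but is excluded from
the sensitivity denominator, since the measurement itself was present and
detected.  Sensitivity and specificity are reported as not-estimated (``NE``)
when the review sample contains no predicted-negative records, as in a
positives-only validation sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

__all__ = [
    "GoldLabel",
    "Prediction",
    "ConfusionCounts",
    "build_confusion",
    "ppv",
    "sensitivity",
    "specificity",
    "metrics_row",
    "format_metric",
    "CL_VALUE_TOLERANCE_CM",
]

TARGETS = ("ptl", "ffn", "tvus", "cl")

#: predicted and gold CL values closer than this are "the same value"
CL_VALUE_TOLERANCE_CM = 0.05


@dataclass(frozen=True)
class GoldLabel:
    """Chart-review adjudication for one sampled visit."""

    visit_id: str
    ptl_confirmed: bool
    ffn_confirmed: bool = False
    tvus_confirmed: bool = False
    cl_gold_cm: float | None = None


@dataclass(frozen=True)
class Prediction:
    """Algorithm output for one visit, keyed like the gold labels."""

    visit_id: str
    ptl: bool = True
    ffn: bool = False
    tvus: bool = False
    cl_cm: float | None = None


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    value_mismatch: int = 0   # CL only: predicted & confirmed, different value

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn, self.value_mismatch) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn + self.value_mismatch

    @property
    def reviewed_negatives(self) -> int:
        """Records whose prediction was negative (the fn+tn arm)."""
        return self.fn + self.tn


def build_confusion(
    predictions: Mapping[str, Prediction] | Sequence[Prediction],
    gold: Sequence[GoldLabel],
    target: str,
    cl_tolerance_cm: float = CL_VALUE_TOLERANCE_CM,
) -> ConfusionCounts:
    """Cross-tabulate predictions against gold labels for one target.

    Every gold visit must have a prediction (unmatched keys raise).  For the
    ``cl`` target a predicted measurement whose confirmed gold value differs by
    more than *cl_tolerance_cm* increments ``value_mismatch`` instead of tp.
    """
    if target not in TARGETS:
        raise ValueError(f"unknown target {target!r}; expected one of {TARGETS}")
    if not isinstance(predictions, Mapping):
        predictions = {p.visit_id: p for p in predictions}
    tp = fp = fn = tn = mismatch = 0
    for g in gold:
        if g.visit_id not in predictions:
            raise KeyError(f"no prediction for gold visit {g.visit_id!r}")
        p = predictions[g.visit_id]
        if target == "cl":
            pred_yes, gold_yes = p.cl_cm is not None, g.cl_gold_cm is not None
            if pred_yes and gold_yes:
                if abs(p.cl_cm - g.cl_gold_cm) <= cl_tolerance_cm:
                    tp += 1
                else:
                    mismatch += 1
            elif pred_yes:
                fp += 1
            elif gold_yes:
                fn += 1
            else:
                tn += 1
        else:
            pred_yes = getattr(p, target)
            gold_yes = {
                "ptl": g.ptl_confirmed,
                "ffn": g.ffn_confirmed,
                "tvus": g.tvus_confirmed,
            }[target]
            tp += pred_yes and gold_yes
            fp += pred_yes and not gold_yes
            fn += not pred_yes and gold_yes
            tn += not pred_yes and not gold_yes
    return ConfusionCounts(tp, fp, fn, tn, mismatch)


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def ppv(c: ConfusionCounts) -> float | None:
    """Positive predictive value, percent; ``None`` (NE) on empty denominator.

    A value-mismatch record is a detected-but-wrong prediction: an fp here.
    """
    denom = c.tp + c.fp + c.value_mismatch
    if denom == 0:
        return None
    return _round2(100.0 * c.tp / denom)


def sensitivity(c: ConfusionCounts) -> float | None:
    """Sensitivity (recall), percent.

    NE when no predicted-negative records were reviewed (the false-negative
    arm was never sampled) or the denominator is empty.  Value-mismatch
    records are excluded from the denominator: the measurement was detected.
    """
    if c.reviewed_negatives == 0 or c.tp + c.fn == 0:
        return None
    return _round2(100.0 * c.tp / (c.tp + c.fn))


def specificity(c: ConfusionCounts) -> float | None:
    """Specificity, percent; value-mismatch records count as false positives.

    NE when no predicted-negative records were reviewed or the denominator is
    empty.
    """
    denom = c.tn + c.fp + c.value_mismatch
    if c.reviewed_negatives == 0 or denom == 0:
        return None
    return _round2(100.0 * c.tn / denom)


def metrics_row(c: ConfusionCounts) -> dict[str, float | None]:
    """PPV / sensitivity / specificity for one confusion table."""
    return {"ppv": ppv(c), "sensitivity": sensitivity(c), "specificity": specificity(c)}


def format_metric(value: float | None) -> str:
    """Display formatting: 2 decimals, trailing zeros trimmed, NE for None."""
    if value is None:
        return "NE"
    text = f"{value:.2f}".rstrip("0").rstrip(".")
    return text or "0"
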