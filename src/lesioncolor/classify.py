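"""Single-parameter threshold diagnosis with confusion-matrix reporting.

A rule such as "call MCC when a* ≥ 37" is evaluated against the recorded
diagnoses of a two-class cohort, yielding sensitivity, specificity,
accuracy, PPV and NPV. A scan over all candidate thresholds finds the
cutoff maximizing sensitivity + specificity and reports whether the two
classes are perfectly separable on that parameter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .features import PARAMETER_NAMES, PatientRecord

__all__ = ["ThresholdRule", "ConfusionReport", "apply_rule", "separation_scan"]

ABOVE = "above_is_positive"
BELOW = "below_is_positive"


@dataclass(frozen=True)
class ThresholdRule:
    """Classify by comparing one color parameter against a threshold.

    A value exactly at the threshold counts as positive.
    """

    parameter: str
    threshold: float
    direction: str = ABOVE
    positive_class: str = "MCC"

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETER_NAMES:
            raise ValueError(
                f"unknown parameter {self.parameter!r}; expected one of "
                f"{PARAMETER_NAMES}"
            )
        if self.direction not in (ABOVE, BELOW):
            raise ValueError(f"direction must be {ABOVE!r} or {BELOW!r}")

    def predicts_positive(self, value: float) -> bool:
        if self.direction == ABOVE:
            return value >= self.threshold
        return value <= self.threshold


def _pct(num: int, den: int) -> Optional[float]:
    return 100.0 * num / den if den else None


def _truncate1(value: float) -> float:
    return math.floor(value * 10) / 10


@dataclass(frozen=True)
class ConfusionReport:
    """Raw counts and derived diagnostic metrics (percentages).

    A metric whose denominator is zero is ``None`` and listed in
    ``undefined`` rather than silently reported as 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> Optional[float]:
        return _pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return _pct(self.tn, self.tn + self.fp)

    @property
    def accuracy(self) -> Optional[float]:
        return _pct(self.tp + self.tn, self.total)

    @property
    def ppv(self) -> Optional[float]:
        return _pct(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Optional[float]:
        return _pct(self.tn, self.tn + self.fn)

    @property
    def undefined(self) -> tuple[str, ...]:
        return tuple(
            name
            for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv")
            if getattr(self, name) is None
        )

    def display(self) -> dict[str, str]:
        """Metrics formatted at typical clinical-report precision:
        sensitivity/accuracy/NPV to the nearest percent, specificity
        truncated at one decimal, PPV at two decimals."""
        out: dict[str, str] = {}
        if self.sensitivity is not None:
            out["sensitivity"] = f"{round(self.sensitivity):g}%"
        if self.specificity is not None:
            out["specificity"] = f"{_truncate1(self.specificity):g}%"
        if self.accuracy is not None:
            out["accuracy"] = f"{round(self.accuracy):g}%"
        if self.ppv is not None:
            out["ppv"] = f"{round(self.ppv, 2):g}%"
        if self.npv is not None:
            out["npv"] = f"{round(self.npv):g}%"
        return out

    def to_json(self, rule: Optional[ThresholdRule] = None) -> str:
        payload: dict = {
            "counts": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "metrics": {
                name: getattr(self, name)
                for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv")
            },
            "display": self.display(),
            "undefined": list(self.undefined),
        }
        if rule is not None:
            payload["rule"] = {
                "parameter": rule.parameter,
                "threshold": rule.threshold,
                "direction": rule.direction,
                "positive_class": rule.positive_class,
            }
        return json.dumps(payload, indent=2)


def apply_rule(
    records: Sequence[PatientRecord], rule: ThresholdRule, negative_class: str
) -> ConfusionReport:
    """Evaluate a threshold rule on the records of two diagnosis classes."""
    tp = fp = tn = fn = 0
    seen = {rule.positive_class: 0, negative_class: 0}
    for rec in records:
        if rec.diagnosis not in (rule.positive_class, negative_class):
            continue
        seen[rec.diagnosis] += 1
        predicted_positive = rule.predicts_positive(rec.parameter(rule.parameter))
        actual_positive = rec.diagnosis == rule.positive_class
        if predicted_positive and actual_positive:
            tp += 1
        elif predicted_positive:
            fp += 1
        elif actual_positive:
            fn += 1
        else:
            tn += 1
    for dx, count in seen.items():
        if count == 0:
            raise ValueError(f"no records with diagnosis {dx!r}")
    return ConfusionReport(tp=tp, fp=fp, tn=tn, fn=fn)


def separation_scan(
    records: Sequence[PatientRecord],
    parameter: str,
    positive_class: str,
    negative_class: str,
) -> tuple[ThresholdRule, ConfusionReport, bool]:
    """Best single threshold on one parameter for separating two classes.

    Scans every midpoint between adjacent sorted values (both rule
    directions) and returns the rule maximizing sensitivity +
    specificity, its confusion report, and whether it separates the
    classes perfectly (sensitivity = specificity = 100%).
    """
    values = sorted(
        {
            rec.parameter(parameter)
            for rec in records
            if rec.diagnosis in (positive_class, negative_class)
        }
    )
    if not values:
        raise ValueError("no records in either class")
    candidates = [values[0] - 1.0]
    candidates += [(a + b) / 2 for a, b in zip(values, values[1:])]
    candidates += [values[-1] + 1.0]
    best: tuple[float, ThresholdRule, ConfusionReport] | None = None
    for direction in (ABOVE, BELOW):
        for thr in candidates:
            rule = ThresholdRule(parameter, thr, direction, positive_class)
            report = apply_rule(records, rule, negative_class)
            score = (report.sensitivity or 0.0) + (report.specificity or 0.0)
            if best is None or score > best[0]:
                best = (score, rule, report)
    _, rule, report = best
    perfect = report.sensitivity == 100.0 and report.specificity == 100.0
    return rule, report, perfect
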