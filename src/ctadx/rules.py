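"""Binary and staged (three-zone) stenosis/plaque-burden classification rules.

A staged rule splits the stenosis axis into three zones: below ``lower``
everything is negative, above ``upper`` everything is positive, and inside
the band ``[lower, upper]`` the call is made on plaque burden (PAV) against
``pav_threshold``.  A plain binary stenosis cutoff is the degenerate case
``upper < lower`` (empty band), so all rules evaluated here live in one
algebra.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

__all__ = [
    "StagedRule",
    "ConfusionMatrix",
    "classify_binary",
    "classify_staged",
    "classify_staged_array",
    "evaluate_rule",
    "MODEL1",
    "MODEL2",
    "MODEL3",
]


@dataclass(frozen=True)
class StagedRule:
    """Three-zone classifier ``(lower, upper, pav_threshold)``.

    ``upper`` may be ``math.inf`` (no rule-in zone).  ``upper < lower`` is
    permitted and denotes a pure binary cutoff at ``lower``.
    """

    lower: float
    upper: float
    pav_threshold: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower):
            raise ValueError(f"lower must be >= 0, got {self.lower}")
        if not (self.upper <= 100.0 or math.isinf(self.upper)):
            raise ValueError(f"upper must be <= 100 or +inf, got {self.upper}")
        if not (0.0 <= self.pav_threshold <= 100.0):
            raise ValueError(
                f"pav_threshold must be in [0, 100], got {self.pav_threshold}"
            )

    @property
    def is_degenerate(self) -> bool:
        """True when the band is empty and the rule is a pure stenosis cutoff."""
        return self.upper < self.lower

    @property
    def band_width(self) -> float:
        return max(self.upper - self.lower, 0.0)

    def to_dict(self) -> dict:
        upper = "inf" if math.isinf(self.upper) else self.upper
        return {"lower": self.lower, "upper": upper, "pav_threshold": self.pav_threshold}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "StagedRule":
        upper = d["upper"]
        if isinstance(upper, str):
            upper = math.inf if upper.lower() in ("inf", "+inf", "infinity") else float(upper)
        return cls(float(d["lower"]), float(upper), float(d["pav_threshold"]))

    @classmethod
    def parse(cls, text: str) -> "StagedRule":
        """Parse the CLI shorthand ``"lower:upper:pav"``, e.g. ``"30:70:12.2"``.

        ``upper`` accepts ``inf`` for an unbounded rule-in zone.
        """
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"rule must be 'lower:upper:pav', got {text!r}")
        lower = float(parts[0])
        upper = math.inf if parts[1].strip().lower() == "inf" else float(parts[1])
        return cls(lower, upper, float(parts[2]))


#: Named rules as evaluated in the analysis: plain >=50% stenosis; 50% gate
#: plus PAV >=16.8%; and the 30-70% band with in-band PAV >=12.2%.
MODEL1 = StagedRule(lower=50.0, upper=0.0, pav_threshold=0.0)
MODEL2 = StagedRule(lower=50.0, upper=math.inf, pav_threshold=16.8)
MODEL3 = StagedRule(lower=30.0, upper=70.0, pav_threshold=12.2)

NAMED_RULES = {"model1": MODEL1, "model2": MODEL2, "model3": MODEL3}


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts of a classification against the reference label."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        """Reference-positive count (column margin)."""
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


def classify_binary(stenosis: float, cutoff: float) -> bool:
    """Positive iff ``stenosis >= cutoff`` (inclusive at the cutoff)."""
    if not (0.0 < cutoff < 100.0):
        raise ValueError(f"cutoff must be in (0, 100), got {cutoff}")
    return bool(stenosis >= cutoff)


def classify_staged(stenosis: float, pav: float, rule: StagedRule) -> bool:
    """Apply a staged rule to one patient.

    Below the band -> negative; above -> positive; inside the (inclusive)
    band positive iff ``pav >= pav_threshold``.  Degenerate rules reduce to
    ``stenosis >= lower``.
    """
    if rule.is_degenerate:
        return bool(stenosis >= rule.lower)
    if stenosis < rule.lower:
        return False
    if stenosis > rule.upper:
        return True
    return bool(pav >= rule.pav_threshold)


def classify_staged_array(
    stenosis: np.ndarray, pav: np.ndarray, rule: StagedRule
) -> np.ndarray:
    """Vectorised :func:`classify_staged` over parallel arrays."""
    stenosis = np.asarray(stenosis, dtype=float)
    pav = np.asarray(pav, dtype=float)
    if rule.is_degenerate:
        return stenosis >= rule.lower
    return np.where(
        stenosis < rule.lower,
        False,
        np.where(stenosis > rule.upper, True, pav >= rule.pav_threshold),
    )


RuleLike = Union[StagedRule, float, int]


def _as_rule(rule: RuleLike) -> StagedRule:
    if isinstance(rule, StagedRule):
        return rule
    # a bare number is a binary stenosis cutoff
    cutoff = float(rule)
    if not (0.0 < cutoff < 100.0):
        raise ValueError(f"cutoff must be in (0, 100), got {cutoff}")
    return StagedRule(lower=cutoff, upper=0.0, pav_threshold=0.0)


def evaluate_rule(cohort: Sequence, rule: RuleLike) -> ConfusionMatrix:
    """Count a rule's classifications against the ischemia labels of a cohort.

    ``cohort`` is any sequence of records exposing ``stenosis``, ``pav`` and
    ``ischemia`` attributes.  ``rule`` may be a :class:`StagedRule` or a bare
    binary stenosis cutoff.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must not be empty")
    r = _as_rule(rule)
    stenosis = np.array([p.stenosis for p in cohort], dtype=float)
    pav = np.array([p.pav for p in cohort], dtype=float)
    labels = np.array([bool(p.ischemia) for p in cohort], dtype=bool)
    pred = classify_staged_array(stenosis, pav, r)
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
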