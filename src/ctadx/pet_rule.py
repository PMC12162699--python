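"""Reference-standard labelling from 17-segment stress perfusion.

Stress perfusion is abnormal when hyperaemic myocardial blood flow (MBF) is
at or below a threshold (default 2.30 mL/min/g) in at least two *adjacent*
segments of the AHA 17-segment polar map, excluding the basal septum
(taken here as segments 2 and 3).  The composite ischemic-CAD label is the
abnormality call for patients who underwent PET and negative for everyone
else (the selective-referral protocol labels unreferred patients
non-ischemic).

The segment adjacency of the polar map is not standardised anywhere, so the
default table below is an explicit, documented convention and is fully
injectable through :class:`PerfusionRuleConfig`:

* circumferential neighbours within each ring, with ring closure
  (basal 1-6, mid 7-12, apical 13-16);
* radial neighbours basal-mid aligned by sector (1-7 ... 6-12);
* mid-apical contacts by sector overlap: 7-13, 8-13, 8-14, 9-14, 10-15,
  11-15, 11-16, 12-16 (diagonal sector-boundary contacts 7-16 and 10-14
  deliberately excluded);
* the apex (17) touches all four apical segments.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Optional, Sequence, Tuple

__all__ = [
    "SegmentPerfusion",
    "PerfusionRuleConfig",
    "DEFAULT_ADJACENCY",
    "DEFAULT_THRESHOLD",
    "DEFAULT_EXCLUDED",
    "classify_perfusion",
    "abnormal_from_below_set",
    "assign_label",
    "read_perfusion_csv",
    "adjacency_from_json",
]

DEFAULT_THRESHOLD = 2.30
DEFAULT_EXCLUDED = frozenset({2, 3})

_EDGES = [
    # basal ring
    (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 1),
    # mid ring
    (7, 8), (8, 9), (9, 10), (10, 11), (11, 12), (12, 7),
    # apical ring
    (13, 14), (14, 15), (15, 16), (16, 13),
    # basal-mid radial
    (1, 7), (2, 8), (3, 9), (4, 10), (5, 11), (6, 12),
    # mid-apical by sector overlap
    (7, 13), (8, 13), (8, 14), (9, 14), (10, 15), (11, 15), (11, 16), (12, 16),
    # apex
    (13, 17), (14, 17), (15, 17), (16, 17),
]

DEFAULT_ADJACENCY: FrozenSet[FrozenSet[int]] = frozenset(
    frozenset(e) for e in _EDGES
)


@dataclass(frozen=True)
class SegmentPerfusion:
    """Hyperaemic MBF (mL/min/g) on AHA segments 1-17.

    ``mbf[i]`` is segment ``i + 1``.
    """

    mbf: Tuple[float, ...]

    def __post_init__(self) -> None:
        mbf = tuple(float(v) for v in self.mbf)
        object.__setattr__(self, "mbf", mbf)
        if len(mbf) != 17:
            raise ValueError(f"mbf must have exactly 17 values, got {len(mbf)}")
        for i, v in enumerate(mbf, start=1):
            if not math.isfinite(v) or v <= 0.0:
                raise ValueError(f"mbf for segment {i} must be finite and > 0, got {v}")

    def segment(self, number: int) -> float:
        if not 1 <= number <= 17:
            raise ValueError(f"segment number must be in 1..17, got {number}")
        return self.mbf[number - 1]


def _validate_adjacency(adjacency: Iterable) -> FrozenSet[FrozenSet[int]]:
    edges = set()
    for e in adjacency:
        pair = frozenset(int(x) for x in e)
        if len(pair) != 2:
            raise ValueError(f"adjacency edges must join two distinct segments, got {sorted(e)}")
        if not pair <= set(range(1, 18)):
            raise ValueError(f"adjacency edge outside segments 1..17: {sorted(pair)}")
        edges.add(pair)
    return frozenset(edges)


@dataclass(frozen=True)
class PerfusionRuleConfig:
    threshold: float = DEFAULT_THRESHOLD
    excluded_segments: FrozenSet[int] = DEFAULT_EXCLUDED
    adjacency: FrozenSet[FrozenSet[int]] = DEFAULT_ADJACENCY

    def __post_init__(self) -> None:
        if not (self.threshold > 0.0):
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        excluded = frozenset(int(s) for s in self.excluded_segments)
        if not excluded <= set(range(1, 18)):
            raise ValueError(f"excluded_segments must be within 1..17, got {sorted(excluded)}")
        object.__setattr__(self, "excluded_segments", excluded)
        object.__setattr__(self, "adjacency", _validate_adjacency(self.adjacency))


DEFAULT_CONFIG = PerfusionRuleConfig()


def abnormal_from_below_set(
    below: Iterable[int], config: PerfusionRuleConfig = DEFAULT_CONFIG
) -> bool:
    """Abnormality from the set of segments at or below threshold.

    True iff two distinct non-excluded below-threshold segments share an
    adjacency edge.  Monotone in ``below`` by construction.
    """
    eligible = set(below) - config.excluded_segments
    if len(eligible) < 2:
        return False
    return any(edge <= eligible for edge in config.adjacency)


def classify_perfusion(
    perfusion: SegmentPerfusion, config: PerfusionRuleConfig = DEFAULT_CONFIG
) -> bool:
    """Abnormal-perfusion call for one patient (threshold is inclusive: <=)."""
    below = {
        seg for seg in range(1, 18) if perfusion.segment(seg) <= config.threshold
    }
    return abnormal_from_below_set(below, config)


def assign_label(pet_performed: bool, abnormal: Optional[bool] = None) -> bool:
    """Composite ischemic-CAD label under the selective-referral protocol.

    Patients without PET are labelled non-ischemic; for patients with PET
    the label is the perfusion abnormality call.  ``abnormal`` must be
    supplied exactly when ``pet_performed``.
    """
    if pet_performed and abnormal is None:
        raise ValueError("abnormal is required when pet_performed is True")
    if not pet_performed and abnormal is not None:
        raise ValueError("abnormal must be absent when pet_performed is False")
    return bool(abnormal) if pet_performed else False


def read_perfusion_csv(path) -> dict:
    """Read ``patient_id,seg1..seg17`` rows into SegmentPerfusion objects."""
    expected = ["patient_id"] + [f"seg{i}" for i in range(1, 18)]
    out = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != expected:
            raise ValueError(
                f"perfusion CSV header must be {','.join(expected)}, got {reader.fieldnames}"
            )
        for row in reader:
            out[row["patient_id"]] = SegmentPerfusion(
                mbf=tuple(float(row[f"seg{i}"]) for i in range(1, 18))
            )
    return out


def adjacency_from_json(path) -> FrozenSet[FrozenSet[int]]:
    """Load an adjacency override from a JSON edge list ``[[i, j], ...]``."""
    with open(path, encoding="utf-8") as fh:
        edges = json.load(fh)
    return _validate_adjacency(edges)
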