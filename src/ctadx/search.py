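"""Youden-index cutpoint optimisation for staged stenosis/plaque rules.

Two searches are provided:

* :func:`youden_threshold_subgroup` — one-dimensional plaque-burden
  threshold selection inside a fixed stenosis band (how the 50%-gate and
  30-70%-band thresholds are derived);
* :func:`grid_search_staged` — the exhaustive three-parameter search over
  (lower, upper, pav_threshold), default grid 1..99% x 1..99% (upper >=
  lower) by 1% and 0.1..49.0% by 0.1% = 2,425,500 rules.

The grid search counts with 2-D cumulative case/control histograms instead
of re-scanning the cohort per rule.  Stenosis values are placed on a
*doubled* bin scale (2 x #edges <= value, minus parity for exact edge hits)
so that the strict comparisons ``stenosis < lower`` and ``stenosis > upper``
are answered exactly from cumulative sums even for off-grid inputs; plaque
thresholds index a suffix-cumulated axis.  All comparisons reduce to
``searchsorted`` against the same float grids a naive scan would use, so
results are bit-identical to per-rule enumeration.

Everything is deterministic; Youden ties are enumerated and broken by a
documented lexicographic preference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .rules import ConfusionMatrix, StagedRule

__all__ = [
    "GridSpec",
    "SearchResult",
    "ThresholdResult",
    "default_pav_grid",
    "youden_threshold_subgroup",
    "grid_search_staged",
    "refit_threshold_for_band",
    "j_surface",
]


def default_pav_grid() -> np.ndarray:
    """Plaque-burden candidate thresholds 0.1..49.0 by 0.1 (490 values)."""
    return np.arange(1, 491) / 10.0


def _default_stenosis_grid() -> np.ndarray:
    return np.arange(1, 100, dtype=float)


@dataclass(frozen=True)
class GridSpec:
    """Candidate grids for (lower, upper, pav_threshold)."""

    lower_values: np.ndarray = field(default_factory=_default_stenosis_grid)
    upper_values: np.ndarray = field(default_factory=_default_stenosis_grid)
    pav_values: np.ndarray = field(default_factory=default_pav_grid)

    def __post_init__(self) -> None:
        for name in ("lower_values", "upper_values", "pav_values"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size == 0:
                raise ValueError(f"{name} must be non-empty")
            if arr.ndim != 1 or np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, arr)

    @classmethod
    def default(cls) -> "GridSpec":
        return cls()

    @property
    def n_rules(self) -> int:
        """Number of (lower, upper, pav) rules with upper >= lower."""
        n_pairs = int(
            np.sum(
                self.upper_values[None, :] >= self.lower_values[:, None]
            )
        )
        return n_pairs * self.pav_values.size


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a one-dimensional plaque-threshold search."""

    threshold: float
    j: float
    cm: ConfusionMatrix
    sensitivity: float
    specificity: float


@dataclass
class SearchResult:
    best_rule: StagedRule
    best_j: float
    best_cm: ConfusionMatrix
    ties: List[StagedRule]
    grid_evaluated: int

    def to_dict(self) -> dict:
        return {
            "best_rule": self.best_rule.to_dict(),
            "best_j": self.best_j,
            "best_cm": self.best_cm.to_dict(),
            "n_ties": len(self.ties),
            "ties": [r.to_dict() for r in self.ties],
            "grid_evaluated": self.grid_evaluated,
        }


def _cohort_arrays(cohort: Sequence) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    stenosis = np.array([p.stenosis for p in cohort], dtype=float)
    pav = np.array([p.pav for p in cohort], dtype=float)
    labels = np.array([bool(p.ischemia) for p in cohort], dtype=bool)
    return stenosis, pav, labels


def _ge_counts(sorted_values: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """#values >= t for each t, via searchsorted on a pre-sorted array."""
    return sorted_values.size - np.searchsorted(sorted_values, thresholds, side="left")


def youden_threshold_subgroup(
    cohort: Sequence,
    subgroup_lower: float,
    subgroup_upper: float = math.inf,
    candidate_thresholds: Optional[np.ndarray] = None,
    objective: str = "subgroup",
) -> ThresholdResult:
    """Best plaque-burden threshold (by Youden's J) inside a stenosis band.

    The band ``[subgroup_lower, subgroup_upper]`` is inclusive at both
    ends; ``subgroup_upper`` may be ``inf``.  With ``objective="subgroup"``
    (default) J is computed on band members only, with
    ``objective="cohort"`` on the whole cohort under the staged rule
    ``(subgroup_lower, subgroup_upper, t)``.

    Ties on J are broken toward higher sensitivity, then the largest
    threshold, so the choice is deterministic.
    """
    if objective not in ("subgroup", "cohort"):
        raise ValueError(f"objective must be 'subgroup' or 'cohort', got {objective!r}")
    stenosis, pav, labels = _cohort_arrays(cohort)
    thresholds = (
        default_pav_grid()
        if candidate_thresholds is None
        else np.asarray(candidate_thresholds, dtype=float)
    )
    if thresholds.size == 0:
        raise ValueError("candidate_thresholds must be non-empty")
    band = (stenosis >= subgroup_lower) & (stenosis <= subgroup_upper)
    if not band.any():
        raise ValueError("subgroup is empty")
    band_cases = band & labels
    band_ctrls = band & ~labels
    if objective == "subgroup":
        if not band_cases.any():
            raise ValueError("subgroup contains no reference-positive patients")
        if not band_ctrls.any():
            raise ValueError("subgroup contains no reference-negative patients")
        n_case = int(band_cases.sum())
        n_ctrl = int(band_ctrls.sum())
        extra_tp = 0
        extra_fp = 0
    else:
        if not labels.any():
            raise ValueError("cohort contains no reference-positive patients")
        if labels.all():
            raise ValueError("cohort contains no reference-negative patients")
        n_case = int(labels.sum())
        n_ctrl = int((~labels).sum())
        above = stenosis > subgroup_upper
        extra_tp = int(np.sum(above & labels))
        extra_fp = int(np.sum(above & ~labels))

    case_pav = np.sort(pav[band_cases])
    ctrl_pav = np.sort(pav[band_ctrls])
    tp = extra_tp + _ge_counts(case_pav, thresholds)
    fp = extra_fp + _ge_counts(ctrl_pav, thresholds)
    se = tp / n_case
    sp = (n_ctrl - fp) / n_ctrl
    j = se + sp - 1.0

    best_j = j.max()
    at_best = j == best_j
    best_se = se[at_best].max()
    at_best &= se == best_se
    idx = int(np.flatnonzero(at_best)[-1])  # largest threshold among remaining ties

    cm = ConfusionMatrix(
        tp=int(tp[idx]),
        fp=int(fp[idx]),
        fn=n_case - int(tp[idx]),
        tn=n_ctrl - int(fp[idx]),
    )
    return ThresholdResult(
        threshold=float(thresholds[idx]),
        j=float(j[idx]),
        cm=cm,
        sensitivity=float(se[idx]),
        specificity=float(sp[idx]),
    )


def _doubled_bins(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Doubled-scale stenosis bin: (#edges < v) + (#edges <= v).

    For edge index k (0-based): ``v < edges[k]``  iff bin <= 2k and
    ``v > edges[k]`` iff bin >= 2k + 2; a value exactly at the edge sits at
    2k + 1.  This answers both strict band comparisons from one cumsum.
    """
    lt = np.searchsorted(edges, values, side="left")
    le = np.searchsorted(edges, values, side="right")
    return lt + le


def _cumulative_table(
    stenosis: np.ndarray, pav: np.ndarray, edges: np.ndarray, pav_grid: np.ndarray
) -> np.ndarray:
    """P[s, j] = #patients with doubled-bin <= s and pav >= pav_grid[j-1].

    Column 0 ignores pav (always-true threshold).
    """
    n_sbins = 2 * edges.size + 1
    n_p = pav_grid.size
    sbin = _doubled_bins(stenosis, edges)
    pbin = np.searchsorted(pav_grid, pav, side="right")  # #thresholds <= pav
    hist = np.zeros((n_sbins, n_p + 1), dtype=np.int64)
    np.add.at(hist, (sbin, pbin), 1)
    # suffix over pav axis: column j counts pbin >= j, i.e. pav >= grid[j-1]
    suffix = np.cumsum(hist[:, ::-1], axis=1)[:, ::-1]
    # prefix over the doubled stenosis axis
    return np.cumsum(suffix, axis=0)


def grid_search_staged(cohort: Sequence, spec: Optional[GridSpec] = None) -> SearchResult:
    """Exhaustive staged-rule search maximising whole-cohort Youden's J.

    Evaluates every (lower, upper, pav_threshold) with ``upper >= lower``.
    J comparisons are exact (integer count arithmetic), so the tie set is
    the true maximiser set.  Tie-break: higher specificity, then narrower
    band, then lower pav_threshold; ties are reported in (lower, upper,
    pav_threshold) order.
    """
    if spec is None:
        spec = GridSpec.default()
    stenosis, pav, labels = _cohort_arrays(cohort)
    if not labels.any():
        raise ValueError("cohort contains no reference-positive patients")
    if labels.all():
        raise ValueError("cohort contains no reference-negative patients")
    n_case = int(labels.sum())
    n_ctrl = int((~labels).sum())

    lows = spec.lower_values
    ups = spec.upper_values
    pgrid = spec.pav_values
    edges = np.unique(np.concatenate([lows, ups]))

    pc = _cumulative_table(stenosis[labels], pav[labels], edges, pgrid)
    pn = _cumulative_table(stenosis[~labels], pav[~labels], edges, pgrid)

    low_idx = np.searchsorted(edges, lows)  # exact positions in the edge list
    up_idx = np.searchsorted(edges, ups)

    pair_ok = ups[None, :] >= lows[:, None]
    ki, mi = np.nonzero(pair_ok)  # ordered by (lower, upper)
    lo_rows = 2 * low_idx[ki]  # doubled-bin row for "stenosis < lower"
    up_rows = 2 * up_idx[mi] + 1  # doubled-bin row for "stenosis <= upper"

    # above-band counts (stenosis > upper), any pav
    above_tp = n_case - pc[up_rows, 0]
    above_fp = n_ctrl - pn[up_rows, 0]
    # in-band counts with pav >= threshold, per threshold column
    tp = above_tp[:, None] + (pc[up_rows, 1:] - pc[lo_rows, 1:])
    fp = above_fp[:, None] + (pn[up_rows, 1:] - pn[lo_rows, 1:])

    # J maximisation on an exact integer scale:
    # J * n_case * n_ctrl + const  ==  tp * n_ctrl + tn * n_case
    score = tp * n_ctrl + (n_ctrl - fp) * n_case
    best_score = int(score.max())
    tie_pair, tie_j = np.nonzero(score == best_score)  # (lower, upper, pav) order

    tie_lower = lows[ki[tie_pair]]
    tie_upper = ups[mi[tie_pair]]
    tie_pav = pgrid[tie_j]
    tie_fp = fp[tie_pair, tie_j]
    # prefer higher specificity (lower fp), then narrower band, then lower pav
    order = np.lexsort((tie_pav, tie_upper - tie_lower, tie_fp))
    sel = order[0]

    ties = [
        StagedRule(float(lo), float(up), float(t))
        for lo, up, t in zip(tie_lower, tie_upper, tie_pav)
    ]
    best_rule = StagedRule(
        float(tie_lower[sel]), float(tie_upper[sel]), float(tie_pav[sel])
    )
    best_tp = int(tp[tie_pair[sel], tie_j[sel]])
    best_fp = int(tie_fp[sel])
    best_cm = ConfusionMatrix(
        tp=best_tp, fp=best_fp, fn=n_case - best_tp, tn=n_ctrl - best_fp
    )
    best_j = best_tp / n_case + (n_ctrl - best_fp) / n_ctrl - 1.0
    return SearchResult(
        best_rule=best_rule,
        best_j=float(best_j),
        best_cm=best_cm,
        ties=ties,
        grid_evaluated=int(ki.size) * pgrid.size,
    )


def refit_threshold_for_band(
    cohort: Sequence,
    band_lower: float,
    band_upper: float,
    candidate_thresholds: Optional[np.ndarray] = None,
    objective: str = "subgroup",
) -> StagedRule:
    """Fix a (possibly clinically rounded) band and refit its plaque threshold."""
    res = youden_threshold_subgroup(
        cohort,
        band_lower,
        band_upper,
        candidate_thresholds=candidate_thresholds,
        objective=objective,
    )
    return StagedRule(band_lower, band_upper, res.threshold)


def j_surface(cohort: Sequence, spec: Optional[GridSpec] = None):
    """Yield ``(lower, upper, pav_threshold, j)`` for every rule in the grid.

    Intended for heat-map style exports; rows come out in (lower, upper,
    pav_threshold) order.
    """
    if spec is None:
        spec = GridSpec.default()
    stenosis, pav, labels = _cohort_arrays(cohort)
    if not labels.any() or labels.all():
        raise ValueError("cohort must contain both label classes")
    n_case = int(labels.sum())
    n_ctrl = int((~labels).sum())
    lows = spec.lower_values
    ups = spec.upper_values
    pgrid = spec.pav_values
    edges = np.unique(np.concatenate([lows, ups]))
    pc = _cumulative_table(stenosis[labels], pav[labels], edges, pgrid)
    pn = _cumulative_table(stenosis[~labels], pav[~labels], edges, pgrid)
    low_idx = np.searchsorted(edges, lows)
    up_idx = np.searchsorted(edges, ups)
    for k, lo in enumerate(lows):
        for m, up in enumerate(ups):
            if up < lo:
                continue
            lo_row = 2 * low_idx[k]
            up_row = 2 * up_idx[m] + 1
            tp = (n_case - pc[up_row, 0]) + (pc[up_row, 1:] - pc[lo_row, 1:])
            fp = (n_ctrl - pn[up_row, 0]) + (pn[up_row, 1:] - pn[lo_row, 1:])
            j = tp / n_case - fp / n_ctrl
            for t, jv in zip(pgrid, j):
                yield float(lo), float(up), float(t), float(jv)
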