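"""End-to-end orchestration: simulate -> label -> classify -> evaluate -> search -> report.

Also reproduces the published six-row accuracy table (sensitivity,
specificity, PPV, NPV, accuracy, AUC for the three named rules) exactly
from the packaged confusion-matrix fixtures.  Fixture mode carries only
marginal counts, so paired between-rule p-values are reported as
unavailable there; on patient-level cohorts the full paired machinery is
used.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import metrics as _metrics
from .metrics import DiagnosticReport, metrics_from_cm
from .rules import NAMED_RULES, ConfusionMatrix, StagedRule, classify_staged_array, evaluate_rule
from .search import GridSpec, grid_search_staged, refit_threshold_for_band
from .synth import (
    GeneratorConfig,
    PatientRecord,
    generate_cohort,
    load_fixture_matrices,
    read_cohort_csv,
    write_cohort_csv,
)

__all__ = ["RunConfig", "run_table3", "run_full", "format_metric_table"]

SCHEMA_VERSION = 1

_METRIC_ROWS = [
    ("sensitivity", "Sensitivity"),
    ("specificity", "Specificity"),
    ("ppv", "PPV"),
    ("npv", "NPV"),
    ("accuracy", "Diagnostic accuracy"),
    ("auc", "AUC"),
]


def format_metric_table(reports: Dict[str, DiagnosticReport]) -> str:
    """Aligned text table with one row per metric and one column per rule."""
    names = list(reports)
    rounded = {name: reports[name].rounded() for name in names}
    width = max(len(label) for _, label in _METRIC_ROWS)
    col_w = 22
    lines = [" " * width + "  " + "".join(f"{n:>{col_w}}" for n in names)]
    for key, label in _METRIC_ROWS:
        cells = []
        for name in names:
            cell = rounded[name][key]
            if cell is None:
                cells.append("undefined")
            elif key == "auc":
                cells.append(
                    f"{cell['value']:.2f} ({cell['ci'][0]:.2f}-{cell['ci'][1]:.2f})"
                )
            else:
                cells.append(f"{cell['value']} ({cell['ci'][0]}-{cell['ci'][1]})")
        lines.append(f"{label:<{width}}  " + "".join(f"{c:>{col_w}}" for c in cells))
    return "\n".join(lines) + "\n"


def run_table3(
    fixtures: Optional[Dict[str, ConfusionMatrix]] = None, ci_level: float = 0.95
) -> dict:
    """Metric table for the three named rules from their count fixtures.

    Paired p-values cannot be recovered from marginal tables, so
    comparisons report point differences only.
    """
    if fixtures is None:
        fixtures = load_fixture_matrices()
    if not fixtures:
        raise ValueError("no fixtures supplied")
    reports = {name: metrics_from_cm(cm, ci_level) for name, cm in fixtures.items()}
    reference = "model1" if "model1" in reports else next(iter(reports))
    comparisons = {}
    for name, rep in reports.items():
        if name == reference:
            continue
        ref = reports[reference]
        comparisons[f"{name}_vs_{reference}"] = {
            "auc_difference": rep.auc.value - ref.auc.value,
            "sensitivity_difference": rep.sensitivity.value - ref.sensitivity.value,
            "specificity_difference": rep.specificity.value - ref.specificity.value,
            "p_values": None,
            "note": "paired p-values unavailable from marginal count fixtures",
        }
    return {
        "schema_version": SCHEMA_VERSION,
        "input": "fixtures",
        "models": {
            name: {
                "counts": fixtures[name].to_dict(),
                "metrics": reports[name].to_dict(),
                "rounded": reports[name].rounded(),
            }
            for name in fixtures
        },
        "comparisons": comparisons,
        "table": format_metric_table(reports),
    }


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``fixture``, ``cohort_csv`` or ``generator`` selects the
    input source.
    """

    fixture: bool = False
    cohort_csv: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    rules: Dict[str, StagedRule] = field(
        default_factory=lambda: dict(NAMED_RULES)
    )
    reference: str = "model1"
    ci_level: float = 0.95
    run_grid_search: bool = False
    grid: Optional[GridSpec] = None
    refit_band: Optional[tuple] = (30.0, 70.0)
    out_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        sources = sum([self.fixture, self.cohort_csv is not None, self.generator is not None])
        if sources != 1:
            raise ValueError("exactly one input source (fixture | cohort_csv | generator) required")
        if not self.rules and not self.fixture:
            raise ValueError("at least one rule required")
        if self.rules and self.reference not in self.rules and not self.fixture:
            raise ValueError(f"reference rule {self.reference!r} not among rules")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        kwargs = {}
        source = raw.get("input", {})
        kind = source.get("kind")
        if kind == "fixture":
            kwargs["fixture"] = True
        elif kind == "cohort_csv":
            kwargs["cohort_csv"] = source["path"]
        elif kind == "generator":
            gen_raw = dict(source.get("config", {}))
            kwargs["generator"] = GeneratorConfig(**gen_raw)
        else:
            raise ValueError(f"unknown input kind {kind!r}")
        if "rules" in raw:
            kwargs["rules"] = {
                name: NAMED_RULES[spec] if isinstance(spec, str) and spec in NAMED_RULES
                else StagedRule.parse(spec) if isinstance(spec, str)
                else StagedRule.from_dict(spec)
                for name, spec in raw["rules"].items()
            }
        for key in ("reference", "ci_level", "run_grid_search", "seed", "out_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        if "refit_band" in raw:
            band = raw["refit_band"]
            kwargs["refit_band"] = None if band is None else (float(band[0]), float(band[1]))
        return cls(**kwargs)


def _paired_comparisons(
    cohort: Sequence[PatientRecord],
    rules: Dict[str, StagedRule],
    reference: str,
) -> dict:
    stenosis = np.array([p.stenosis for p in cohort], dtype=float)
    pav = np.array([p.pav for p in cohort], dtype=float)
    labels = np.array([p.ischemia for p in cohort], dtype=bool)
    preds = {
        name: classify_staged_array(stenosis, pav, rule) for name, rule in rules.items()
    }
    ref_pred = preds[reference]
    out = {}
    for name, pred in preds.items():
        if name == reference:
            continue
        ppv_res, npv_res = _metrics.compare_predictive_values(pred, ref_pred, labels)
        out[f"{name}_vs_{reference}"] = {
            "sensitivity": _metrics.compare_sensitivity(pred, ref_pred, labels).to_dict(),
            "specificity": _metrics.compare_specificity(pred, ref_pred, labels).to_dict(),
            "ppv": ppv_res.to_dict(),
            "npv": npv_res.to_dict(),
            "auc": _metrics.compare_auc_binary(pred, ref_pred, labels).to_dict(),
        }
    return out


def run_full(config: RunConfig) -> dict:
    """Run the configured pipeline and return (and optionally write) the bundle.

    Deterministic for a fixed configuration: reports carry no timestamps
    and JSON output is key-sorted, so repeated runs are byte-identical.
    """
    if config.fixture:
        bundle = run_table3(ci_level=config.ci_level)
        _write_bundle(bundle, config.out_dir, cohort=None)
        return bundle

    if config.cohort_csv is not None:
        cohort = read_cohort_csv(config.cohort_csv)
        source = {"kind": "cohort_csv", "path": str(config.cohort_csv)}
    else:
        gen = config.generator  # the generator's own seed is authoritative
        cohort = generate_cohort(gen)
        source = {"kind": "generator", "n": gen.n_patients, "seed": gen.seed}

    reports = {}
    model_entries = {}
    for name, rule in config.rules.items():
        cm = evaluate_rule(cohort, rule)
        rep = metrics_from_cm(cm, config.ci_level)
        reports[name] = rep
        model_entries[name] = {
            "rule": rule.to_dict(),
            "counts": cm.to_dict(),
            "metrics": rep.to_dict(),
            "rounded": rep.rounded(),
        }

    comparisons = _paired_comparisons(cohort, config.rules, config.reference)

    searches = {}
    if config.refit_band is not None:
        lo, hi = config.refit_band
        refit = refit_threshold_for_band(cohort, lo, hi)
        refit_cm = evaluate_rule(cohort, refit)
        searches["refit_band"] = {
            "rule": refit.to_dict(),
            "counts": refit_cm.to_dict(),
            "metrics": metrics_from_cm(refit_cm, config.ci_level).to_dict(),
        }
    if config.run_grid_search:
        result = grid_search_staged(cohort, config.grid)
        searches["grid"] = {
            "best_rule": result.best_rule.to_dict(),
            "best_j": result.best_j,
            "best_cm": result.best_cm.to_dict(),
            "n_ties": len(result.ties),
            "grid_evaluated": result.grid_evaluated,
        }

    bundle = {
        "schema_version": SCHEMA_VERSION,
        "input": source,
        "n_patients": len(cohort),
        "models": model_entries,
        "comparisons": comparisons,
        "searches": searches,
        "table": format_metric_table(reports),
    }
    _write_bundle(bundle, config.out_dir, cohort=cohort)
    return bundle


def _write_bundle(bundle: dict, out_dir: Optional[str], cohort) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "report.txt", "w", encoding="utf-8") as fh:
        fh.write(bundle["table"])
    if cohort is not None:
        write_cohort_csv(cohort, out / "cohort.csv")
        # stenosis-vs-PAV scatter export for external plotting
        with open(out / "scatter.csv", "w", encoding="utf-8", newline="") as fh:
            fh.write("stenosis_pct,pav_pct,ischemia\n")
            for p in cohort:
                fh.write(f"{p.stenosis!r},{p.pav!r},{int(p.ischemia)}\n")
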