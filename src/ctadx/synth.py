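"""Synthetic cohorts with the joint structure the staged-rule analysis assumes.

The generator emulates the selective hybrid CTA->PET protocol:

1. per-patient maximum diameter stenosis from a two-component mixture
   (no/minimal-disease component plus a truncated-normal diseased
   component on [0, 100]);
2. plaque burden (PAV) tied to stenosis through a log-linear link with
   Gaussian noise, giving the monotone heteroscedastic stenosis-PAV
   scatter;
3. a latent ischemia state from a logistic model on (stenosis, PAV);
4. referral to PET when the *visually read* stenosis (quantitative
   stenosis plus truncated Gaussian misreading noise) reaches the referral
   cutoff;
5. the composite label: ischemic only if latent-ischemic AND referred.
   Unreferred patients are labelled non-ischemic regardless of latent
   state, which is exactly the verification-bias structure of the
   registry protocol.  The latent state is retained on each record so the
   bias can be studied.

All randomness flows from one seed through a single uniform matrix with a
fixed number of columns per record, so record ``i`` is a pure function of
``(seed, i)``: cohorts are reproducible and prefix-stable in ``n``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit

from .rules import ConfusionMatrix, StagedRule, classify_staged_array

__all__ = [
    "StenosisMixture",
    "PavLink",
    "IschemiaModel",
    "GeneratorConfig",
    "PatientRecord",
    "generate_cohort",
    "generate_planted_cohort",
    "compute_pav",
    "load_fixture_matrices",
    "write_cohort_csv",
    "read_cohort_csv",
]

COHORT_CSV_HEADER = [
    "patient_id",
    "stenosis_pct",
    "pav_pct",
    "ncpv_pct",
    "cpv_pct",
    "pet_performed",
    "ischemia",
]


@dataclass(frozen=True)
class StenosisMixture:
    """Two-component stenosis marginal on [0, 100] percent.

    A fraction ``healthy_fraction`` of patients draw from the no/minimal
    disease component, the rest from the diseased component; both are
    truncated normals on [0, 100].  Defaults bracket the reported group
    medians/IQRs (non-ischemic ~16 [7-31], ischemic ~64 [48-75]).
    """

    healthy_fraction: float = 0.70
    healthy_loc: float = 14.0
    healthy_scale: float = 13.0
    diseased_loc: float = 58.0
    diseased_scale: float = 18.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.healthy_fraction <= 1.0):
            raise ValueError(
                f"healthy_fraction must be in [0, 1], got {self.healthy_fraction}"
            )
        for name in ("healthy_scale", "diseased_scale"):
            if not (getattr(self, name) > 0.0):
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class PavLink:
    """log(PAV + epsilon) linear in stenosis with Gaussian noise."""

    intercept: float = 0.34
    slope: float = 0.040
    noise_sd: float = 0.60
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if not (self.noise_sd > 0.0):
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not (self.epsilon > 0.0):
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")


@dataclass(frozen=True)
class IschemiaModel:
    """Logistic latent-ischemia model on (stenosis, PAV)."""

    intercept: float = -8.0
    stenosis_coef: float = 0.13
    pav_coef: float = 0.07


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int = 2000
    stenosis_dist: StenosisMixture = field(default_factory=StenosisMixture)
    pav_link: PavLink = field(default_factory=PavLink)
    ischemia_coef: IschemiaModel = field(default_factory=IschemiaModel)
    visual_referral_cutoff: float = 50.0
    visual_noise_sd: float = 7.0
    calcified_frac_a: float = 1.2
    calcified_frac_b: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_patients, (int, np.integer)) and self.n_patients >= 1):
            raise ValueError(f"n_patients must be a positive integer, got {self.n_patients}")
        if not (0.0 < self.visual_referral_cutoff < 100.0):
            raise ValueError(
                f"visual_referral_cutoff must be in (0, 100), got {self.visual_referral_cutoff}"
            )
        if self.visual_noise_sd < 0.0:
            raise ValueError(f"visual_noise_sd must be >= 0, got {self.visual_noise_sd}")
        for name in ("calcified_frac_a", "calcified_frac_b"):
            if not (getattr(self, name) > 0.0):
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's quantitative CTA measures and labels.

    ``latent_ischemia`` is the simulation truth and is None for real data;
    the composite ``ischemia`` label is False for unreferred patients.
    """

    patient_id: str
    stenosis: float
    pav: float
    ncpv: float
    cpv: float
    pet_performed: bool
    ischemia: bool
    latent_ischemia: Optional[bool] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.stenosis <= 100.0):
            raise ValueError(f"stenosis must be in [0, 100], got {self.stenosis}")
        if not (0.0 <= self.pav <= 100.0):
            raise ValueError(f"pav must be in [0, 100], got {self.pav}")
        if self.ncpv < 0.0 or self.cpv < 0.0:
            raise ValueError("ncpv and cpv must be >= 0")
        if abs((self.ncpv + self.cpv) - self.pav) > 1e-9:
            raise ValueError(
                f"ncpv + cpv must equal pav within 1e-9 (got {self.ncpv + self.cpv} vs {self.pav})"
            )
        if self.ischemia and not self.pet_performed:
            raise ValueError("ischemia requires pet_performed (composite label)")


# number of uniform columns consumed per record; fixed so that record i is a
# pure function of (seed, i) regardless of n_patients
_N_UNIFORM_COLS = 6


def _draw_measures(config: GeneratorConfig):
    rng = np.random.default_rng(config.seed)
    u = rng.random((config.n_patients, _N_UNIFORM_COLS))

    mix = config.stenosis_dist
    diseased = u[:, 0] >= mix.healthy_fraction
    loc = np.where(diseased, mix.diseased_loc, mix.healthy_loc)
    scale = np.where(diseased, mix.diseased_scale, mix.healthy_scale)
    a = (0.0 - loc) / scale
    b = (100.0 - loc) / scale
    stenosis = stats.truncnorm.ppf(u[:, 1], a, b, loc=loc, scale=scale)
    stenosis = np.clip(stenosis, 0.0, 100.0)

    link = config.pav_link
    log_pav = (
        link.intercept
        + link.slope * stenosis
        + link.noise_sd * stats.norm.ppf(u[:, 2])
    )
    pav = np.clip(np.exp(log_pav) - link.epsilon, 0.0, 100.0)

    calc_frac = stats.beta.ppf(u[:, 5], config.calcified_frac_a, config.calcified_frac_b)
    cpv = calc_frac * pav
    ncpv = pav - cpv
    return u, stenosis, pav, ncpv, cpv


def _referral(config: GeneratorConfig, stenosis: np.ndarray, u_col: np.ndarray) -> np.ndarray:
    if config.visual_noise_sd == 0.0:
        visual = stenosis
    else:
        visual = np.clip(
            stenosis + config.visual_noise_sd * stats.norm.ppf(u_col), 0.0, 100.0
        )
    return visual >= config.visual_referral_cutoff


def _records(
    stenosis, pav, ncpv, cpv, pet, ischemia, latent
) -> List[PatientRecord]:
    return [
        PatientRecord(
            patient_id=f"P{i:06d}",
            stenosis=float(stenosis[i]),
            pav=float(pav[i]),
            ncpv=float(ncpv[i]),
            cpv=float(cpv[i]),
            pet_performed=bool(pet[i]),
            ischemia=bool(ischemia[i]),
            latent_ischemia=bool(latent[i]),
        )
        for i in range(stenosis.size)
    ]


def generate_cohort(config: GeneratorConfig) -> List[PatientRecord]:
    """Generate a cohort under the selective-referral protocol.

    Deterministic given ``config`` (including the seed).
    """
    u, stenosis, pav, ncpv, cpv = _draw_measures(config)
    coef = config.ischemia_coef
    logit = coef.intercept + coef.stenosis_coef * stenosis + coef.pav_coef * pav
    latent = u[:, 3] < expit(logit)
    pet = _referral(config, stenosis, u[:, 4])
    ischemia = latent & pet
    return _records(stenosis, pav, ncpv, cpv, pet, ischemia, latent)


def generate_planted_cohort(
    config: GeneratorConfig, rule: StagedRule, flip_prob: float = 0.0
) -> List[PatientRecord]:
    """Cohort whose labels are a planted staged rule's output plus label noise.

    The latent state is the rule's classification XOR an independent flip
    with probability ``flip_prob``.  Every patient is treated as referred
    (``pet_performed`` True) so the planted rule is recoverable without
    verification-bias distortion; use :func:`generate_cohort` for the
    selective protocol.
    """
    if not (0.0 <= flip_prob < 0.5):
        raise ValueError(f"flip_prob must be in [0, 0.5), got {flip_prob}")
    u, stenosis, pav, ncpv, cpv = _draw_measures(config)
    planted = classify_staged_array(stenosis, pav, rule)
    flips = u[:, 3] < flip_prob
    latent = planted ^ flips
    pet = np.ones(stenosis.size, dtype=bool)
    return _records(stenosis, pav, ncpv, cpv, pet, latent, latent)


def compute_pav(total_plaque_volume: float, vessel_volume: float) -> float:
    """Plaque burden: total plaque volume as a percent of vessel volume."""
    if vessel_volume <= 0.0:
        raise ValueError(f"vessel_volume must be > 0, got {vessel_volume}")
    if total_plaque_volume < 0.0 or total_plaque_volume > vessel_volume:
        raise ValueError(
            "total_plaque_volume must be in [0, vessel_volume], got "
            f"{total_plaque_volume} / {vessel_volume}"
        )
    return 100.0 * total_plaque_volume / vessel_volume


def load_fixture_matrices() -> Dict[str, ConfusionMatrix]:
    """Packaged published confusion matrices, keyed model1/model2/model3."""
    text = resources.files("ctadx").joinpath("data/fixtures_v1.json").read_text("utf-8")
    payload = json.loads(text)
    return {
        name: ConfusionMatrix(**counts)
        for name, counts in payload["matrices"].items()
    }


def write_cohort_csv(cohort: Sequence[PatientRecord], path) -> None:
    """Write the exact cohort schema (booleans as 0/1, RFC 4180, UTF-8)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_CSV_HEADER)
        for p in cohort:
            writer.writerow(
                [
                    p.patient_id,
                    repr(p.stenosis),
                    repr(p.pav),
                    repr(p.ncpv),
                    repr(p.cpv),
                    int(p.pet_performed),
                    int(p.ischemia),
                ]
            )


def read_cohort_csv(path) -> List[PatientRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != COHORT_CSV_HEADER:
            raise ValueError(
                f"cohort CSV header must be {','.join(COHORT_CSV_HEADER)}, "
                f"got {reader.fieldnames}"
            )
        return [
            PatientRecord(
                patient_id=row["patient_id"],
                stenosis=float(row["stenosis_pct"]),
                pav=float(row["pav_pct"]),
                ncpv=float(row["ncpv_pct"]),
                cpv=float(row["cpv_pct"]),
                pet_performed=bool(int(row["pet_performed"])),
                ischemia=bool(int(row["ischemia"])),
            )
            for row in reader
        ]
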