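"""Synthetic cohort generator for detector-validation studies.

Emulates an opportunistic-CT screening cohort: per-patient vertebral fracture
truth (levels + Genant grades), two independent radiologist readings drawn
from a pool of three plus a senior adjudicator, a patient-level binary index
test (positive / negative / non-evaluable), and a demographics table.  The
default parameters reproduce, in expectation, the marginal distributions of a
1200-patient chest/abdomen CT validation cohort: prevalence 227/1087,
highest-grade mix 90/81/56, multiplicity split 112/115, non-evaluable rate
113/1200, detector per-grade sensitivity (42/90, 60/81, 47/56) and false
positive rate 82/860.

Reproducibility: every patient has an independent substream derived from the
root seed, so cohorts are byte-identical for the same (config, seed) and the
first k patients do not change when n_patients grows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .adjudicate import VertebralReading
from .levels import LEVELS, N_LEVELS

# Radiologist-positive counts per level (T1..L5) from the validation study's
# per-level table; the default level weights are this vector normalised.
LEVEL_COUNTS_ANY = np.array(
    [2, 3, 8, 9, 20, 25, 29, 50, 32, 34, 62, 70, 64, 35, 19, 12, 8], dtype=float
)

READER_POOL = ("R1", "R2", "R3")
SENIOR_ID = "SENIOR"

AGE_BINS = ((50, 60), (61, 70), (71, 80), (81, 90), (91, 102))
REGIONS = ("chest", "abdomen_pelvis", "both")


def _default_confusion() -> np.ndarray:
    # rows: true grade 0..3; cols: reported grade 0..3.  Row 0 gives the
    # per-level reader false-positive channel; rows 1-3 the grade blur around
    # the truth (off-diagonal mass concentrated on adjacent grades).
    return np.array(
        [
            [0.997, 0.002, 0.0008, 0.0002],
            [0.08, 0.76, 0.14, 0.02],
            [0.03, 0.12, 0.70, 0.15],
            [0.01, 0.03, 0.16, 0.80],
        ]
    )


def _senior_confusion() -> np.ndarray:
    return np.array(
        [
            [0.999, 0.0008, 0.0001, 0.0001],
            [0.02, 0.93, 0.045, 0.005],
            [0.01, 0.04, 0.90, 0.05],
            [0.005, 0.01, 0.05, 0.935],
        ]
    )


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Probabilities are per patient unless noted.  ``detector_sens_by_grade``
    is indexed by the patient's most severe fracture (mild, moderate,
    severe); the detector operates at the patient level only.
    """

    n_patients: int = 1200
    prevalence_any: float = 227 / 1087
    grade_mix: tuple[float, float, float] = (90 / 227, 81 / 227, 56 / 227)
    multi_fracture_prob: float = 115 / 227
    extra_fracture_geom_p: float = 0.45
    level_weights: tuple[float, ...] = tuple(LEVEL_COUNTS_ANY / LEVEL_COUNTS_ANY.sum())
    detector_sens_by_grade: tuple[float, float, float] = (42 / 90, 60 / 81, 47 / 56)
    detector_fpr: float = 82 / 860
    nonevaluable_rate: float = 113 / 1200
    rater_presence_agreement: float = 0.90
    rater_grade_confusion: tuple = tuple(map(tuple, _default_confusion()))
    senior_presence_agreement: float = 0.97
    senior_grade_confusion: tuple = tuple(map(tuple, _senior_confusion()))
    perfect_senior: bool = False
    female_fraction: float = 588 / 1087
    age_bin_weights: tuple[float, ...] = (154, 311, 345, 215, 62)
    region_weights: tuple[float, float, float] = (962 / 1200, 169 / 1200, 69 / 1200)
    prior_vcf_prob: float = 100 / 1200
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError(f"n_patients must be >= 0, got {self.n_patients}")
        probs = {
            "prevalence_any": self.prevalence_any,
            "multi_fracture_prob": self.multi_fracture_prob,
            "detector_fpr": self.detector_fpr,
            "nonevaluable_rate": self.nonevaluable_rate,
            "rater_presence_agreement": self.rater_presence_agreement,
            "senior_presence_agreement": self.senior_presence_agreement,
            "female_fraction": self.female_fraction,
            "prior_vcf_prob": self.prior_vcf_prob,
        }
        for g, s in zip(("mild", "moderate", "severe"), self.detector_sens_by_grade):
            probs[f"detector_sens_by_grade[{g}]"] = s
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        if not 0.0 < self.extra_fracture_geom_p <= 1.0:
            raise ValueError("extra_fracture_geom_p must be in (0, 1]")
        if len(self.grade_mix) != 3 or abs(sum(self.grade_mix) - 1.0) > 1e-12:
            raise ValueError(f"grade_mix must be a probability triple summing to 1, got {self.grade_mix}")
        if len(self.level_weights) != N_LEVELS or abs(sum(self.level_weights) - 1.0) > 1e-12:
            raise ValueError("level_weights must be a 17-vector summing to 1")
        if min(self.grade_mix) < 0 or min(self.level_weights) < 0:
            raise ValueError("grade_mix and level_weights must be non-negative")
        for label, mat in (
            ("rater_grade_confusion", np.asarray(self.rater_grade_confusion, float)),
            ("senior_grade_confusion", np.asarray(self.senior_grade_confusion, float)),
        ):
            if mat.shape != (4, 4) or (mat < 0).any():
                raise ValueError(f"{label} must be a non-negative 4x4 matrix")
            if np.abs(mat.sum(axis=1) - 1.0).max() > 1e-12:
                raise ValueError(f"{label} rows must each sum to 1")
        if len(self.age_bin_weights) != len(AGE_BINS) or min(self.age_bin_weights) < 0:
            raise ValueError("age_bin_weights must be 5 non-negative weights")
        if len(self.region_weights) != 3 or min(self.region_weights) < 0:
            raise ValueError("region_weights must be 3 non-negative weights")

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, (tuple, list)):
                return [plain(x) for x in v]
            if isinstance(v, bool) or isinstance(v, (np.bool_,)):
                return bool(v)
            if isinstance(v, (int, np.integer)):
                return int(v)
            if isinstance(v, (float, np.floating)):
                return float(v)
            return v

        return {k: plain(v) for k, v in dataclasses.asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                if isinstance(v, list):
                    v = tuple(tuple(r) if isinstance(r, list) else r for r in v)
                kwargs[f.name] = v
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def default_config(**overrides) -> CohortConfig:
    """The study-condition defaults (see module docstring); keyword overrides
    are applied and the result validated."""
    cfg = dataclasses.replace(CohortConfig(), **overrides)
    cfg.validate()
    return cfg


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth fracture set for one patient: level -> grade (1-3)."""

    patient_id: str
    fractures: dict[str, int] = field(default_factory=dict)

    @property
    def any_vcf(self) -> bool:
        return len(self.fractures) > 0

    @property
    def max_grade(self) -> int:
        return max(self.fractures.values(), default=0)

    @property
    def n_fractures(self) -> int:
        return len(self.fractures)


@dataclass(frozen=True)
class IndexResult:
    patient_id: str
    result: str  # positive | negative | non_evaluable

    def __post_init__(self) -> None:
        if self.result not in ("positive", "negative", "non_evaluable"):
            raise ValueError(f"invalid index result {self.result!r}")


@dataclass
class Cohort:
    config: CohortConfig
    truth: list[TruthRecord]
    readings: list[VertebralReading]  # two primary readings per patient
    senior: list[VertebralReading]  # one senior reading per patient
    index: list[IndexResult]
    demographics: pd.DataFrame


def _patient_rng(seed: int, i: int) -> np.random.Generator:
    # per-patient substream: stable under changes to n_patients
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, i))))


def _sample_cat(rng: np.random.Generator, cum: np.ndarray) -> int:
    return int(np.searchsorted(cum, rng.random(), side="right"))


def _perturb_reading(
    truth: dict[str, int],
    rng: np.random.Generator,
    agreement: float,
    conf_cum: np.ndarray,
    identity: bool,
) -> dict[str, int]:
    """One reader's noisy view of the truth.

    Each true fracture is detected with probability ``agreement`` and, if
    detected, re-graded through the confusion row of its true grade (a drawn
    grade of 0 is a further miss).  Fracture-free levels pass through row 0,
    giving reader false positives.
    """
    if identity:
        return dict(truth)
    findings: dict[str, int] = {}
    for level, g in truth.items():
        if rng.random() >= agreement:
            continue
        rep = _sample_cat(rng, conf_cum[g])
        if rep:
            findings[level] = rep
    # false-positive channel over the fracture-free levels
    p_fp = 1.0 - conf_cum[0, 0]
    free = [lv for lv in LEVELS if lv not in truth]
    if p_fp > 0.0 and free:
        n_fp = rng.binomial(len(free), p_fp)
        if n_fp:
            picks = rng.choice(len(free), size=n_fp, replace=False)
            # grade conditional on being a false positive
            tail = np.diff(conf_cum[0]) / p_fp
            tail_cum = np.cumsum(tail)
            for j in picks:
                findings[free[j]] = 1 + _sample_cat(rng, tail_cum)
    return findings


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full synthetic cohort (truth, readings, index test, demographics)."""
    config.validate()
    grade_cum = np.cumsum(config.grade_mix)
    weights = np.asarray(config.level_weights, float)
    conf = np.asarray(config.rater_grade_confusion, float)
    conf_cum = np.cumsum(conf, axis=1)
    sconf = np.asarray(config.senior_grade_confusion, float)
    sconf_cum = np.cumsum(sconf, axis=1)
    rater_identity = (
        config.rater_presence_agreement == 1.0 and np.array_equal(conf, np.eye(4))
    )
    senior_identity = config.perfect_senior or (
        config.senior_presence_agreement == 1.0 and np.array_equal(sconf, np.eye(4))
    )
    age_w = np.asarray(config.age_bin_weights, float)
    age_cum = np.cumsum(age_w / age_w.sum())
    region_w = np.asarray(config.region_weights, float)
    region_cum = np.cumsum(region_w / region_w.sum())

    truth: list[TruthRecord] = []
    readings: list[VertebralReading] = []
    senior: list[VertebralReading] = []
    index: list[IndexResult] = []
    demo_rows = []

    width = max(4, len(str(max(config.n_patients, 1))))
    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i)
        pid = f"P{i + 1:0{width}d}"

        # --- truth ---
        fractures: dict[str, int] = {}
        if rng.random() < config.prevalence_any:
            gmax = 1 + _sample_cat(rng, grade_cum)
            if rng.random() < config.multi_fracture_prob:
                extra = rng.geometric(config.extra_fracture_geom_p) - 1
                count = min(2 + int(extra), N_LEVELS)
            else:
                count = 1
            lv_idx = rng.choice(N_LEVELS, size=count, replace=False, p=weights)
            fractures[LEVELS[lv_idx[0]]] = gmax
            if count > 1 and gmax == 1:
                for j in lv_idx[1:]:
                    fractures[LEVELS[j]] = 1
            elif count > 1:
                sub = np.asarray(config.grade_mix[:gmax], float)
                sub_cum = np.cumsum(sub / sub.sum())
                for j in lv_idx[1:]:
                    fractures[LEVELS[j]] = 1 + _sample_cat(rng, sub_cum)
        rec = TruthRecord(pid, fractures)
        truth.append(rec)

        # --- two primary readers from the pool of three ---
        r_idx = rng.choice(len(READER_POOL), size=2, replace=False)
        for ridx in r_idx:
            f = _perturb_reading(
                fractures, rng, config.rater_presence_agreement, conf_cum, rater_identity
            )
            readings.append(VertebralReading(pid, READER_POOL[ridx], f))

        # --- senior (adjudicator) reading ---
        sf = _perturb_reading(
            fractures, rng, config.senior_presence_agreement, sconf_cum, senior_identity
        )
        senior.append(VertebralReading(pid, SENIOR_ID, sf))

        # --- index test (patient level; keyed to most severe fracture) ---
        u_ne, u_det = rng.random(), rng.random()
        if u_ne < config.nonevaluable_rate:
            res = "non_evaluable"
        elif rec.any_vcf:
            res = "positive" if u_det < config.detector_sens_by_grade[rec.max_grade - 1] else "negative"
        else:
            res = "positive" if u_det < config.detector_fpr else "negative"
        index.append(IndexResult(pid, res))

        # --- demographics ---
        sex = "F" if rng.random() < config.female_fraction else "M"
        b = _sample_cat(rng, age_cum)
        lo, hi = AGE_BINS[b]
        age = int(rng.integers(lo, hi + 1))
        region = REGIONS[_sample_cat(rng, region_cum)]
        prior = int(rng.random() < config.prior_vcf_prob)
        demo_rows.append((pid, age, sex, region, prior))

    demographics = pd.DataFrame(
        demo_rows, columns=["patient_id", "age_years", "sex", "region", "prior_vcf"]
    )
    return Cohort(config, truth, readings, senior, index, demographics)


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write the three flat input tables (readings / index / demographics).

    Readings include the two primary readers and the senior adjudicator
    (reader id ``SENIOR``); a reader with no findings contributes one row
    with level ``NONE`` and grade 0 so every (patient, reader) pair appears.
    """
    from . import io  # local import to avoid a cycle

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "readings": directory / "readings.csv",
        "index": directory / "index.csv",
        "demographics": directory / "demographics.csv",
    }
    io.write_readings(cohort.readings + cohort.senior, paths["readings"])
    io.write_index(cohort.index, paths["index"])
    io.write_demographics(cohort.demographics, paths["demographics"])
    return paths
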