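"""Adjudicated radiologist reference standard.

Each CT study is read independently by two neuroradiologists who record, per
flagged vertebra, the level (T1..T12, L1..L5) and a Genant semiquantitative
grade (1 mild, 2 moderate, 3 severe).  Any difference between the two
readings — in fracture presence, grade, or location — is resolved by a senior
reader whose reading becomes the final (consensus) diagnosis.  The consensus
is then summarised per patient into the reference standard used to score the
index test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .levels import LEVELS, validate_findings


@dataclass(frozen=True)
class VertebralReading:
    """One reader's finding set for one patient.

    ``findings`` maps vertebral level code -> Genant grade (1-3).  An empty
    mapping means the reader saw no fracture.
    """

    patient_id: str
    reader_id: str
    findings: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_findings(self.findings)
        object.__setattr__(self, "findings", dict(self.findings))

    @property
    def any_vcf(self) -> bool:
        return len(self.findings) > 0

    @property
    def max_grade(self) -> int:
        return max(self.findings.values(), default=0)


@dataclass(frozen=True)
class DisagreementFlags:
    """Which of the three adjudication triggers fired between two readings."""

    presence: bool
    grade: bool
    location: bool

    @property
    def any(self) -> bool:
        return self.presence or self.grade or self.location


@dataclass(frozen=True)
class PatientReference:
    """Adjudicated truth summary for one patient."""

    patient_id: str
    any_vcf: bool
    max_grade: int
    n_fractures: int
    per_level: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_findings(self.per_level)
        object.__setattr__(self, "per_level", dict(self.per_level))
        if self.any_vcf != (self.n_fractures >= 1) or self.any_vcf != (self.max_grade >= 1):
            raise ValueError(
                f"inconsistent summary for {self.patient_id}: "
                f"any={self.any_vcf}, max_grade={self.max_grade}, n={self.n_fractures}"
            )
        if self.n_fractures != len(self.per_level):
            raise ValueError(
                f"n_fractures={self.n_fractures} != |per_level|={len(self.per_level)} "
                f"for {self.patient_id}"
            )


def detect_disagreement(a: VertebralReading, b: VertebralReading) -> DisagreementFlags:
    """Compare two readings of the same patient.

    presence: one reader calls any fracture and the other none.
    location: the sets of flagged levels differ (presence implies location).
    grade:    some shared level carries different grades, or the locations
              differ (a level graded by one reader only counts as both a
              location and a grade discordance).
    """
    if a.patient_id != b.patient_id:
        raise ValueError(f"readings refer to different patients: {a.patient_id!r} vs {b.patient_id!r}")
    levels_a, levels_b = set(a.findings), set(b.findings)
    presence = a.any_vcf != b.any_vcf
    location = levels_a != levels_b
    grade = location or any(a.findings[lv] != b.findings[lv] for lv in levels_a & levels_b)
    return DisagreementFlags(presence=presence, grade=grade, location=location)


def adjudicate(
    a: VertebralReading,
    b: VertebralReading,
    senior: VertebralReading | None = None,
) -> dict[str, int]:
    """Resolve a pair of readings into the consensus finding set.

    If the two primary readings agree exactly the consensus is that reading
    and the senior reader is never consulted.  On any disagreement the
    senior's entire reading becomes the consensus.
    """
    flags = detect_disagreement(a, b)
    if not flags.any:
        return dict(a.findings)
    if senior is None:
        raise ValueError(
            f"patient {a.patient_id}: readings disagree "
            f"(presence={flags.presence}, grade={flags.grade}, location={flags.location}) "
            "but no senior reading was provided"
        )
    if senior.patient_id != a.patient_id:
        raise ValueError(
            f"senior reading is for {senior.patient_id!r}, expected {a.patient_id!r}"
        )
    return dict(senior.findings)


def patient_summary(patient_id: str, consensus: Mapping[str, int]) -> PatientReference:
    """Summarise a consensus finding set into the per-patient reference."""
    consensus = dict(consensus)
    return PatientReference(
        patient_id=patient_id,
        any_vcf=len(consensus) > 0,
        max_grade=max(consensus.values(), default=0),
        n_fractures=len(consensus),
        per_level=consensus,
    )


def build_reference(
    readings: Iterable[VertebralReading],
    senior_id: str = "SENIOR",
) -> tuple[list[PatientReference], dict]:
    """Adjudicate a whole cohort of readings.

    ``readings`` holds, per patient, exactly two primary readings and
    (optionally) one reading by the senior reader ``senior_id``.  Returns the
    per-patient references in first-appearance order plus a stats dict
    (patients, adjudicated count, per-flag disagreement counts).
    """
    by_patient: dict[str, dict[str, list[VertebralReading] | VertebralReading | None]] = {}
    order: list[str] = []
    primaries: dict[str, list[VertebralReading]] = {}
    seniors: dict[str, VertebralReading] = {}
    for r in readings:
        if r.patient_id not in primaries:
            primaries[r.patient_id] = []
            order.append(r.patient_id)
        if r.reader_id == senior_id:
            seniors[r.patient_id] = r
        else:
            primaries[r.patient_id].append(r)

    refs: list[PatientReference] = []
    stats = {"n_patients": 0, "n_adjudicated": 0, "presence": 0, "grade": 0, "location": 0}
    for pid in order:
        pair = primaries[pid]
        if len(pair) != 2:
            raise ValueError(f"patient {pid}: expected exactly 2 primary readings, got {len(pair)}")
        a, b = pair
        flags = detect_disagreement(a, b)
        consensus = adjudicate(a, b, seniors.get(pid))
        refs.append(patient_summary(pid, consensus))
        stats["n_patients"] += 1
        if flags.any:
            stats["n_adjudicated"] += 1
        for name in ("presence", "grade", "location"):
            stats[name] += int(getattr(flags, name))
    return refs, stats
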