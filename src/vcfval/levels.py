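"""Vertebral level vocabulary (thoracic T1-T12, lumbar L1-L5) and Genant grades."""

from __future__ import annotations

from typing import Mapping

LEVELS: tuple[str, ...] = tuple(f"T{i}" for i in range(1, 13)) + tuple(
    f"L{i}" for i in range(1, 6)
)
N_LEVELS = len(LEVELS)
LEVEL_INDEX: dict[str, int] = {lv: i for i, lv in enumerate(LEVELS)}

GRADES = (1, 2, 3)
GRADE_LABELS = {0: "none", 1: "mild", 2: "moderate", 3: "severe"}

# sentinel used in readings.csv for a reader who flagged nothing
NO_FINDING = "NONE"


def validate_findings(findings: Mapping[str, int]) -> None:
    """Check a level -> grade mapping against the vocabulary (at most one
    grade per level is structural in a dict)."""
    for level, grade in findings.items():
        if level not in LEVEL_INDEX:
            raise ValueError(f"unknown vertebral level {level!r}")
        if grade not in GRADES:
            raise ValueError(f"grade must be 1, 2 or 3; got {grade!r} at {level}")
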