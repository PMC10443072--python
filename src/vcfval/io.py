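"""Readers/writers for the flat study tables.

Schemas
-------
readings.csv:      patient_id, reader_id, level, grade
                   (one row per flagged vertebra; a reader with no findings
                   appears once with level=NONE, grade=0)
index.csv:         patient_id, result in {positive, negative, non_evaluable}
demographics.csv:  patient_id, age_years, sex in {F, M},
                   region in {chest, abdomen_pelvis, both}, prior_vcf in {0, 1}
reference.csv:     patient_id, any_vcf, max_grade, n_fractures, one column
                   per vertebral level with grade 0-3
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .adjudicate import PatientReference, VertebralReading
from .cohort import IndexResult
from .levels import LEVELS, NO_FINDING


def write_readings(readings: Iterable[VertebralReading], path: str | Path) -> None:
    rows = []
    for r in readings:
        if r.findings:
            for level in sorted(r.findings, key=LEVELS.index):
                rows.append((r.patient_id, r.reader_id, level, r.findings[level]))
        else:
            rows.append((r.patient_id, r.reader_id, NO_FINDING, 0))
    pd.DataFrame(rows, columns=["patient_id", "reader_id", "level", "grade"]).to_csv(
        path, index=False
    )


def read_readings(path: str | Path) -> list[VertebralReading]:
    df = pd.read_csv(path, dtype={"patient_id": str, "reader_id": str, "level": str})
    _require_columns(df, ["patient_id", "reader_id", "level", "grade"], path)
    out: list[VertebralReading] = []
    grouped: dict[tuple[str, str], dict[str, int]] = {}
    order: list[tuple[str, str]] = []
    for row in df.itertuples(index=False):
        key = (row.patient_id, row.reader_id)
        if key not in grouped:
            grouped[key] = {}
            order.append(key)
        if row.level == NO_FINDING:
            if int(row.grade) != 0:
                raise ValueError(f"{path}: level NONE must carry grade 0 ({key})")
            continue  # canonicalised to the empty finding set
        grouped[key][row.level] = int(row.grade)
    for pid, rid in order:
        out.append(VertebralReading(pid, rid, grouped[(pid, rid)]))
    return out


def write_index(index: Iterable[IndexResult], path: str | Path) -> None:
    pd.DataFrame(
        [(r.patient_id, r.result) for r in index], columns=["patient_id", "result"]
    ).to_csv(path, index=False)


def read_index(path: str | Path) -> list[IndexResult]:
    df = pd.read_csv(path, dtype={"patient_id": str, "result": str})
    _require_columns(df, ["patient_id", "result"], path)
    return [IndexResult(r.patient_id, r.result) for r in df.itertuples(index=False)]


def write_demographics(demographics: pd.DataFrame, path: str | Path) -> None:
    cols = ["patient_id", "age_years", "sex", "region", "prior_vcf"]
    _require_columns(demographics, cols, path)
    demographics[cols].to_csv(path, index=False)


def read_demographics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "sex": str, "region": str})
    _require_columns(df, ["patient_id", "age_years", "sex", "region", "prior_vcf"], path)
    bad_sex = set(df["sex"]) - {"F", "M"}
    if bad_sex:
        raise ValueError(f"{path}: invalid sex values {sorted(bad_sex)}")
    bad_region = set(df["region"]) - {"chest", "abdomen_pelvis", "both"}
    if bad_region:
        raise ValueError(f"{path}: invalid region values {sorted(bad_region)}")
    return df


def write_reference(refs: Sequence[PatientReference], path: str | Path) -> None:
    rows = []
    for r in refs:
        row = {
            "patient_id": r.patient_id,
            "any_vcf": int(r.any_vcf),
            "max_grade": r.max_grade,
            "n_fractures": r.n_fractures,
        }
        for lv in LEVELS:
            row[lv] = r.per_level.get(lv, 0)
        rows.append(row)
    cols = ["patient_id", "any_vcf", "max_grade", "n_fractures", *LEVELS]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_reference(path: str | Path) -> list[PatientReference]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, ["patient_id", "any_vcf", "max_grade", "n_fractures", *LEVELS], path)
    refs = []
    for row in df.itertuples(index=False):
        per_level = {lv: int(getattr(row, lv)) for lv in LEVELS if int(getattr(row, lv)) > 0}
        refs.append(
            PatientReference(
                patient_id=row.patient_id,
                any_vcf=bool(row.any_vcf),
                max_grade=int(row.max_grade),
                n_fractures=int(row.n_fractures),
                per_level=per_level,
            )
        )
    return refs


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
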