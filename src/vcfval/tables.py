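"""Dichotomisation rules and 2x2 cross-tabulation of reference vs index test.

The adjudicated reference is dichotomised at configurable severity
thresholds (any fracture; moderate-or-severe; severe; two-or-more
fractures) and cross-tabulated against the patient-level binary index test.
Non-evaluable index results are excluded from the counts (the primary
analysis base) and tallied separately so the inclusive re-analysis can add
them back.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .adjudicate import PatientReference
from .cohort import IndexResult
from .levels import LEVELS


class ComparisonRule(str, Enum):
    """Reference-positive definitions (each against everything below it)."""

    ANY = "any"
    MODERATE_OR_SEVERE = "moderate_or_severe"
    SEVERE = "severe"
    TWO_OR_MORE = "two_or_more"

    def predicate(self, ref: PatientReference) -> bool:
        if self is ComparisonRule.ANY:
            return ref.max_grade >= 1
        if self is ComparisonRule.MODERATE_OR_SEVERE:
            return ref.max_grade >= 2
        if self is ComparisonRule.SEVERE:
            return ref.max_grade == 3
        return ref.n_fractures >= 2


@dataclass(frozen=True)
class Table2x2:
    """TP/FN/FP/TN counts for one dichotomisation rule.

    Cells count algorithm-evaluable patients only; ``n_excluded_nonevaluable``
    records how many were set aside.
    """

    tp: int
    fn: int
    fp: int
    tn: int
    rule: ComparisonRule | None = None
    n_excluded_nonevaluable: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("2x2 cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_reference_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_test_positive(self) -> int:
        return self.tp + self.fp


def _index_map(index: Iterable[IndexResult]) -> dict[str, str]:
    return {r.patient_id: r.result for r in index}


def build_table(
    refs: Sequence[PatientReference],
    index: Iterable[IndexResult],
    rule: ComparisonRule,
) -> Table2x2:
    """Cross-tabulate the reference (dichotomised by ``rule``) against the
    index test, excluding non-evaluable patients from the counts."""
    rule = ComparisonRule(rule)
    imap = _index_map(index)
    missing = [r.patient_id for r in refs if r.patient_id not in imap]
    if missing:
        raise ValueError(
            f"{len(missing)} reference patients missing from the index table: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    tp = fn = fp = tn = excluded = 0
    for ref in refs:
        res = imap[ref.patient_id]
        if res == "non_evaluable":
            excluded += 1
            continue
        pos = rule.predicate(ref)
        test_pos = res == "positive"
        if pos and test_pos:
            tp += 1
        elif pos:
            fn += 1
        elif test_pos:
            fp += 1
        else:
            tn += 1
    return Table2x2(tp, fn, fp, tn, rule=rule, n_excluded_nonevaluable=excluded)


def all_tables(
    refs: Sequence[PatientReference], index: Iterable[IndexResult]
) -> dict[ComparisonRule, Table2x2]:
    index = list(index)
    return {rule: build_table(refs, index, rule) for rule in ComparisonRule}


def vertebral_sensitivity_table(
    refs: Sequence[PatientReference],
    index: Iterable[IndexResult],
    min_grade: int = 1,
) -> pd.DataFrame:
    """Per-level reference-positive and algorithm-positive counts.

    A level is reference-positive for a patient when the consensus carries a
    fracture of grade >= ``min_grade`` at that level (the level's own grade,
    not the patient's maximum).  The index test is patient-level, so the
    "algorithm positive" column counts, among the level's reference-positive
    patients, those whose whole-patient index result is positive — a
    cross-level construct, not per-level detector accuracy.  Multi-fracture
    patients contribute to every fractured level; non-evaluable patients are
    excluded.
    """
    if min_grade not in (1, 2):
        raise ValueError(f"min_grade must be 1 or 2, got {min_grade}")
    imap = _index_map(index)
    n_ref = {lv: 0 for lv in LEVELS}
    n_pos = {lv: 0 for lv in LEVELS}
    for ref in refs:
        res = imap.get(ref.patient_id)
        if res is None:
            raise ValueError(f"patient {ref.patient_id} missing from the index table")
        if res == "non_evaluable":
            continue
        for lv, grade in ref.per_level.items():
            if grade >= min_grade:
                n_ref[lv] += 1
                if res == "positive":
                    n_pos[lv] += 1
    return pd.DataFrame(
        {
            "level": list(LEVELS),
            "n_reference_positive": [n_ref[lv] for lv in LEVELS],
            "n_algo_positive": [n_pos[lv] for lv in LEVELS],
        }
    ).set_index("level")


def tables_to_frame(tables: dict[ComparisonRule, Table2x2]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rule": rule.value,
                "tp": t.tp,
                "fn": t.fn,
                "fp": t.fp,
                "tn": t.tn,
                "n_excluded_nonevaluable": t.n_excluded_nonevaluable,
            }
            for rule, t in tables.items()
        ]
    )


def frame_to_tables(df: pd.DataFrame) -> dict[ComparisonRule, Table2x2]:
    out = {}
    for row in df.itertuples(index=False):
        rule = ComparisonRule(row.rule)
        out[rule] = Table2x2(
            int(row.tp),
            int(row.fn),
            int(row.fp),
            int(row.tn),
            rule=rule,
            n_excluded_nonevaluable=int(getattr(row, "n_excluded_nonevaluable", 0)),
        )
    return out
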