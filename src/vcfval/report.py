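"""End-to-end orchestration: adjudication -> tables -> accuracy -> reliability.

``run_pipeline`` consumes the three flat input tables (readings, index,
demographics), builds the adjudicated reference, cross-tabulates it against
the index test under all four dichotomisation rules, computes operating
characteristics with exact CIs and likelihood ratios, the per-level
sensitivity table, the non-evaluable-inclusive sensitivity, and the
inter-rater ICC suite, and renders everything into a ``StudyReport`` plus
CSV artifacts.  Regenerating from identical inputs yields byte-identical
output (no timestamps; fixed formatting; seeded bootstrap).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io
from .accuracy import (
    accuracy_summary,
    inclusive_sensitivity,
    likelihood_ratios,
)
from .adjudicate import PatientReference, build_reference
from .cohort import Cohort, IndexResult
from .reliability import ICCEstimate, icc_suite
from .tables import (
    ComparisonRule,
    Table2x2,
    all_tables,
    tables_to_frame,
    vertebral_sensitivity_table,
)

log = logging.getLogger("vcfval")


@dataclass
class StudyReport:
    cohort_summary: pd.DataFrame
    fracture_distribution: pd.DataFrame
    tables: dict[ComparisonRule, Table2x2]
    vertebral: dict[int, pd.DataFrame]  # min_grade -> per-level table
    accuracy: pd.DataFrame
    reliability: pd.DataFrame | None
    adjudication_stats: dict
    provenance: dict = field(default_factory=dict)

    def render(self) -> str:
        lines = ["# Study report", ""]
        lines += ["## Cohort", self.cohort_summary.to_string(index=False), ""]
        lines += ["## Fracture distribution (evaluable patients)",
                  self.fracture_distribution.to_string(index=False), ""]
        lines += ["## Index test vs reference (2x2 tables)",
                  tables_to_frame(self.tables).to_string(index=False), ""]
        lines += ["## Operating characteristics",
                  self.accuracy.to_string(index=False), ""]
        for mg, vt in self.vertebral.items():
            label = "any grade" if mg == 1 else "moderate or severe"
            lines += [f"## Per-level sensitivity ({label})",
                      vt.reset_index().to_string(index=False), ""]
        if self.reliability is not None:
            lines += ["## Inter-rater reliability (ICC)",
                      self.reliability.to_string(index=False), ""]
        lines += ["## Provenance",
                  json.dumps(self.provenance, indent=2, sort_keys=True), ""]
        return "\n".join(lines)


def _fmt(x: float) -> float:
    return float(f"{x:.6g}")


def accuracy_frame(
    tables: dict[ComparisonRule, Table2x2],
    level: float = 0.95,
    n_total: int | None = None,
) -> pd.DataFrame:
    """Long-format accuracy table: one row per (rule, statistic)."""
    rows = []
    for rule, t in tables.items():
        summ = accuracy_summary(t, level=level)
        for name, est in summ.items():
            if est is None:
                continue
            rows.append(
                dict(rule=rule.value, statistic=name, numerator=est.numerator,
                     denominator=est.denominator, point=_fmt(est.point),
                     ci_low=_fmt(est.ci_low), ci_high=_fmt(est.ci_high),
                     method=est.method)
            )
        if t.tp + t.fn > 0 and t.fp + t.tn > 0:
            for name, est in likelihood_ratios(t, level=level).items():
                rows.append(
                    dict(rule=rule.value, statistic=name, numerator=pd.NA,
                         denominator=pd.NA, point=_fmt(est.point),
                         ci_low=_fmt(est.ci_low), ci_high=_fmt(est.ci_high),
                         method=est.method + ("+cc" if est.continuity_corrected else ""))
                )
        if n_total is not None and t.tp + t.fn > 0:
            n_eval = t.n
            est = inclusive_sensitivity(t, n_total=n_total, n_evaluable=n_eval, level=level)
            rows.append(
                dict(rule=rule.value, statistic="inclusive_sensitivity",
                     numerator=est.numerator, denominator=est.denominator,
                     point=_fmt(est.point), ci_low=_fmt(est.ci_low),
                     ci_high=_fmt(est.ci_high), method=est.method)
            )
    return pd.DataFrame(rows)


def reliability_frame(estimates: dict[str, ICCEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(outcome=name, sigma2_subject=_fmt(e.sigma2_subject),
                 sigma2_resid=_fmt(e.sigma2_resid), icc=_fmt(e.icc),
                 ci_low=_fmt(e.ci_low), ci_high=_fmt(e.ci_high),
                 n_boot=e.n_boot, seed=e.seed)
            for name, e in estimates.items()
        ]
    )


def _cohort_summary(demographics: pd.DataFrame | None, n_total: int, n_eval: int) -> pd.DataFrame:
    rows = [("total_patients", n_total), ("algorithm_evaluable", n_eval),
            ("non_evaluable", n_total - n_eval)]
    if demographics is not None and len(demographics):
        rows.append(("female", int((demographics["sex"] == "F").sum())))
        rows.append(("median_age", float(demographics["age_years"].median())))
    return pd.DataFrame(rows, columns=["characteristic", "value"])


def _fracture_distribution(refs: list[PatientReference], index: list[IndexResult]) -> pd.DataFrame:
    ne = {r.patient_id for r in index if r.result == "non_evaluable"}
    ev = [r for r in refs if r.patient_id not in ne]
    algo_pos = sum(
        1 for r in index if r.result == "positive" and r.patient_id not in ne
    )
    rows = [
        ("algorithm_positive", algo_pos),
        ("radiologist_any_vcf", sum(r.any_vcf for r in ev)),
        ("no_fracture", sum(not r.any_vcf for r in ev)),
        ("one_fracture", sum(r.n_fractures == 1 for r in ev)),
        ("two_or_more", sum(r.n_fractures >= 2 for r in ev)),
        ("highest_grade_mild", sum(r.max_grade == 1 for r in ev)),
        ("highest_grade_moderate", sum(r.max_grade == 2 for r in ev)),
        ("highest_grade_severe", sum(r.max_grade == 3 for r in ev)),
    ]
    return pd.DataFrame(rows, columns=["characteristic", "count"])


def run_pipeline(
    readings=None,
    index=None,
    demographics: pd.DataFrame | None = None,
    *,
    refs: list[PatientReference] | None = None,
    cohort: Cohort | None = None,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
    with_reliability: bool = True,
    out_dir: str | Path | None = None,
    senior_id: str = "SENIOR",
) -> StudyReport:
    """Run the full validation analysis.

    Inputs are either a ``Cohort``, or readings+index(+demographics), or
    pre-adjudicated ``refs``+index.  Artifacts (reference.csv, table3.csv,
    table4.csv, accuracy.csv, reliability.csv, report.txt) are written to
    ``out_dir`` when given, only after the whole analysis has succeeded.
    """
    if cohort is not None:
        readings = cohort.readings + cohort.senior
        index = cohort.index
        demographics = cohort.demographics
    if index is None:
        raise ValueError("an index-result table is required")
    index = list(index)

    adjudication_stats: dict = {}
    if refs is None:
        if readings is None:
            raise ValueError("either readings or pre-built references are required")
        refs, adjudication_stats = build_reference(list(readings), senior_id=senior_id)
        log.info("adjudicated %d patients (%d disagreements resolved)",
                 adjudication_stats["n_patients"], adjudication_stats["n_adjudicated"])

    n_total = len(refs)
    tables = all_tables(refs, index)
    n_eval = tables[ComparisonRule.ANY].n
    log.info("cohort: %d patients, %d evaluable, %d non-evaluable excluded",
             n_total, n_eval, n_total - n_eval)

    acc = accuracy_frame(tables, level=level, n_total=n_total)
    vertebral = {
        1: vertebral_sensitivity_table(refs, index, min_grade=1),
        2: vertebral_sensitivity_table(refs, index, min_grade=2),
    }

    rel_frame = None
    if with_reliability and readings is not None:
        primaries = [r for r in readings if r.reader_id != senior_id]
        if primaries:
            rel = icc_suite(primaries, n_boot=n_boot, seed=seed)
            rel_frame = reliability_frame(rel)

    provenance = {
        "software": "vcfval",
        "version": __version__,
        "seed": seed,
        "confidence_level": level,
        "n_boot": n_boot,
        "inputs_sha256": _inputs_hash(refs, index),
    }
    if cohort is not None:
        provenance["config_sha256"] = hashlib.sha256(
            json.dumps(cohort.config.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    report = StudyReport(
        cohort_summary=_cohort_summary(demographics, n_total, n_eval),
        fracture_distribution=_fracture_distribution(refs, index),
        tables=tables,
        vertebral=vertebral,
        accuracy=acc,
        reliability=rel_frame,
        adjudication_stats=adjudication_stats,
        provenance=provenance,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        io.write_reference(refs, out_dir / "reference.csv")
        tables_to_frame(tables).to_csv(out_dir / "table3.csv", index=False)
        t4 = pd.concat(
            [vt.reset_index().assign(min_grade=mg) for mg, vt in vertebral.items()]
        )
        t4.to_csv(out_dir / "table4.csv", index=False)
        acc.to_csv(out_dir / "accuracy.csv", index=False)
        if rel_frame is not None:
            rel_frame.to_csv(out_dir / "reliability.csv", index=False)
        (out_dir / "report.txt").write_text(report.render())
    return report


def _inputs_hash(refs, index) -> str:
    h = hashlib.sha256()
    for r in refs:
        h.update(repr((r.patient_id, sorted(r.per_level.items()))).encode())
    for r in index:
        h.update(f"{r.patient_id}:{r.result}".encode())
    return h.hexdigest()
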