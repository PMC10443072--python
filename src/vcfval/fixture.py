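"""Deterministic benchmark cohort reproducing the validation study's margins.

Constructs, by constraint satisfaction (no sampling), a 1200-patient dataset
that simultaneously satisfies every printed marginal of the motivating
validation study:

* 113 non-evaluable index results; 1087 evaluable;
* 227 fractured patients (highest grade 90 mild / 81 moderate / 56 severe;
  112 with one fracture, 115 with two or more) and 860 fracture-free;
* the four 2x2 tables — any (149/78/82/778), moderate-or-severe
  (107/30/124/826), severe (47/9/184/847), two-or-more (90/25/141/831) —
  hence 231 algorithm-positive patients;
* the per-level (reference-positive, algorithm-positive) counts for both the
  any-grade and the moderate-or-severe columns of the per-level table.

Construction: differencing the cumulative severity tables fixes the joint
distribution of (highest grade x algorithm result): mild 42+/48-, moderate
60+/21-, severe 47+/9-.  The two-or-more table fixes (multiplicity x
algorithm result): multi 90+/25-, single 59+/53-.  Singles are assigned
mild-first, so all multi-fracture patients are moderate/severe.  Within each
algorithm stratum the per-level slots (split grade>=2 vs grade 1 by the two
table columns) are dealt greedily from the thoracolumbar junction outward:
grade>=2 anchor slots first (grade 3 for severe patients, 2 for moderate),
then remaining slots to the multi-fracture patient with the fewest vertebrae
that does not already occupy the level.  The result is verified against all
margins on load; any violation raises ``FixtureError``.
"""

from __future__ import annotations

from .adjudicate import PatientReference
from .cohort import IndexResult
from .levels import LEVELS

# per-level (reference-positive, algorithm-positive) counts, T1..L5
TABLE_LEVEL_ANY = {
    "T1": (2, 1), "T2": (3, 2), "T3": (8, 4), "T4": (9, 5), "T5": (20, 13),
    "T6": (25, 17), "T7": (29, 20), "T8": (50, 32), "T9": (32, 25),
    "T10": (34, 28), "T11": (62, 46), "T12": (70, 52), "L1": (64, 53),
    "L2": (35, 31), "L3": (19, 15), "L4": (12, 10), "L5": (8, 5),
}
TABLE_LEVEL_MODSEV = {
    "T1": (0, 0), "T2": (0, 0), "T3": (4, 2), "T4": (3, 3), "T5": (8, 8),
    "T6": (10, 7), "T7": (14, 12), "T8": (24, 17), "T9": (15, 12),
    "T10": (10, 10), "T11": (27, 25), "T12": (48, 38), "L1": (35, 30),
    "L2": (22, 19), "L3": (10, 9), "L4": (6, 6), "L5": (2, 2),
}

# 2x2 tables: rule -> (tp, fn, fp, tn)
TABLE_2X2 = {
    "any": (149, 78, 82, 778),
    "moderate_or_severe": (107, 30, 124, 826),
    "severe": (47, 9, 184, 847),
    "two_or_more": (90, 25, 141, 831),
}

N_TOTAL = 1200
N_EVALUABLE = 1087
N_NONEVALUABLE = 113

# deal levels from the thoracolumbar junction outward
_LEVEL_ORDER = (
    "T12", "L1", "T11", "L2", "T10", "L3", "T9", "L4", "T8", "L5",
    "T7", "T6", "T5", "T4", "T3", "T2", "T1",
)


class FixtureError(ValueError):
    """The printed margins could not be satisfied simultaneously."""


def _grade_by_algo() -> dict[str, dict[int, int]]:
    """(algorithm result -> highest grade -> patient count) by differencing
    the three cumulative severity tables."""
    tp_any, fn_any = TABLE_2X2["any"][:2]
    tp_ms, fn_ms = TABLE_2X2["moderate_or_severe"][:2]
    tp_sev, fn_sev = TABLE_2X2["severe"][:2]
    pos = {3: tp_sev, 2: tp_ms - tp_sev, 1: tp_any - tp_ms}
    neg = {3: fn_sev, 2: fn_ms - fn_sev, 1: fn_any - fn_ms}
    if min(*pos.values(), *neg.values()) < 0:
        raise FixtureError("cumulative severity tables are not nested")
    return {"positive": pos, "negative": neg}


class _Patient:
    __slots__ = ("max_grade", "multi", "algo", "fractures")

    def __init__(self, max_grade: int, multi: bool, algo: str):
        self.max_grade = max_grade
        self.multi = multi
        self.algo = algo
        self.fractures: dict[str, int] = {}


def _build_stratum(algo: str, grade_counts: dict[int, int], n_single: int,
                   n_multi: int) -> list[_Patient]:
    """Construct one algorithm stratum's fractured patients and deal their
    vertebral levels from the per-level slot pools."""
    if algo == "positive":
        ge2_pool = {lv: TABLE_LEVEL_MODSEV[lv][1] for lv in LEVELS}
        g1_pool = {
            lv: TABLE_LEVEL_ANY[lv][1] - TABLE_LEVEL_MODSEV[lv][1] for lv in LEVELS
        }
    else:
        ge2_pool = {
            lv: TABLE_LEVEL_MODSEV[lv][0] - TABLE_LEVEL_MODSEV[lv][1] for lv in LEVELS
        }
        g1_pool = {
            lv: (TABLE_LEVEL_ANY[lv][0] - TABLE_LEVEL_MODSEV[lv][0])
            - (TABLE_LEVEL_ANY[lv][1] - TABLE_LEVEL_MODSEV[lv][1])
            for lv in LEVELS
        }
    if min(g1_pool.values()) < 0:
        raise FixtureError(f"level table columns inconsistent in {algo} stratum")

    # multiplicity assignment: singles mild-first, then moderate, then severe
    order = [1] * grade_counts[1] + [2] * grade_counts[2] + [3] * grade_counts[3]
    if n_single + n_multi != len(order):
        raise FixtureError(
            f"{algo} stratum: multiplicity split ({n_single}+{n_multi}) does not "
            f"match grade total ({len(order)})"
        )
    singles = [_Patient(g, False, algo) for g in order[:n_single]]
    multis = [_Patient(g, True, algo) for g in order[n_single:]]

    def pop(pool: dict[str, int]) -> str:
        for lv in _LEVEL_ORDER:
            if pool[lv] > 0:
                pool[lv] -= 1
                return lv
        raise FixtureError(f"{algo} stratum: ran out of level slots")

    # anchor vertebra at the patient's own maximum grade
    for p in singles + multis:
        if p.max_grade >= 2:
            p.fractures[pop(ge2_pool)] = p.max_grade
        else:
            p.fractures[pop(g1_pool)] = 1

    # distribute the leftover slots among multi-fracture patients: fewest
    # vertebrae first, never twice at one level; extra grade>=2 slots are
    # graded 2 (every multi patient here is moderate or severe)
    leftovers = [(lv, 2) for lv in _LEVEL_ORDER for _ in range(ge2_pool[lv])]
    leftovers += [(lv, 1) for lv in _LEVEL_ORDER for _ in range(g1_pool[lv])]
    for lv, grade in leftovers:
        cands = [p for p in multis if lv not in p.fractures]
        if grade == 2:
            cands = [p for p in cands if p.max_grade >= 2]
        if not cands:
            raise FixtureError(f"{algo} stratum: no patient can absorb a slot at {lv}")
        target = min(cands, key=lambda p: len(p.fractures))
        target.fractures[lv] = grade
    short = [p for p in multis if len(p.fractures) < 2]
    if short:
        raise FixtureError(
            f"{algo} stratum: {len(short)} multi-fracture patients received < 2 levels"
        )
    return singles + multis


def load_study_fixture() -> tuple[list[PatientReference], list[IndexResult]]:
    """The 1200-patient benchmark dataset (see module docstring).

    Returns the adjudicated references and the index results; every printed
    margin is re-verified on construction.
    """
    grade_by_algo = _grade_by_algo()
    tp2, fn2, fp2, tn2 = TABLE_2X2["two_or_more"]
    fp_any = TABLE_2X2["any"][2]
    # multi split is forced by the two-or-more table: its fp row mixes
    # fracture-free (82) and single-fracture algorithm-positive patients
    n_multi_pos, n_multi_neg = tp2, fn2
    n_single_pos = fp2 - fp_any
    n_single_neg = tn2 - TABLE_2X2["any"][3]
    pos = _build_stratum("positive", grade_by_algo["positive"], n_single_pos, n_multi_pos)
    neg = _build_stratum("negative", grade_by_algo["negative"], n_single_neg, n_multi_neg)

    refs: list[PatientReference] = []
    index: list[IndexResult] = []
    counter = 0

    def emit(fractures: dict[str, int], result: str) -> None:
        nonlocal counter
        counter += 1
        pid = f"F{counter:04d}"
        refs.append(
            PatientReference(
                patient_id=pid,
                any_vcf=bool(fractures),
                max_grade=max(fractures.values(), default=0),
                n_fractures=len(fractures),
                per_level=dict(fractures),
            )
        )
        index.append(IndexResult(pid, result))

    for p in pos + neg:
        emit(p.fractures, p.algo)
    for _ in range(fp_any):  # fracture-free, algorithm false positives
        emit({}, "positive")
    for _ in range(TABLE_2X2["any"][3]):  # fracture-free true negatives
        emit({}, "negative")
    for _ in range(N_NONEVALUABLE):  # non-evaluable (truth unconstrained)
        emit({}, "non_evaluable")

    _verify(refs, index)
    return refs, index


def _verify(refs, index) -> None:
    from .tables import ComparisonRule, build_table, vertebral_sensitivity_table

    problems = []
    if len(refs) != N_TOTAL:
        problems.append(f"total patients {len(refs)} != {N_TOTAL}")
    n_ne = sum(r.result == "non_evaluable" for r in index)
    if n_ne != N_NONEVALUABLE:
        problems.append(f"non-evaluable {n_ne} != {N_NONEVALUABLE}")
    for rule_name, expected in TABLE_2X2.items():
        t = build_table(refs, index, ComparisonRule(rule_name))
        got = (t.tp, t.fn, t.fp, t.tn)
        if got != expected:
            problems.append(f"2x2[{rule_name}] {got} != {expected}")
    for min_grade, table in ((1, TABLE_LEVEL_ANY), (2, TABLE_LEVEL_MODSEV)):
        vt = vertebral_sensitivity_table(refs, index, min_grade=min_grade)
        for lv, (nr, na) in table.items():
            got = (int(vt.loc[lv, "n_reference_positive"]), int(vt.loc[lv, "n_algo_positive"]))
            if got != (nr, na):
                problems.append(f"level[{lv}, min_grade={min_grade}] {got} != {(nr, na)}")
    if problems:
        raise FixtureError("fixture violates printed margins: " + "; ".join(problems))
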