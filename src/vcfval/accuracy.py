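"""Operating characteristics with exact and log-scale interval estimates.

Proportions (sensitivity, specificity, predictive values) carry
Clopper-Pearson exact binomial 95% CIs.  Likelihood ratios carry log-method
CIs: the delta-method standard error of the log of a ratio of two
independent binomial proportions,

    var(ln LR+) = 1/tp - 1/(tp+fn) + 1/fp - 1/(fp+tn),

with the interval exp(ln LR +/- z * SE) — the interval a log-link binomial
regression reproduces.  Also provides the non-evaluable-inclusive
sensitivity re-analysis and the LR-precision sample-size calculation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .tables import Table2x2


@dataclass(frozen=True)
class ProportionEstimate:
    """k/n with an exact (Clopper-Pearson) confidence interval."""

    numerator: int
    denominator: int
    point: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "clopper_pearson"

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.point + 1e-12 and self.point <= self.ci_high + 1e-12):
            raise ValueError(
                f"interval must bracket the point: {self.ci_low}, {self.point}, {self.ci_high}"
            )


@dataclass(frozen=True)
class RatioEstimate:
    """A positive ratio with a log-symmetric confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    log_se: float
    level: float = 0.95
    method: str = "log_ratio"
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.ci_low <= self.point <= self.ci_high):
            raise ValueError(
                f"interval must bracket the point: {self.ci_low}, {self.point}, {self.ci_high}"
            )


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> ProportionEstimate:
    """Clopper-Pearson exact binomial CI for a proportion k/n.

    Bounds invert the binomial tail probabilities; computed through the
    standard beta-quantile closed form.  k=0 pins the lower bound at 0 and
    k=n the upper bound at 1.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n]; got k={k}, n={n}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return ProportionEstimate(k, n, k / n, low, high, level=level)


_STATS = {
    # statistic -> (numerator cell, denominator margin) as attribute getters
    "sensitivity": (lambda t: t.tp, lambda t: t.tp + t.fn),
    "specificity": (lambda t: t.tn, lambda t: t.fp + t.tn),
    "ppv": (lambda t: t.tp, lambda t: t.tp + t.fp),
    "npv": (lambda t: t.tn, lambda t: t.fn + t.tn),
}

_MARGIN_NAMES = {
    "sensitivity": "tp+fn (reference positives)",
    "specificity": "fp+tn (reference negatives)",
    "ppv": "tp+fp (test positives)",
    "npv": "fn+tn (test negatives)",
}


def accuracy_summary(
    t: Table2x2, level: float = 0.95, strict: bool = False
) -> dict[str, ProportionEstimate | None]:
    """Sensitivity, specificity, PPV and NPV with exact CIs.

    A statistic whose denominator margin is zero is undefined: returned as
    ``None`` by default, or raised (naming the zero margin) when ``strict``.
    """
    out: dict[str, ProportionEstimate | None] = {}
    for name, (num, den) in _STATS.items():
        d = den(t)
        if d == 0:
            if strict:
                raise ValueError(f"{name} is undefined: zero margin {_MARGIN_NAMES[name]}")
            out[name] = None
        else:
            out[name] = exact_binomial_ci(num(t), d, level=level)
    return out


def likelihood_ratios(
    t: Table2x2, level: float = 0.95, strict: bool = False
) -> dict[str, RatioEstimate]:
    """Positive and negative likelihood ratios with log-method CIs.

    LR+ = sens/(1-spec), LR- = (1-sens)/spec.  If any 2x2 cell is zero the
    ratios are degenerate; in strict mode this raises, otherwise 0.5 is
    added to all four cells (recorded on the estimates).
    """
    tp, fn, fp, tn = t.tp, t.fn, t.fp, t.tn
    if t.tp + t.fn == 0 or t.fp + t.tn == 0:
        raise ValueError("likelihood ratios need both reference-positive and -negative patients")
    corrected = False
    if min(tp, fn, fp, tn) == 0:
        if strict:
            raise ValueError("zero cell in the 2x2 table; likelihood ratio undefined in strict mode")
        tp, fn, fp, tn = tp + 0.5, fn + 0.5, fp + 0.5, tn + 0.5
        corrected = True
    sens = tp / (tp + fn)
    spec = tn / (fp + tn)
    z = stats.norm.ppf(0.5 + level / 2.0)
    out = {}
    for name, point, var in (
        ("lr_pos", sens / (1.0 - spec), 1 / tp - 1 / (tp + fn) + 1 / fp - 1 / (fp + tn)),
        ("lr_neg", (1.0 - sens) / spec, 1 / fn - 1 / (tp + fn) + 1 / tn - 1 / (fp + tn)),
    ):
        se = math.sqrt(var)
        out[name] = RatioEstimate(
            point=point,
            ci_low=point * math.exp(-z * se),
            ci_high=point * math.exp(z * se),
            log_se=se,
            level=level,
            continuity_corrected=corrected,
        )
    return out


def inclusive_sensitivity(
    t: Table2x2, n_total: int, n_evaluable: int, level: float = 0.95
) -> ProportionEstimate:
    """Sensitivity inclusive of non-evaluable studies.

    Assumes fracture prevalence among the non-evaluable studies equals that
    among the evaluable ones; every imputed non-evaluable reference-positive
    counts as a miss.  The point estimate is the multiplicative form
    sens * n_evaluable/n_total; the CI is exact binomial on the rounded
    augmented denominator.
    """
    if n_evaluable <= 0:
        raise ValueError("n_evaluable must be positive")
    if n_evaluable > n_total:
        raise ValueError(f"n_evaluable ({n_evaluable}) exceeds n_total ({n_total})")
    pos = t.tp + t.fn
    if pos == 0:
        raise ValueError("no reference-positive patients; sensitivity undefined")
    point = (t.tp / pos) * (n_evaluable / n_total)
    imputed = pos * (n_total - n_evaluable) / n_evaluable
    denom = round(pos + imputed)
    base = exact_binomial_ci(t.tp, denom, level=level)
    return ProportionEstimate(
        numerator=t.tp,
        denominator=denom,
        point=point,
        ci_low=min(base.ci_low, point),
        ci_high=max(base.ci_high, point),
        level=level,
    )


def sample_size_for_lr(
    sens: float,
    spec: float,
    prevalence: float,
    exclude_value: float,
    level: float = 0.95,
) -> int:
    """Smallest n whose expected LR+ CI lower bound excludes ``exclude_value``.

    At the planning values the expected 2x2 cells are n*prev*sens etc.; the
    log-scale variance of LR+ then scales as c/n with

        c = 1/(prev*sens) - 1/prev + 1/((1-prev)*(1-spec)) - 1/(1-prev),

    and the requirement exp(ln LR+ - z*sqrt(c/n)) >= exclude_value gives
    n >= z^2 c / (ln(LR+/exclude_value))^2.
    """
    for name, p in (("sens", sens), ("spec", spec)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {p}")
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    lr = sens / (1.0 - spec)
    if exclude_value <= 0:
        raise ValueError("exclude_value must be positive")
    if exclude_value >= lr:
        raise ValueError(
            f"exclude_value ({exclude_value}) must lie below the planned LR+ ({lr:.3f})"
        )
    c = (
        1.0 / (prevalence * sens)
        - 1.0 / prevalence
        + 1.0 / ((1.0 - prevalence) * (1.0 - spec))
        - 1.0 / (1.0 - prevalence)
    )
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    slack = math.log(lr / exclude_value)
    n = math.ceil(z * z * c / (slack * slack))
    # guard against floating-point edge: confirm minimality by direct check
    def ok(m: int) -> bool:
        return z * math.sqrt(c / m) <= slack + 1e-15

    while n > 1 and ok(n - 1):
        n -= 1
    while not ok(n):
        n += 1
    return n
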