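"""Inter-rater reliability via variance components with BCa bootstrap CIs.

Each patient is rated by two raters drawn from a pool of three.  The model
is a linear mixed model with a random intercept per patient and fixed
effects for rater identity,

    y_ij = mu + rater_j + b_i + e_ij,   b_i ~ N(0, s2_subject),  e_ij ~ N(0, s2_resid),

fitted by REML.  The intraclass correlation coefficient is the
between-subject share of total variance,

    ICC = s2_subject / (s2_subject + s2_resid).

Ratings are treated as continuous even when binary (presence 0/1) or
ordinal (severity 0-3, fracture count).  Confidence intervals come from a
bias-corrected accelerated (BCa) bootstrap that resamples patients with
replacement, keeping each patient's pair of ratings together.

The REML fit is profiled down to a one-dimensional search over the variance
ratio, exploiting the per-patient block structure of the marginal
covariance; this makes the ~10^4-10^5 refits of a bootstrap/coverage study
cheap.  Three raters are too few to support a rater variance component, so
rater enters as fixed effects only (``rater_effects="none"`` drops it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .adjudicate import VertebralReading

__all__ = [
    "RatingMatrix",
    "ICCEstimate",
    "fit_variance_components",
    "bca_ci",
    "icc_suite",
    "rating_matrix_from_readings",
    "simulate_ratings",
]


@dataclass(frozen=True)
class RatingMatrix:
    """Long-format ratings: one row per (patient, rater) rating."""

    patient: np.ndarray  # labels (any hashable dtype)
    rater: np.ndarray  # labels
    outcome: np.ndarray  # float

    def __post_init__(self) -> None:
        p = np.asarray(self.patient)
        r = np.asarray(self.rater)
        y = np.asarray(self.outcome, dtype=float)
        if not (len(p) == len(r) == len(y)):
            raise ValueError("patient, rater, outcome must have equal length")
        if len(y) and not np.isfinite(y).all():
            raise ValueError("outcomes must be finite")
        object.__setattr__(self, "patient", p)
        object.__setattr__(self, "rater", r)
        object.__setattr__(self, "outcome", y)

    @property
    def n_patients(self) -> int:
        return len(np.unique(self.patient))

    def require_pairs(self) -> None:
        _, counts = np.unique(self.patient, return_counts=True)
        if not (counts == 2).all():
            raise ValueError("design requires exactly 2 ratings per patient")


@dataclass(frozen=True)
class ICCEstimate:
    sigma2_subject: float
    sigma2_resid: float
    icc: float
    rater_effects: dict = field(default_factory=dict)
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_boot: int = 0
    seed: int | None = None
    degenerate: bool = False


def _design(m: RatingMatrix, rater_effects: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Fixed-effect design matrix (intercept + rater dummies, first rater as
    the reference) and patient group codes."""
    _, gidx = np.unique(m.patient, return_inverse=True)
    n = len(m.outcome)
    cols = [np.ones(n)]
    names = ["intercept"]
    if rater_effects == "fixed":
        raters = np.unique(m.rater)
        for r in raters[1:]:
            cols.append((m.rater == r).astype(float))
            names.append(f"rater[{r}]")
    elif rater_effects != "none":
        raise ValueError(f"rater_effects must be 'fixed' or 'none', got {rater_effects!r}")
    X = np.column_stack(cols)
    return X, gidx, names


def _profiled_reml(y: np.ndarray, X: np.ndarray, gidx: np.ndarray):
    """REML for y = X b + Zu + e with one random intercept per group.

    Profiles the fixed effects and the residual variance, leaving a 1-D
    criterion in lam = s2_subject/s2_resid.  The group structure makes
    W = I + lam ZZ' block diagonal; Woodbury gives every quantity from
    per-group sums.  Returns (lam_hat, sigma2_resid, beta).
    """
    n, p = X.shape
    m = gidx.max() + 1
    k = np.bincount(gidx, minlength=m).astype(float)
    Gx = np.zeros((m, p))
    np.add.at(Gx, gidx, X)
    gy = np.bincount(gidx, weights=y, minlength=m)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def parts(lam: float):
        c = lam / (1.0 + k * lam)
        A = XtX - (Gx * c[:, None]).T @ Gx
        b = Xty - Gx.T @ (c * gy)
        beta = np.linalg.solve(A, b)
        rss = yty - float(np.dot(c * gy, gy)) - float(beta @ b)
        return c, A, beta, max(rss, 1e-300)

    def score(lam: float) -> float:
        # d/d lam of the -2 REML log-likelihood, computed analytically:
        # d log|W| = sum k/(1+k lam);  d rss = -||Z' P y||^2;
        # d log|X'W^-1 X| = -tr(A^-1 X'W^-1 ZZ' W^-1 X)
        c, A, beta, rss = parts(lam)
        w1 = 1.0 - k * c  # = 1/(1 + k lam)
        u = w1 * (gy - Gx @ beta)  # Z' P y
        drss = -float(u @ u)
        B = (Gx * (w1 * w1)[:, None]).T @ Gx
        dldA = -float(np.trace(np.linalg.solve(A, B)))
        dldW = float(np.sum(k * w1))
        return (n - p) * drss / rss + dldW + dldA

    lam = 0.0
    if score(0.0) < 0.0:  # interior optimum: bracket and root-find the score
        hi = 1.0
        while score(hi) < 0.0 and hi < 1e8:
            hi *= 8.0
        if hi >= 1e8:
            lam = hi  # all variance between subjects; icc -> 1
        else:
            lam = float(optimize.brentq(score, hi / 8.0 if hi > 1.0 else 0.0, hi,
                                        xtol=1e-12, rtol=8.9e-16))
    _, _, beta, rss = parts(lam)
    sigma2_resid = rss / (n - p)
    return lam, sigma2_resid, beta


def fit_variance_components(
    m: RatingMatrix, rater_effects: str = "fixed"
) -> ICCEstimate:
    """REML point estimates of the subject and residual variances and the ICC.

    Negative subject-variance estimates are truncated to zero (the REML
    search is bounded below at lam = 0).  If the outcomes carry no variance
    at all, or the residual variance collapses to zero, the fit is flagged
    degenerate with ICC 1.
    """
    y = m.outcome
    if m.n_patients < 2:
        raise ValueError("need at least 2 patients to estimate an ICC")
    if float(np.var(y)) == 0.0:
        return ICCEstimate(0.0, 0.0, 1.0, degenerate=True)
    X, gidx, names = _design(m, rater_effects)
    lam, s2e, beta = _profiled_reml(y, X, gidx)
    if lam >= 1e7:
        # essentially no within-subject noise left after the rater effects
        return ICCEstimate(lam * s2e, s2e, 1.0,
                           rater_effects=dict(zip(names[1:], beta[1:])), degenerate=True)
    if s2e < 1e-12 * float(np.var(y)):
        # ratings are an exact function of patient (+ rater): no within-subject noise
        return ICCEstimate(lam * s2e, s2e, 1.0,
                           rater_effects=dict(zip(names[1:], beta[1:])), degenerate=True)
    s2b = lam * s2e
    icc = float(np.clip(s2b / (s2b + s2e), 0.0, 1.0))
    return ICCEstimate(
        sigma2_subject=float(s2b),
        sigma2_resid=float(s2e),
        icc=icc,
        rater_effects=dict(zip(names[1:], np.asarray(beta[1:], float))),
    )


def _patient_blocks(m: RatingMatrix) -> tuple[np.ndarray, list[np.ndarray]]:
    labels, gidx = np.unique(m.patient, return_inverse=True)
    order = np.argsort(gidx, kind="stable")
    bounds = np.searchsorted(gidx[order], np.arange(len(labels) + 1))
    blocks = [order[bounds[i]:bounds[i + 1]] for i in range(len(labels))]
    return labels, blocks


def _resample(m: RatingMatrix, blocks: list[np.ndarray], idx: np.ndarray) -> RatingMatrix:
    # a patient drawn twice becomes two distinct subjects in the resample
    rows = np.concatenate([blocks[i] for i in idx])
    sizes = np.array([len(blocks[i]) for i in idx])
    new_patient = np.repeat(np.arange(len(idx)), sizes)
    return RatingMatrix(new_patient, m.rater[rows], m.outcome[rows])


def bca_ci(
    m: RatingMatrix,
    statistic: Callable[[RatingMatrix], float],
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    max_failure_frac: float = 0.05,
) -> tuple[float, float]:
    """Bias-corrected accelerated bootstrap CI for a patient-level statistic.

    Resampling unit is the patient (both ratings move together).  The bias
    correction z0 comes from the fraction of bootstrap statistics below the
    point estimate; the acceleration from the jackknife-over-patients
    skewness.  Deterministic given ``seed``.
    """
    if n_boot < 200:
        raise ValueError(f"n_boot must be >= 200, got {n_boot}")
    theta_hat = float(statistic(m))
    labels, blocks = _patient_blocks(m)
    npat = len(labels)
    rng = np.random.default_rng(seed)
    thetas = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, npat, npat)
        try:
            thetas.append(float(statistic(_resample(m, blocks, idx))))
        except Exception:
            failures += 1
    if failures > max_failure_frac * n_boot:
        raise RuntimeError(
            f"statistic failed on {failures}/{n_boot} bootstrap resamples "
            f"(> {max_failure_frac:.0%} allowed)"
        )
    thetas = np.asarray(thetas)
    if thetas.size == 0 or float(np.ptp(thetas)) == 0.0:
        c = theta_hat if thetas.size == 0 else float(thetas[0])
        return (c, c)

    frac_below = float(np.mean(thetas < theta_hat))
    frac_below = min(max(frac_below, 1.0 / (len(thetas) + 1)), len(thetas) / (len(thetas) + 1.0))
    z0 = float(stats.norm.ppf(frac_below))

    # acceleration via jackknife over patients
    jack = np.empty(npat)
    keep = np.ones(npat, dtype=bool)
    for i in range(npat):
        keep[i] = False
        jack[i] = float(statistic(_resample(m, blocks, np.flatnonzero(keep))))
        keep[i] = True
    d = jack.mean() - jack
    denom = float(np.sum(d * d)) ** 1.5
    a = float(np.sum(d**3) / (6.0 * denom)) if denom > 0 else 0.0

    alpha = 1.0 - level
    out = []
    for q in (alpha / 2.0, 1.0 - alpha / 2.0):
        zq = stats.norm.ppf(q)
        adj = stats.norm.cdf(z0 + (z0 + zq) / (1.0 - a * (z0 + zq)))
        out.append(float(np.quantile(thetas, adj)))
    return out[0], out[1]


def fit_with_bca(
    m: RatingMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    rater_effects: str = "fixed",
) -> ICCEstimate:
    """Point REML fit plus BCa interval for the ICC (clipped to [0, 1])."""
    est = fit_variance_components(m, rater_effects=rater_effects)
    lo, hi = bca_ci(
        m,
        lambda mm: fit_variance_components(mm, rater_effects=rater_effects).icc,
        n_boot=n_boot,
        seed=seed,
        level=level,
    )
    lo, hi = float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))
    lo, hi = min(lo, est.icc), max(hi, est.icc)
    return replace(est, ci_low=lo, ci_high=hi, n_boot=n_boot, seed=seed)


OUTCOMES = ("presence", "severity", "count")


def rating_matrix_from_readings(
    readings: Iterable[VertebralReading],
    outcome: str,
    senior_id: str = "SENIOR",
) -> RatingMatrix:
    """Per-(patient, rater) outcomes from the initial (pre-adjudication)
    readings, excluding the senior adjudicator.

    presence: any fracture flagged (0/1); severity: Genant grade of the most
    severe flagged fracture (0-3); count: number of flagged vertebrae.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}, got {outcome!r}")
    pats, rats, ys = [], [], []
    for r in readings:
        if r.reader_id == senior_id:
            continue
        pats.append(r.patient_id)
        rats.append(r.reader_id)
        if outcome == "presence":
            ys.append(float(r.any_vcf))
        elif outcome == "severity":
            ys.append(float(r.max_grade))
        else:
            ys.append(float(len(r.findings)))
    m = RatingMatrix(np.asarray(pats), np.asarray(rats), np.asarray(ys))
    m.require_pairs()
    return m


def icc_suite(
    readings: Iterable[VertebralReading],
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    senior_id: str = "SENIOR",
) -> dict[str, ICCEstimate]:
    """Presence / severity / count ICCs with BCa intervals."""
    readings = list(readings)
    out = {}
    for j, outcome in enumerate(OUTCOMES):
        m = rating_matrix_from_readings(readings, outcome, senior_id=senior_id)
        out[outcome] = fit_with_bca(m, n_boot=n_boot, seed=seed + j, level=level)
    return out


def simulate_ratings(
    n_patients: int,
    sigma2_subject: float,
    sigma2_resid: float,
    mu: float = 0.0,
    rater_offsets: Sequence[float] = (0.0, 0.15, -0.1),
    seed: int = 0,
) -> RatingMatrix:
    """Draw ratings from the variance-components model on the 2-of-3 design.

    Each patient receives two raters chosen at random from the pool; the
    implied true ICC is sigma2_subject / (sigma2_subject + sigma2_resid).
    """
    rng = np.random.default_rng(seed)
    n_raters = len(rater_offsets)
    b = rng.normal(0.0, np.sqrt(sigma2_subject), n_patients)
    pats = np.repeat(np.arange(n_patients), 2)
    raters = np.empty(2 * n_patients, dtype=int)
    for i in range(n_patients):
        raters[2 * i: 2 * i + 2] = rng.choice(n_raters, size=2, replace=False)
    e = rng.normal(0.0, np.sqrt(sigma2_resid), 2 * n_patients)
    y = mu + np.asarray(rater_offsets)[raters] + np.repeat(b, 2) + e
    return RatingMatrix(pats, np.char.add("R", (raters + 1).astype(str)), y)
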