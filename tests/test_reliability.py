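"""Variance-components ICC and BCa bootstrap."""

import numpy as np
import pytest

import vcfval as v
from vcfval.reliability import (
    RatingMatrix,
    bca_ci,
    fit_variance_components,
    icc_suite,
    rating_matrix_from_readings,
    simulate_ratings,
)


def balanced_matrix(n=200, k=3, s2b=1.0, s2e=0.36, offsets=(0.0, 0.3, -0.2), seed=3):
    rng = np.random.default_rng(seed)
    b = rng.normal(0, np.sqrt(s2b), n)
    y = (b[:, None] + np.asarray(offsets)[None, :] + rng.normal(0, np.sqrt(s2e), (n, k))).ravel()
    pats = np.repeat(np.arange(n), k)
    rats = np.tile(np.array([f"R{j+1}" for j in range(k)]), n)
    return RatingMatrix(pats, rats, y)


def anova_consistency_icc(m: RatingMatrix, n: int, k: int) -> float:
    """Classical two-way (subject x rater) consistency ICC on a balanced
    complete design — the independent oracle."""
    Y = m.outcome.reshape(n, k)
    gm, rowm, colm = Y.mean(), Y.mean(1), Y.mean(0)
    msr = k * np.sum((rowm - gm) ** 2) / (n - 1)
    mse = np.sum((Y - rowm[:, None] - colm[None, :] + gm) ** 2) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


class TestFitVarianceComponents:
    def test_matches_anova_oracle_on_balanced_design(self):
        m = balanced_matrix()
        est = fit_variance_components(m)
        assert est.icc == pytest.approx(anova_consistency_icc(m, 200, 3), abs=1e-8)

    def test_matches_mixedlm_oracle(self):
        import pandas as pd
        import statsmodels.formula.api as smf

        m = simulate_ratings(400, 1.0, 0.429, mu=2.0, seed=42)
        est = fit_variance_components(m)
        df = pd.DataFrame({"y": m.outcome, "pat": m.patient, "rat": m.rater})
        fit = smf.mixedlm("y ~ C(rat)", df, groups=df["pat"]).fit(reml=True)
        s2b, s2e = float(fit.cov_re.iloc[0, 0]), float(fit.scale)
        assert est.sigma2_subject == pytest.approx(s2b, rel=1e-3, abs=1e-4)
        assert est.sigma2_resid == pytest.approx(s2e, rel=1e-3, abs=1e-4)
        assert est.icc == pytest.approx(s2b / (s2b + s2e), abs=1e-4)

    def test_identical_raters_give_icc_one(self):
        # both raters always agree, outcomes vary across patients
        y = np.repeat(np.arange(50, dtype=float), 2)
        m = RatingMatrix(np.repeat(np.arange(50), 2), np.tile(["R1", "R2"], 50), y)
        assert fit_variance_components(m).icc == 1.0

    def test_pure_noise_gives_icc_near_zero(self):
        m = simulate_ratings(2000, 0.0, 1.0, seed=5)
        assert fit_variance_components(m).icc <= 0.05

    def test_parameter_recovery_two_of_three_design(self):
        # Var(subject)=1, Var(resid)=0.429 -> true ICC 1/1.429 = 0.6998
        m = simulate_ratings(1200, 1.0, 0.429, seed=7)
        est = fit_variance_components(m)
        assert est.icc == pytest.approx(1 / 1.429, abs=0.05)
        assert est.icc == pytest.approx(
            est.sigma2_subject / (est.sigma2_subject + est.sigma2_resid), abs=1e-12
        )

    def test_constant_outcomes_flagged_degenerate(self):
        m = RatingMatrix(np.repeat(np.arange(10), 2), np.tile(["R1", "R2"], 10), np.full(20, 3.0))
        est = fit_variance_components(m)
        assert est.icc == 1.0 and est.degenerate

    def test_shift_and_scale_invariance(self):
        m = simulate_ratings(500, 1.0, 0.5, seed=11)
        base = fit_variance_components(m).icc
        shifted = RatingMatrix(m.patient, m.rater, m.outcome + 7.5)
        scaled = RatingMatrix(m.patient, m.rater, m.outcome * 3.25)
        assert fit_variance_components(shifted).icc == pytest.approx(base, abs=1e-10)
        assert fit_variance_components(scaled).icc == pytest.approx(base, abs=1e-10)

    def test_truncation_to_unit_interval(self):
        for seed in range(5):
            m = simulate_ratings(50, 0.01, 1.0, seed=seed)
            assert 0.0 <= fit_variance_components(m).icc <= 1.0

    def test_too_few_patients_rejected(self):
        m = RatingMatrix(np.array([0, 0]), np.array(["R1", "R2"]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            fit_variance_components(m)


class TestBcaCI:
    def test_constant_statistic_gives_point_interval(self):
        m = simulate_ratings(50, 1.0, 0.4, seed=0)
        assert bca_ci(m, lambda _: 0.5, n_boot=200, seed=1) == (0.5, 0.5)

    def test_deterministic_given_seed(self):
        m = simulate_ratings(150, 1.0, 0.429, seed=4)
        stat = lambda mm: fit_variance_components(mm).icc
        assert bca_ci(m, stat, n_boot=300, seed=9) == bca_ci(m, stat, n_boot=300, seed=9)

    def test_near_symmetric_statistic_close_to_percentiles(self):
        # the patient-mean outcome bootstraps nearly symmetrically, so the
        # BCa endpoints should sit close to the plain 2.5/97.5 percentiles
        m = simulate_ratings(400, 1.0, 0.4, seed=12)
        stat = lambda mm: float(np.mean(mm.outcome))
        lo, hi = bca_ci(m, stat, n_boot=1000, seed=3)
        rng = np.random.default_rng(3)
        npat = m.n_patients
        thetas = []
        means = m.outcome.reshape(npat, 2).mean(axis=1)
        for _ in range(1000):
            idx = rng.integers(0, npat, npat)
            thetas.append(means[idx].mean())
        q = np.quantile(thetas, [0.025, 0.975])
        width = q[1] - q[0]
        assert lo == pytest.approx(q[0], abs=0.25 * width)
        assert hi == pytest.approx(q[1], abs=0.25 * width)

    def test_interval_brackets_point_estimate(self):
        m = simulate_ratings(200, 1.0, 0.429, seed=6)
        from vcfval.reliability import fit_with_bca

        est = fit_with_bca(m, n_boot=300, seed=2)
        assert est.ci_low <= est.icc <= est.ci_high
        assert 0.0 <= est.ci_low and est.ci_high <= 1.0

    def test_too_few_bootstrap_samples_rejected(self):
        m = simulate_ratings(50, 1.0, 0.4, seed=0)
        with pytest.raises(ValueError):
            bca_ci(m, lambda mm: 0.0, n_boot=50, seed=0)

    def test_failing_statistic_aborts_with_diagnostics(self):
        m = simulate_ratings(50, 1.0, 0.4, seed=0)
        calls = {"n": 0}

        def bad(_):
            # succeeds on the point estimate, fails on every resample
            calls["n"] += 1
            if calls["n"] > 1:
                raise RuntimeError("boom")
            return 0.5

        with pytest.raises(RuntimeError, match="bootstrap resamples"):
            bca_ci(m, bad, n_boot=200, seed=0)


class TestIccSuite:
    def test_noiseless_raters_all_icc_one(self, noiseless_kwargs):
        cohort = v.generate_cohort(v.default_config(n_patients=150, seed=8, **noiseless_kwargs))
        suite = icc_suite(cohort.readings, n_boot=200, seed=0)
        for est in suite.values():
            assert est.icc == pytest.approx(1.0, abs=1e-9)

    def test_presence_icc_recovery_from_latent_components(self):
        # variance components chosen to give a presence-style ratio of 0.68
        m = simulate_ratings(1200, 0.68, 0.32, seed=15)
        assert fit_variance_components(m).icc == pytest.approx(0.68, abs=0.05)

    def test_severity_icc_exceeds_presence_icc_with_mild_grade_confusion(self):
        # noisy presence detection (25% misses, mild-call false positives)
        # but nearly faithful grading: grading agreement survives, presence
        # agreement does not
        conf = (
            (0.99, 0.01, 0.0, 0.0),
            (0.02, 0.96, 0.02, 0.0),
            (0.0, 0.02, 0.96, 0.02),
            (0.0, 0.0, 0.02, 0.98),
        )
        cfg = v.default_config(
            n_patients=4000, seed=17, rater_presence_agreement=0.75, rater_grade_confusion=conf
        )
        cohort = v.generate_cohort(cfg)
        pres = fit_variance_components(rating_matrix_from_readings(cohort.readings, "presence")).icc
        sev = fit_variance_components(rating_matrix_from_readings(cohort.readings, "severity")).icc
        assert sev > pres

    def test_outcomes_and_design(self, small_cohort):
        suite = icc_suite(small_cohort.readings, n_boot=200, seed=1)
        assert set(suite) == {"presence", "severity", "count"}
        m = rating_matrix_from_readings(small_cohort.readings, "count")
        m.require_pairs()
        with pytest.raises(ValueError):
            rating_matrix_from_readings(small_cohort.readings, "kappa")
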