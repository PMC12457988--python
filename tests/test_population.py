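import numpy as np
import pytest

import avypop as ap
from avypop.population import (
    DEFAULT_FECUNDITY_SHAPE,
    VitalRateSchedule,
    adjusted_matrix,
    build_matrix,
    calibrate_baseline,
    dominant_lambda,
    largest_remainder_round,
    project_one_year,
    sample_parameters,
    schedule_from_fit,
    stable_stage_distribution,
)
from avypop.stages import N_AGE_CLASSES, Stage


def toy_schedule(**kw):
    """Single-sex two-age toy: survivals (0.5, 0), fecundity (0, 2), S_neo=1."""
    sf = np.zeros(N_AGE_CLASSES)
    sf[0] = 0.5
    fec = np.zeros(N_AGE_CLASSES)
    fec[1] = 2.0
    base = dict(
        survival_female=sf,
        survival_male=np.zeros(N_AGE_CLASSES),
        fecundity=fec,
        s_neo=1.0,
        birth_sex_ratio=1.0,  # all female: reduces to the classic Leslie toy
    )
    base.update(kw)
    return VitalRateSchedule(**base)


class TestBuildMatrix:
    def test_toy_two_age_eigenstructure(self):
        m = build_matrix(toy_schedule())
        assert dominant_lambda(m) == pytest.approx(1.0, abs=1e-10)
        v = stable_stage_distribution(m)
        assert v[0] == pytest.approx(2 / 3, abs=1e-9)
        assert v[1] == pytest.approx(1 / 3, abs=1e-9)

    def test_zero_neonate_survival_kills_recruitment(self):
        # without recruitment the age chain is nilpotent: asymptotic growth 0
        m = build_matrix(toy_schedule(s_neo=0.0))
        assert dominant_lambda(m) == pytest.approx(0.0, abs=1e-12)

    def test_fertility_entries_follow_post_breeding_rule(self, calibrated):
        m = build_matrix(calibrated)
        n = N_AGE_CLASSES
        rho = calibrated.birth_sex_ratio
        for a in range(n):
            expected = calibrated.fecundity[a] * calibrated.s_neo
            assert m.A[0, a] == pytest.approx(expected * rho)
            assert m.A[n, a] == pytest.approx(expected * (1 - rho))
        # survival sub-blocks have column sums <= 1
        surv = m.A.copy()
        surv[m.fertility_mask] = 0.0
        assert (surv.sum(axis=0) <= 1.0 + 1e-12).all()

    def test_schedule_from_fit_uses_stage_lines(self, ref_fit):
        sched = schedule_from_fit(ref_fit)
        assert sched.survival_female[7] == pytest.approx(
            ap.predict_survival(ref_fit, Stage.ADULT_FEMALE, 0.07)
        )
        assert sched.survival_male[12] == pytest.approx(
            ap.predict_survival(ref_fit, Stage.OLD_MALE, 0.07)
        )
        # terminal truncation and recruitment folding
        assert sched.survival_female[-1] == 0.0
        assert sched.survival_female[0] == pytest.approx(
            ap.predict_survival(ref_fit, Stage.YEARLING, 0.07)
        )


class TestStableDistribution:
    def test_eigenpair_identity(self, calibrated):
        m = build_matrix(calibrated)
        v = stable_stage_distribution(m)
        lam = dominant_lambda(m)
        assert v.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(v >= 0)
        assert np.max(np.abs(m.A @ v - lam * v)) < 1e-8

    def test_scaling_matrix_scales_lambda_not_vector(self, calibrated):
        m = build_matrix(calibrated)
        lam = dominant_lambda(m)
        v = stable_stage_distribution(m)
        assert dominant_lambda(m.A * 3.0) == pytest.approx(3.0 * lam)
        assert np.allclose(stable_stage_distribution(m.A * 3.0), v, atol=1e-9)


class TestCalibration:
    def test_hits_published_baseline_growth(self, ref_fit, calibrated):
        assert dominant_lambda(build_matrix(calibrated)) == pytest.approx(
            1.015, abs=1e-6
        )

    def test_doubling_neonate_survival_halves_fecundity_scalar(self, ref_fit):
        a = calibrate_baseline(ref_fit, s_neo=0.4)
        b = calibrate_baseline(ref_fit, s_neo=0.8)
        scale_a = a.fecundity[6]
        scale_b = b.fecundity[6]
        assert scale_b == pytest.approx(scale_a / 2.0, rel=1e-6)

    def test_unreachable_target_reports_bracket(self, ref_fit):
        # the age-truncated survival-only chain has growth 0, so any
        # non-positive target is below the reachable floor
        with pytest.raises(ValueError, match="unreachable"):
            calibrate_baseline(ref_fit, target_lambda=0.0)


class TestSampleParameters:
    def test_zero_covariance_returns_point_estimates(self, ref_fit):
        fit0 = ap.SurvivalModelFit(
            intercept=ref_fit.intercept,
            slope=ref_fit.slope,
            stage_offsets=dict(ref_fit.stage_offsets),
            coefficient_covariance=np.zeros((8, 8)),
        )
        draw = sample_parameters(fit0, fecundity_sd=0.0, horizon=5, seed=0)
        assert np.allclose(draw.fit.beta, fit0.beta, atol=1e-5)
        assert np.all(draw.fecundity_multipliers == 1.0)

    def test_draw_covariance_converges_to_input(self, ref_fit):
        rng = np.random.default_rng(7)
        draws = np.array(
            [
                sample_parameters(ref_fit, 0.0, 1, rng).fit.beta
                for _ in range(50_000)
            ]
        )
        cov = np.cov(draws.T)
        target = ref_fit.coefficient_covariance
        rel = np.linalg.norm(cov - target) / np.linalg.norm(target)
        assert rel < 0.05

    def test_fecundity_multiplier_sd_matches_config(self, ref_fit):
        draw = sample_parameters(ref_fit, fecundity_sd=0.106, horizon=10_000, seed=9)
        assert draw.fecundity_multipliers.std() == pytest.approx(0.106, abs=0.01)
        assert draw.fecundity_multipliers.mean() == pytest.approx(1.0, abs=0.01)

    def test_non_psd_covariance_raises(self, ref_fit):
        bad = -np.eye(8)
        fit_bad = ap.SurvivalModelFit(
            intercept=0.0,
            slope=-1.0,
            stage_offsets=dict(ref_fit.stage_offsets),
            coefficient_covariance=bad,
        )
        with pytest.raises(np.linalg.LinAlgError, match="PSD|positive"):
            sample_parameters(fit_bad, 0.1, 5, seed=0)


class TestProjection:
    def test_anchor_factors_reduce_to_plain_matmul(self, ref_fit, calibrated):
        m = build_matrix(calibrated)
        table = ap.ChangeFactorTable(
            ref_fit, ap.build_neonate_line(ref_fit, calibrated.s_neo, 0.07), 0.07
        )
        state = stable_stage_distribution(m) * 100
        plain = m.A @ state
        anchored = project_one_year(state, m, table.factors_at(0.07), 1.0)
        assert np.allclose(anchored, plain, atol=1e-12)

    def test_zero_state_stays_zero(self, calibrated):
        m = build_matrix(calibrated)
        out = project_one_year(np.zeros(40), m, {Stage.OLD_MALE: 0.5}, 1.0)
        assert np.all(out == 0.0)

    def test_single_transition_factor_arithmetic(self):
        sched = toy_schedule()
        sched.survival_female[0] = 0.8
        m = build_matrix(sched)
        state = np.zeros(40)
        state[0] = 10.0
        out = project_one_year(state, m, {Stage.YEARLING: 0.5}, 1.0)
        assert out[1] == pytest.approx(0.8 * 0.5 * 10.0)

    def test_adjusted_survival_clipped_to_one(self, calibrated):
        m = build_matrix(calibrated)
        A = adjusted_matrix(m, {s: 50.0 for s in Stage}, 1.0)
        surv = A.copy()
        surv[m.fertility_mask] = 0.0
        assert surv.max() <= 1.0

    def test_survival_entries_stay_probabilities_across_scenarios(
        self, ref_fit, calibrated
    ):
        m = build_matrix(calibrated)
        table = ap.ChangeFactorTable(
            ref_fit, ap.build_neonate_line(ref_fit, calibrated.s_neo, 0.07), 0.07
        )
        for mm in np.linspace(0.0, 0.3, 16):
            A = adjusted_matrix(m, table.factors_at(mm))
            surv = A.copy()
            surv[m.fertility_mask] = 0.0
            assert surv.min() >= 0.0
            assert surv.max() <= 1.0

    def test_long_run_growth_converges_to_dominant_eigenvalue(self, calibrated):
        m = build_matrix(calibrated)
        lam = dominant_lambda(m)
        state = np.zeros(40)
        state[3] = 1.0  # far from the stable distribution
        for _ in range(200):
            prev = state.sum()
            state = m.A @ state
            state /= max(state.sum(), 1e-300)  # keep numbers bounded
        ratio = (m.A @ state).sum() / state.sum()
        assert ratio == pytest.approx(lam, abs=1e-6)


def test_largest_remainder_rounding_preserves_total(calibrated):
    v = stable_stage_distribution(build_matrix(calibrated))
    rounded = largest_remainder_round(v, 100)
    assert rounded.sum() == 100
    assert np.all(rounded >= 0)
    assert np.max(np.abs(rounded - v * 100)) < 1.0


def test_default_fecundity_shape_structure():
    shape = np.array(DEFAULT_FECUNDITY_SHAPE)
    assert shape[:4].sum() == 0.0  # no reproduction before age 4
    assert shape.max() == shape[6]  # prime-age plateau
    assert shape[-1] < shape[6]  # senescent decline
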