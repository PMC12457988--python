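import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import avypop as ap
from avypop.stages import MODELED_STAGES, Stage
from avypop.survival import COEF_NAMES, ChangeFactorTable, SurvivalModelFit


class TestPredictSurvival:
    # baseline (m = 0.07) stage survivals implied by the published coefficients
    @pytest.mark.parametrize(
        "stage, expected",
        [
            (Stage.OLD_MALE, 0.61),
            (Stage.OLD_FEMALE, 0.77),
            (Stage.ADULT_MALE, 0.82),
            (Stage.ADULT_FEMALE, 0.88),
            (Stage.YOUNG_ADULT, 0.90),
            (Stage.SUBADULT, 0.96),
            (Stage.YEARLING, 0.86),
        ],
    )
    def test_baseline_stage_survivals(self, ref_fit, stage, expected):
        assert round(ap.predict_survival(ref_fit, stage, 0.07), 2) == expected

    def test_reference_stage_at_zero_mortality(self, ref_fit):
        assert ap.predict_survival(ref_fit, Stage.OLD_MALE, 0.0) == pytest.approx(
            0.6995, abs=5e-4
        )

    def test_neonate_and_bad_inputs_rejected(self, ref_fit):
        with pytest.raises(KeyError):
            ap.predict_survival(ref_fit, Stage.NEONATE, 0.07)
        with pytest.raises(ValueError):
            ap.predict_survival(ref_fit, Stage.OLD_MALE, 1.5)


class TestChangeFactor:
    def test_anchor_is_exactly_one(self, ref_fit):
        for stage in MODELED_STAGES:
            assert ap.change_factor(ref_fit, stage, 0.07, 0.07) == 1.0

    def test_reference_stage_gain_at_zero_mortality(self, ref_fit):
        assert ap.change_factor(ref_fit, Stage.OLD_MALE, 0.0, 0.07) == pytest.approx(
            1.140, abs=0.001
        )

    def test_prime_female_loss_at_maximum_mortality(self, ref_fit):
        assert ap.change_factor(
            ref_fit, Stage.ADULT_FEMALE, 0.23, 0.07
        ) == pytest.approx(0.858, abs=0.001)

    def test_factor_reconstructs_prediction(self, ref_fit):
        # S(stage, m) = S(stage, m_mean) * change_factor to float precision
        for stage in MODELED_STAGES:
            for m in np.linspace(0.0, 0.3, 13):
                lhs = ap.predict_survival(ref_fit, stage, m)
                rhs = ap.predict_survival(ref_fit, stage, 0.07) * ap.change_factor(
                    ref_fit, stage, m, 0.07
                )
                assert lhs == pytest.approx(rhs, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        m1=st.floats(0.0, 0.3),
        m2=st.floats(0.0, 0.3),
        m_mean=st.floats(0.0, 0.3),
    )
    def test_strictly_decreasing_in_m_for_negative_slope(self, ref_fit, m1, m2, m_mean):
        if abs(m1 - m2) < 1e-6:
            return
        lo, hi = sorted((m1, m2))
        for stage in (Stage.OLD_MALE, Stage.ADULT_FEMALE):
            assert ap.change_factor(ref_fit, stage, lo, m_mean) > ap.change_factor(
                ref_fit, stage, hi, m_mean
            )


class TestNeonateLine:
    def test_symmetric_anchor_gives_zero_intercept(self, ref_fit):
        line = ap.build_neonate_line(ref_fit, s_neo=0.5, m_mean=0.0)
        assert line.intercept == pytest.approx(0.0, abs=1e-12)

    def test_known_algebraic_solution(self, ref_fit):
        line = ap.build_neonate_line(ref_fit, s_neo=0.6, m_mean=0.07)
        assert line.intercept == pytest.approx(0.7887, abs=1e-4)
        assert line.slope == ref_fit.slope

    @settings(max_examples=50, deadline=None)
    @given(s_neo=st.floats(0.01, 0.99), m_mean=st.floats(0.0, 0.3))
    def test_defining_constraint(self, ref_fit, s_neo, m_mean):
        line = ap.build_neonate_line(ref_fit, s_neo=s_neo, m_mean=m_mean)
        assert line.predict(m_mean) == pytest.approx(s_neo, abs=1e-9)
        assert line.change_factor(m_mean) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_baseline_rejected(self, ref_fit):
        with pytest.raises(ValueError):
            ap.build_neonate_line(ref_fit, s_neo=1.0, m_mean=0.07)


class TestChangeFactorTable:
    def test_covers_every_stage_including_neonate(self, ref_fit):
        table = ChangeFactorTable(
            ref_fit, ap.build_neonate_line(ref_fit, 0.65, 0.07), 0.07
        )
        factors = table.factors_at(0.23)
        assert set(factors) == set(MODELED_STAGES) | {Stage.NEONATE}
        assert all(0 < f < 1 for f in factors.values())
        assert table.at(Stage.NEONATE, 0.07) == pytest.approx(1.0, abs=1e-12)


class TestAdditivityCurve:
    WEIGHTS = {
        Stage.YEARLING: 0.10,
        Stage.SUBADULT: 0.09,
        Stage.YOUNG_ADULT: 0.22,
        Stage.ADULT_FEMALE: 0.22,
        Stage.ADULT_MALE: 0.17,
        Stage.OLD_FEMALE: 0.12,
        Stage.OLD_MALE: 0.08,
    }

    def test_maximum_at_zero_mortality_and_monotone(self, ref_fit):
        curve = ap.additivity_curve(ref_fit, self.WEIGHTS, np.linspace(0, 0.23, 24))
        assert curve["survival"].iloc[0] == curve["survival"].max()
        assert (np.diff(curve["survival"]) < 0).all()

    def test_compensatory_below_mean_additive_above(self, ref_fit):
        # below the mean rate, survival drops by less than one-for-one
        # (partly compensatory); from the mean up it tracks the additive line
        curve = ap.additivity_curve(ref_fit, self.WEIGHTS, [0.0, 0.07, 0.23])
        s = curve["survival"].to_numpy()
        below_slope = (s[0] - s[1]) / 0.07
        above_slope = (s[1] - s[2]) / 0.16
        assert below_slope < 1.0
        assert below_slope < above_slope
        assert above_slope == pytest.approx(1.0, abs=0.25)

    def test_bad_weights_and_empty_grid_rejected(self, ref_fit):
        with pytest.raises(ValueError):
            ap.additivity_curve(ref_fit, {Stage.OLD_MALE: 0.5}, [0.0])
        with pytest.raises(ValueError):
            ap.additivity_curve(ref_fit, self.WEIGHTS, [])


class TestFitContainer:
    def test_covariance_must_be_symmetric_8x8(self, ref_fit):
        with pytest.raises(ValueError):
            SurvivalModelFit(
                intercept=0.0,
                slope=-1.0,
                stage_offsets=dict(ref_fit.stage_offsets),
                coefficient_covariance=np.zeros((7, 7)),
            )
        bad = np.eye(8)
        bad[0, 1] = 0.5
        with pytest.raises(ValueError):
            SurvivalModelFit(
                intercept=0.0,
                slope=-1.0,
                stage_offsets=dict(ref_fit.stage_offsets),
                coefficient_covariance=bad,
            )

    def test_json_round_trip(self, ref_fit, tmp_path):
        path = tmp_path / "fit.json"
        ref_fit.to_json(path)
        back = SurvivalModelFit.from_json(path)
        assert np.allclose(back.beta, ref_fit.beta)
        assert np.allclose(back.coefficient_covariance, ref_fit.coefficient_covariance)

    def test_summary_table_layout(self, ref_fit):
        table = ref_fit.summary_table()
        assert list(table["parameter"]) == list(COEF_NAMES)
        assert (table["ci_lower"] < table["estimate"]).all()
        # published slope interval
        slope_row = table[table["parameter"] == "avalanche_mortality"].iloc[0]
        assert slope_row["ci_lower"] == pytest.approx(-7.849, abs=0.01)
        assert slope_row["ci_upper"] == pytest.approx(-3.101, abs=0.01)
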