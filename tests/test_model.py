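"""Unit and property tests for the sigmoidal D50 model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from d50track import (
    Aggressiveness,
    D50Model,
    IllPosedFitError,
    InsufficientDataError,
    InvalidArgumentError,
    Phase,
    classify_aggressiveness,
    classify_phase,
    compute_rd50,
    fit_cohort,
    fit_d50,
    predict_alsfrsr,
    progression_rate,
)
from conftest import grid_search_oracle

params = st.tuples(st.floats(1.0, 150.0), st.floats(0.5, 40.0))


class TestPredict:
    def test_half_score_at_d50(self):
        assert predict_alsfrsr(30.0, 30.0, 6.0) == pytest.approx(24.0, abs=1e-12)

    def test_closed_form_value(self):
        # 48 / (1 + e^1) at one decline-scale past D50
        assert predict_alsfrsr(36.0, 30.0, 6.0) == pytest.approx(
            48.0 / (1.0 + np.e), rel=1e-12)

    def test_asymptotes(self):
        assert predict_alsfrsr(1e6, 30.0, 6.0) == pytest.approx(0.0, abs=1e-9)
        assert predict_alsfrsr(-1e6, 30.0, 6.0) == pytest.approx(48.0, abs=1e-9)

    def test_nonfinite_t_rejected(self):
        with pytest.raises(InvalidArgumentError):
            predict_alsfrsr(np.nan, 30.0, 6.0)
        with pytest.raises(InvalidArgumentError):
            predict_alsfrsr(np.inf, 30.0, 6.0)

    @settings(deadline=None, max_examples=50)
    @given(params)
    def test_strictly_decreasing_and_bounded(self, p):
        d50, dx = p
        # stay inside the floating-point-representable band of the logistic
        t = np.linspace(d50 - 25 * dx, d50 + 25 * dx, 300)
        y = predict_alsfrsr(t, d50, dx)
        assert np.all(np.diff(y) < 0)
        assert np.all((y > 0) & (y < 48))


class TestRd50AndLabels:
    def test_anchors(self):
        assert compute_rd50(17.3, 0.0) == 0.0
        assert compute_rd50(30.0, 30.0) == 0.5
        assert compute_rd50(30.0, 60.0) == 1.0

    def test_errors(self):
        with pytest.raises(InvalidArgumentError):
            compute_rd50(0.0, 10.0)
        with pytest.raises(InvalidArgumentError):
            compute_rd50(30.0, -1.0)

    @pytest.mark.parametrize("rd50, phase", [
        (0.17, Phase.I), (0.34, Phase.II), (0.55, Phase.III_IV),
        (0.0, Phase.I), (0.25, Phase.II), (0.5, Phase.III_IV), (3.0, Phase.III_IV),
    ])
    def test_phase_partition(self, rd50, phase):
        assert classify_phase(rd50) is phase

    @pytest.mark.parametrize("d50, tier", [
        (8.92, Aggressiveness.HIGH),
        (26.43, Aggressiveness.INTERMEDIATE),
        (60.13, Aggressiveness.LOW),
        (20.0, Aggressiveness.INTERMEDIATE),
        (40.0, Aggressiveness.LOW),
    ])
    def test_aggressiveness_tiers(self, d50, tier):
        assert classify_aggressiveness(d50) is tier

    def test_label_errors(self):
        with pytest.raises(InvalidArgumentError):
            classify_phase(-0.01)
        with pytest.raises(InvalidArgumentError):
            classify_aggressiveness(0.0)

    @settings(deadline=None, max_examples=100)
    @given(st.floats(0.0, 5.0))
    def test_exactly_one_phase(self, rd50):
        assert classify_phase(rd50) in Phase


class TestProgressionRate:
    @pytest.mark.parametrize("score, dur, rate", [
        (48, 7.0, 0.0), (24, 24.0, 1.0), (36, 16.0, 0.75),
    ])
    def test_values(self, score, dur, rate):
        assert progression_rate(score, dur) == pytest.approx(rate)

    def test_errors(self):
        with pytest.raises(InvalidArgumentError):
            progression_rate(24, 0.0)
        with pytest.raises(InvalidArgumentError):
            progression_rate(49, 10.0)


class TestFit:
    def test_noiseless_recovery(self, noiseless_trajectory):
        t, y = noiseless_trajectory
        res = fit_d50(t, y)
        assert res.converged
        assert res.d50 == pytest.approx(30.0, rel=1e-6)
        assert res.dx == pytest.approx(6.0, rel=1e-6)
        assert res.predict(res.d50) == pytest.approx(24.0, abs=1e-9)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_d50([6.0], [40])

    def test_all_ceiling_ill_posed(self):
        with pytest.raises(IllPosedFitError):
            fit_d50([6.0, 12.0, 18.0], [48, 48, 48])

    def test_all_ceiling_flag_mode(self):
        res = D50Model([6.0, 12.0], [48, 48]).fit(on_no_decline="flag")
        assert not res.converged
        assert res.d50 == 300.0  # pinned at bound, never silent

    def test_two_observation_interpolation(self):
        res = fit_d50([10.0, 20.0], [40, 20], warn_onset=False)
        assert res.low_information
        assert res.rss == pytest.approx(0.0, abs=1e-12)
        assert res.predict(10.0) == pytest.approx(40.0, abs=1e-4)
        assert res.predict(20.0) == pytest.approx(20.0, abs=1e-4)

    def test_order_invariance(self, noiseless_trajectory):
        t, y = noiseless_trajectory
        rng = np.random.default_rng(3)
        perm = rng.permutation(t.size)
        a, b = fit_d50(t, y), fit_d50(t[perm], y[perm])
        assert a.d50 == b.d50 and a.dx == b.dx and a.rss == b.rss

    def test_time_rescaling_equivariance(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(2, 60, 7))
        y = np.rint(np.clip(predict_alsfrsr(t, 25.0, 5.0)
                            + rng.normal(0, 2, 7), 0, 48))
        a = fit_d50(t, y, warn_onset=False)
        k = 2.0
        b = fit_d50(k * t, y, warn_onset=False)
        assert b.d50 == pytest.approx(k * a.d50, rel=1e-4)
        assert b.dx == pytest.approx(k * a.dx, rel=1e-4)

    def test_duplicate_times_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_d50([5.0, 5.0, 10.0], [44, 43, 30])

    def test_matches_grid_oracle_on_noisy_instance(self):
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(1, 55, 6))
        y = np.rint(np.clip(predict_alsfrsr(t, 25.0, 5.0)
                            + rng.normal(0, 2, 6), 0, 48))
        res = fit_d50(t, y, warn_onset=False)
        gd50, gdx, grss = grid_search_oracle(t, y)
        assert res.rss <= grss + 1e-8
        assert res.d50 == pytest.approx(gd50, abs=0.06)
        assert res.dx == pytest.approx(gdx, abs=0.06)

    def test_summary_contains_estimates(self, noiseless_trajectory):
        t, y = noiseless_trajectory
        text = fit_d50(t, y).summary()
        assert "D50" in text and "30.000" in text

    def test_bse_finite_on_noisy_fit(self):
        rng = np.random.default_rng(9)
        t = np.sort(rng.uniform(1, 55, 8))
        y = np.rint(np.clip(predict_alsfrsr(t, 30.0, 6.0)
                            + rng.normal(0, 2, 8), 0, 48))
        res = fit_d50(t, y, warn_onset=False)
        assert np.all(np.isfinite(res.bse))
        ci = res.conf_int()
        assert ci[0, 0] < res.d50 < ci[0, 1]


def test_fit_cohort_accounts_for_every_patient(default_cohort):
    fits, excluded = fit_cohort(default_cohort.alsfrs)
    n_patients = default_cohort.alsfrs["patient_id"].nunique()
    assert len(fits) + len(excluded) == n_patients
    assert fits["converged"].all()
    # phases partition the fitted cohort exhaustively
    phases = [classify_phase(compute_rd50(d, t)).value
              for d, t in zip(fits["d50"], np.full(len(fits), 10.0))]
    assert len(phases) == len(fits)
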