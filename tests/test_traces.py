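"""Trace normalization, ratio channels, AUC, half-time, fold-change helpers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpcrbias.traces import (
    BaselineError,
    KineticTrace,
    delta_ct_expression,
    normalize_to_control,
    normalize_trace,
    ratiometric,
    response_t_half,
    trace_auc,
)
from conftest import make_trace


class TestNormalizeTrace:
    times = np.arange(0.0, 10.5, 0.5)

    def trace(self, values, **kw):
        kw.setdefault("baseline_end", 5.0)
        return make_trace(self.times, values, **kw)

    def test_constant_trace_with_constant_vehicles_is_unity(self):
        tr = self.trace(np.full_like(self.times, 100.0))
        veh = [self.trace(np.full_like(self.times, 100.0), well_id="V1")]
        out = normalize_trace(tr, veh)
        assert np.allclose(out.single_channel(), 1.0)

    def test_two_step_division_by_hand(self):
        sig = np.where(self.times < 5.0, 100.0, 150.0)
        tr = self.trace(sig)
        veh = [self.trace(np.full_like(self.times, 80.0), well_id="V1")]
        out = normalize_trace(tr, veh)
        assert np.allclose(out.single_channel()[self.times >= 5.0], 1.5)
        assert np.allclose(out.single_channel()[self.times < 5.0], 1.0)

    def test_agonist_identical_to_vehicle_mean_is_unity(self):
        sig = 100.0 + 10.0 * np.sin(self.times)
        tr = self.trace(sig)
        veh = [self.trace(sig, well_id="V1"), self.trace(sig, well_id="V2")]
        assert np.allclose(normalize_trace(tr, veh).single_channel(), 1.0)

    def test_idempotent_on_normalized_vehicle(self):
        tr = self.trace(np.full_like(self.times, 1.0))
        veh = [self.trace(np.full_like(self.times, 1.0), well_id="V1")]
        once = normalize_trace(tr, veh)
        twice = normalize_trace(once, [normalize_trace(v, veh) for v in veh])
        assert np.allclose(twice.single_channel(), 1.0)

    def test_nonpositive_baseline_flagged(self):
        tr = self.trace(np.concatenate([np.zeros(10), np.ones(11)]))
        veh = [self.trace(np.full_like(self.times, 100.0), well_id="V1")]
        with pytest.raises(BaselineError):
            normalize_trace(tr, veh)

    def test_mismatched_timebase_rejected(self):
        tr = self.trace(np.full_like(self.times, 100.0))
        veh = [make_trace(self.times[:-1], np.full(len(self.times) - 1, 100.0),
                          baseline_end=5.0, well_id="V1")]
        with pytest.raises(ValueError, match="timebase"):
            normalize_trace(tr, veh)


class TestRatiometric:
    def two_channel(self, num, den):
        t = np.arange(len(num), dtype=float)
        return KineticTrace("W1", t, {"620": np.asarray(num, float),
                                      "520": np.asarray(den, float)})

    def test_blank_subtracted_ratio(self):
        tr = self.two_channel([200.0] * 3, [1000.0] * 3)
        out = ratiometric(tr, "620", "520", blank={"620": 20.0, "520": 100.0})
        assert np.allclose(out.single_channel(), 0.2)

    def test_equal_channels_give_unity(self):
        tr = self.two_channel([5.0, 7.0, 9.0], [5.0, 7.0, 9.0])
        assert np.allclose(ratiometric(tr, "620", "520").single_channel(), 1.0)

    def test_deret_style_drift_is_monotone_increasing(self):
        num = np.linspace(100, 200, 20)
        den = np.linspace(1000, 600, 20)
        out = ratiometric(self.two_channel(num, den), "620", "520")
        assert (np.diff(out.single_channel()) > 0).all()

    def test_nonpositive_denominator_masked_not_fatal(self):
        tr = self.two_channel([10.0, 10.0, 10.0], [5.0, 0.5, 5.0])
        out = ratiometric(tr, "620", "520", blank={"520": 1.0})
        vals = out.single_channel()
        assert np.isnan(vals[1]) and np.isfinite(vals[[0, 2]]).all()
        assert out.flags

    @settings(deadline=None, max_examples=25)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_commutes_with_common_positive_rescaling(self, k):
        tr = self.two_channel([3.0, 4.0, 5.0], [6.0, 5.0, 4.0])
        scaled = self.two_channel(np.array([3.0, 4.0, 5.0]) * k,
                                  np.array([6.0, 5.0, 4.0]) * k)
        a = ratiometric(tr, "620", "520").single_channel()
        b = ratiometric(scaled, "620", "520").single_channel()
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestTraceAuc:
    def test_rectangle(self):
        tr = make_trace(np.linspace(0, 30, 61), np.ones(61))
        assert trace_auc(tr) == pytest.approx(30.0)

    def test_triangle(self):
        t = np.linspace(0, 10, 101)
        assert trace_auc(make_trace(t, t / 10.0)) == pytest.approx(5.0)

    def test_exponential_approach_close_to_analytic(self):
        t = np.arange(0, 30.0001, 0.5)
        y = 1.0 - np.exp(-t / 5.0)
        analytic = 30.0 - 5.0 * (1.0 - np.exp(-6.0))  # 25.0124
        assert trace_auc(make_trace(t, y)) == pytest.approx(analytic, rel=1e-3)

    def test_additive_over_contiguous_intervals_and_exact_piecewise_linear(self):
        t = np.array([0.0, 1.0, 2.5, 4.0, 7.0])
        y = np.array([0.0, 2.0, 2.0, -1.0, 3.0])
        left = trace_auc(make_trace(t[:3], y[:3]))
        right = trace_auc(make_trace(t[2:], y[2:]))
        assert left + right == pytest.approx(trace_auc(make_trace(t, y)), abs=1e-12)

    def test_baseline_correction_zeroes_flat_trace(self):
        t = np.arange(0.0, 20.5, 0.5)
        tr = make_trace(t, np.full_like(t, 7.0), baseline_end=5.0)
        assert trace_auc(tr, baseline_correct=True) == pytest.approx(0.0, abs=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            trace_auc(make_trace([0.0, 1.0], [1.0, 1.0], baseline_end=0.75))


class TestResponseTHalf:
    def test_exponential_association_half_time(self):
        k = np.log(2) / 1.5
        t = np.arange(0, 30.001, 0.5)
        tr = make_trace(t, 1.0 - np.exp(-k * t))
        assert response_t_half(tr) == pytest.approx(1.5, abs=1e-3)

    def test_step_interpolates_midpoint(self):
        t = np.arange(0, 10.5, 0.5)
        y = (t >= 5.5).astype(float)
        assert response_t_half(make_trace(t, y)) == pytest.approx(5.25)

    def test_flat_trace_reports_missing(self):
        t = np.arange(0, 10.5, 0.5)
        assert response_t_half(make_trace(t, np.ones_like(t))) is None

    @pytest.mark.parametrize("dt", [1.0, 0.5, 0.1, 0.02])
    def test_converges_to_ln2_over_k_with_finer_sampling(self, dt):
        k = 0.31
        t = np.arange(0, 30 + dt / 2, dt)
        th = response_t_half(make_trace(t, 1.0 - np.exp(-k * t)))
        assert abs(th - np.log(2) / k) < dt  # error bounded by the read interval

    def test_fit_method_agrees_on_clean_association(self):
        k = 0.2
        t = np.arange(0, 30.001, 0.5)
        tr = make_trace(t, 5.0 * (1.0 - np.exp(-k * t)))
        assert response_t_half(tr, method="fit") == pytest.approx(np.log(2) / k, rel=1e-6)


class TestNormalizeToControl:
    def table(self):
        return pd.DataFrame({
            "condition": ["agonist", "forskolin", "forskolin", "agonist", "forskolin"],
            "response": [5.4, 10.0, 10.0, 3.0, 6.0],
            "block": ["B1", "B1", "B1", "B2", "B2"],
        })

    def test_percent_of_forskolin(self):
        out = normalize_to_control(self.table(), "forskolin", mode="percent")
        assert out.loc[0, "response"] == pytest.approx(54.0)  # 5.4 / 10 * 100
        assert out.loc[out["condition"] == "forskolin", "response"].iloc[0] == 100.0

    def test_fold_change_of_unstimulated(self):
        df = pd.DataFrame({"condition": ["stim", "unstim"], "response": [0.06, 0.05],
                           "block": ["B1", "B1"]})
        out = normalize_to_control(df, "unstim", mode="fold")
        assert out.loc[0, "response"] == pytest.approx(1.2)
        assert out.loc[1, "response"] == pytest.approx(1.0)

    def test_nonpositive_control_block_excluded(self):
        df = self.table()
        df.loc[df["block"] == "B2", "response"] = [0.0, -6.0]
        out = normalize_to_control(df, "forskolin")
        assert set(out["block"]) == {"B1"}


@pytest.mark.parametrize("ct_t, ct_r, expected", [
    (20.0, 10.0, 2.0 ** -10),
    (15.0, 15.0, 1.0),
    (14.0, 15.0, 2.0),
])
def test_delta_ct_expression(ct_t, ct_r, expected):
    assert delta_ct_expression(ct_t, ct_r) == pytest.approx(expected, rel=1e-12)


def test_delta_ct_missing_is_nan():
    assert np.isnan(delta_ct_expression(float("nan"), 15.0))
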