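"""Curve-analytics tests: normalization, AUC, zero timing, termination."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecisbarrier.timecourse import (
    TimeCourse,
    ZeroReferenceError,
    analysis_frequency,
    auc,
    detect_confluence,
    endpoint,
    first_zero_time,
    normalize,
    surface_matrix,
    terminate_dependent_curves,
)


def tc(times, values, mask=None, **kw):
    return TimeCourse(times=np.asarray(times, float), values=np.asarray(values, float),
                      mask=mask, **kw)


class TestNormalize:
    def test_reference_point_is_exactly_one(self):
        c = normalize(tc([0, 1, 2], [2, 4, 6]))
        assert c.values[0] == 1.0
        assert list(c.values) == [1.0, 2.0, 3.0]
        assert c.ref_value == 2.0

    def test_constant_curve_normalizes_to_one(self):
        c = normalize(tc([0, 1, 2], [5, 5, 5]))
        assert np.allclose(c.values, 1.0)

    def test_zero_reference_refused_with_context(self):
        with pytest.raises(ZeroReferenceError, match="W007"):
            normalize(tc([0, 1], [0, 3], well="W007", quantity="Rb"))

    def test_normalize_then_endpoint_at_reference_is_one(self):
        c = normalize(tc([0, 1, 2], [3.3, 2.2, 1.1]))
        assert endpoint(c, 0.0) == 1.0


class TestAuc:
    def test_constant_one_over_thirty_hours(self):
        c = normalize(tc(np.arange(0, 30.25, 0.25), np.ones(121)))
        assert auc(c, 0, 30).area == pytest.approx(30.0)

    def test_linear_decay_to_zero(self):
        t = np.linspace(0, 30, 121)
        c = tc(t, 1 - t / 30)
        assert auc(c, 0, 30).area == pytest.approx(15.0)

    def test_hand_trapezoid(self):
        assert auc(tc([0, 1, 2], [1, 0.5, 0.5]), 0, 2).area == pytest.approx(1.25)

    def test_terminated_curve_reports_realized_span(self):
        mask = np.array([True, True, True, False, False])
        res = auc(tc([0, 1, 2, 3, 4], [1, 1, 1, 1, 1], mask=mask), 0, 4)
        assert res.area == pytest.approx(2.0)
        assert (res.t_start, res.t_end) == (0.0, 2.0)

    def test_empty_window_is_an_error(self):
        mask = np.array([True, False, False])
        with pytest.raises(ValueError):
            auc(tc([0, 1, 2], [1, 1, 1], mask=mask), 1, 2)

    @given(split=st.floats(0.3, 2.7))
    def test_additive_over_adjacent_intervals(self, split):
        t = np.linspace(0, 3, 31)
        c = tc(t, np.sin(t) + 2)
        total = auc(c, 0, 3).area
        assert auc(c, 0, split).area + auc(c, split, 3).area == pytest.approx(total)

    def test_invariant_under_collinear_insertion(self):
        c1 = tc([0, 2], [1, 3])
        c2 = tc([0, 1, 2], [1, 2, 3])
        assert auc(c1, 0, 2).area == pytest.approx(auc(c2, 0, 2).area)


class TestEndpoint:
    def test_grid_point_returns_stored_value(self):
        assert endpoint(tc([0, 1, 2], [5, 7, 9]), 1.0) == 7.0

    def test_midpoint_is_linear_interpolation(self):
        assert endpoint(tc([0, 1], [1, 3]), 0.5) == 2.0

    def test_after_termination_is_an_error(self):
        mask = np.array([True, True, False])
        with pytest.raises(ValueError):
            endpoint(tc([0, 1, 2], [1, 1, 1], mask=mask), 2.0)


class TestFirstZeroTime:
    def test_never_zero_returns_none(self):
        assert first_zero_time(tc([0, 1, 2], [5, 5, 5])) is None

    def test_immediate_sustained_zero(self):
        t = [0, 0.25, 0.5, 0.75, 1.0]
        assert first_zero_time(tc(t, [5, 0, 0, 0, 0])) == 0.25

    def test_transient_rebound_ignored_by_sustain_rule(self):
        """A genuine rebound moves the zero time to the final return."""
        t = [0, 0.25, 0.5, 0.75, 1.0, 1.25]
        assert first_zero_time(tc(t, [5, 0, 3, 0, 0, 0])) == 0.75

    def test_brute_force_oracle_agreement(self):
        """Against an exhaustive scan implementing the same convention."""
        rng = np.random.default_rng(3)

        def oracle(t, v, eps, k):
            cand = None
            for i in range(len(t)):
                if t[i] <= 0 or v[i] > eps:
                    continue
                if not any(v[j] >= k * eps for j in range(i + 1, len(t))):
                    cand = t[i]
                    break
            return cand

        for _ in range(200):
            n = rng.integers(3, 15)
            t = np.arange(n) * 0.5
            v = np.round(rng.uniform(0, 1, n), 2) * rng.integers(0, 2, n)
            got = first_zero_time(tc(t, v), eps=0.05, rebound_factor=5.0)
            assert got == oracle(t, v, 0.05, 5.0)

    def test_order_preserved_under_pointwise_domination(self):
        rng = np.random.default_rng(11)
        t = np.arange(12) * 0.5
        for _ in range(100):
            lo = rng.uniform(0, 2, 12) * rng.integers(0, 2, 12)
            hi = lo + rng.uniform(0, 2, 12)
            z_lo = first_zero_time(tc(t, lo), eps=0.05, rebound_factor=1.0)
            z_hi = first_zero_time(tc(t, hi), eps=0.05, rebound_factor=1.0)
            if z_hi is not None:
                assert z_lo is not None and z_lo <= z_hi


class TestTermination:
    def test_none_leaves_curves_unchanged(self):
        a, c = tc([0, 1], [1, 1]), tc([0, 1], [1, 1])
        a2, c2 = terminate_dependent_curves(a, c, None)
        assert a2.mask.all() and c2.mask.all()

    def test_zero_time_zero_empties_curves(self):
        a, c = tc([0, 1], [1, 1]), tc([0, 1], [1, 1])
        a2, c2 = terminate_dependent_curves(a, c, 0.0)
        assert not a2.mask.any() and not c2.mask.any()

    def test_last_valid_sample_strictly_before_zero_time(self):
        t = np.arange(0, 5.0, 0.5)
        a, c = tc(t, np.ones_like(t)), tc(t, np.ones_like(t))
        a2, _ = terminate_dependent_curves(a, c, 2.5)
        assert a2.valid_times[-1] == 2.0

    def test_no_alpha_reported_at_or_after_zero_time(self):
        """Global audit of the termination contract."""
        t = np.arange(0, 10.0, 0.25)
        a, c = tc(t, np.ones_like(t)), tc(t, np.ones_like(t))
        for zt in (0.25, 3.0, 7.75):
            a2, c2 = terminate_dependent_curves(a, c, zt)
            assert np.all(a2.valid_times < zt)
            assert np.all(c2.valid_times < zt)


class TestDetectConfluence:
    def test_never_below_threshold(self):
        t = np.arange(0, 20, 0.5)
        assert detect_confluence(tc(t, np.full(t.size, 30.0))) is None

    def test_step_reaches_dwell(self):
        t = np.arange(0, 20.25, 0.25)
        v = np.where(t < 10, 30.0, 15.0)
        assert detect_confluence(tc(t, v), threshold_nf=20.0, dwell_h=2.0) == 12.0

    def test_interrupted_run_restarts_dwell(self):
        t = np.arange(0, 10.25, 0.25)
        v = np.full(t.size, 15.0)
        v[t == 1.0] = 25.0  # blip resets the dwell clock
        assert detect_confluence(tc(t, v), dwell_h=2.0) == pytest.approx(3.25)


class TestAnalysisFrequency:
    def test_defaults(self):
        assert analysis_frequency("resistance") == 4000.0
        assert analysis_frequency("capacitance") == 64000.0

    def test_override_honoured(self):
        assert analysis_frequency("resistance", {"resistance": 2000.0}) == 2000.0

    def test_unknown_quantity_rejected(self):
        with pytest.raises(ValueError):
            analysis_frequency("admittance")


class TestSurfaceMatrix:
    def test_shape_and_unit_start(self):
        times = np.arange(0, 5.0, 0.5)
        freqs = np.array([250.0 * 2 ** k for k in range(9)])
        z = np.outer(np.linspace(1, 2, 9), np.linspace(4, 8, times.size))
        m = surface_matrix(times, freqs, z)
        assert m.shape == (9, times.size)
        assert np.allclose(m.iloc[:, 0], 1.0)

    def test_row_consistent_with_1d_normalized_curve(self):
        times = np.arange(0, 5.0, 0.5)
        freqs = np.array([4000.0, 64000.0])
        z = np.vstack([np.linspace(3, 6, times.size), np.linspace(2, 2, times.size)])
        m = surface_matrix(times, freqs, z)
        curve = normalize(tc(times, z[0]))
        assert np.allclose(m.loc[4000.0].to_numpy(), curve.values)
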