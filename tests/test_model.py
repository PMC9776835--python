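"""Forward-model unit and property tests.

The independent Bessel oracle here is an arbitrary-precision power-series
evaluation (mpmath); the production path goes through scipy's scaled
complex Bessel functions, so the two share no code.
"""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecisbarrier.model import (
    BarrierParams,
    ElectrodeModel,
    FrequencyGrid,
    NonCapacitiveError,
    bessel_ratio,
    gk_covered_impedance,
    membrane_impedance,
    naked_impedance,
    series_rc,
    well_impedance,
)


def mp_bessel_ratio(z: complex) -> complex:
    """(z/2) I0(z)/I1(z) via 50-digit series evaluation (independent oracle)."""
    import mpmath

    with mpmath.workdps(50):
        zm = mpmath.mpc(z)
        i0 = mpmath.besseli(0, zm)
        i1 = mpmath.besseli(1, zm)
        return complex(zm / 2 * i0 / i1)


class TestFrequencyGrid:
    def test_default_grid_is_nine_octaves_from_250(self):
        g = FrequencyGrid.default()
        assert len(g) == 9
        assert g.frequencies == tuple(250.0 * 2 ** k for k in range(9))

    @pytest.mark.parametrize("freqs", [(), (0.0, 100.0), (100.0, 100.0), (200.0, 100.0)])
    def test_invalid_grids_rejected(self, freqs):
        with pytest.raises(ValueError):
            FrequencyGrid(freqs)


class TestNakedImpedance:
    def test_beta_one_is_ideal_capacitor(self):
        c0 = 1e-6  # F/cm^2
        m = ElectrodeModel(cpe_magnitude=1.0 / c0, cpe_exponent=1.0)
        f = 4000.0
        zn = naked_impedance(m, f)
        assert zn.real == pytest.approx(0.0, abs=1e-12 * abs(zn))
        assert zn.imag == pytest.approx(-1.0 / (2 * math.pi * f * c0), rel=1e-12)

    def test_magnitude_and_phase_match_complex_power(self):
        import mpmath

        m = ElectrodeModel(cpe_magnitude=5.0e4, cpe_exponent=0.9)
        f = 4000.0
        zn = naked_impedance(m, f)
        with mpmath.workdps(40):
            w = mpmath.mpf(2) * mpmath.pi * f
            expected = complex(mpmath.mpf(m.cpe_magnitude) * (1j * w) ** (-mpmath.mpf(0.9)))
        assert zn == pytest.approx(expected, rel=1e-12)
        assert np.angle(zn) == pytest.approx(-0.9 * math.pi / 2, rel=1e-12)

    def test_doubling_frequency_halves_magnitude_at_beta_one(self):
        m = ElectrodeModel(cpe_exponent=1.0)
        assert abs(naked_impedance(m, 500.0)) == pytest.approx(
            abs(naked_impedance(m, 1000.0)) * 2, rel=1e-12)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            naked_impedance(ElectrodeModel(), 0.0)


class TestMembraneImpedance:
    def test_unit_omega_value(self):
        # omega = 1 rad/s: Zm = 2/(j Cm') = -2j/Cm'
        zm = membrane_impedance(1.0, 1.0 / (2 * math.pi))
        assert zm == pytest.approx(-2e6j, rel=1e-12)

    def test_hand_value_at_4khz(self):
        zm = membrane_impedance(1.5, 4000.0)
        assert zm.real == 0.0
        assert abs(zm) == pytest.approx(2.0 / (2 * math.pi * 4000 * 1.5e-6), rel=1e-12)

    def test_magnitude_halves_when_cm_doubles(self):
        assert abs(membrane_impedance(2.0, 1000.0)) == pytest.approx(
            abs(membrane_impedance(1.0, 1000.0)) / 2, rel=1e-12)

    def test_nonpositive_cm_rejected(self):
        with pytest.raises(ValueError):
            membrane_impedance(0.0, 1000.0)


class TestGkCoveredImpedance:
    def test_invisible_layer_identity(self, electrode, grid):
        """Rb = alpha = 0 makes the cell layer electrically invisible."""
        p = BarrierParams(rb=0.0, alpha=0.0, cm=1.5)
        for f in grid:
            zn = naked_impedance(electrode, f)
            zc = gk_covered_impedance(zn, membrane_impedance(1.5, f), p)
            assert abs(zc - zn) <= 1e-10 * abs(zn)

    def test_infinite_rb_limit_is_series_membrane(self, electrode):
        f = 4000.0
        zn = naked_impedance(electrode, f)
        zm = membrane_impedance(1.5, f)
        p = BarrierParams(rb=1e9, alpha=8.0, cm=1.5)
        zc = gk_covered_impedance(zn, zm, p)
        assert zc == pytest.approx(zn + zm, rel=1e-6)

    def test_against_series_oracle(self, electrode):
        """Cross-check vs the independent high-precision Bessel series."""
        import mpmath

        f = 4000.0
        zn = complex(naked_impedance(electrode, f))
        zm = complex(membrane_impedance(1.5, f))
        p = BarrierParams(rb=4.0, alpha=8.0, cm=1.5)
        inv = 1.0 / zn + 1.0 / zm
        gamma = p.alpha * np.sqrt(inv)
        denom = mp_bessel_ratio(complex(gamma)) + p.rb * inv
        bracket = zn / (zn + zm) + (zm / (zn + zm)) / denom
        expected = zn / bracket
        got = gk_covered_impedance(zn, zm, p)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_continuity_across_bessel_series_cutoff(self, electrode):
        f = 4000.0
        zn = naked_impedance(electrode, f)
        zm = membrane_impedance(1.5, f)
        vals = [gk_covered_impedance(zn, zm, BarrierParams(rb=1.0, alpha=a, cm=1.5))
                for a in (1e-9, 1e-6, 1e-4, 1e-3)]
        for v in vals[1:]:
            assert v == pytest.approx(vals[0], rel=1e-6)


class TestWellImpedance:
    def test_zero_coverage_is_naked_well(self, electrode):
        p = BarrierParams(rb=4.0, alpha=8.0, cm=1.5)
        f = 4000.0
        zw = well_impedance(electrode.with_coverage(0.0), p, f)
        expected = (naked_impedance(electrode, f) / electrode.electrode_area
                    + electrode.series_resistance)
        assert zw == pytest.approx(expected, rel=1e-12)

    def test_full_coverage_invisible_layer_matches_naked(self, electrode):
        p0 = BarrierParams(rb=0.0, alpha=0.0, cm=1.5)
        f = 4000.0
        assert well_impedance(electrode.with_coverage(1.0), p0, f) == pytest.approx(
            well_impedance(electrode.with_coverage(0.0), p0, f), rel=1e-12)

    def test_vehicle_well_is_finite_above_series_resistance(self, electrode, grid):
        p = BarrierParams(rb=4.0, alpha=8.0, cm=1.5)
        zw = well_impedance(electrode, p, 4000.0)
        assert np.isfinite(zw)
        assert zw.real > electrode.series_resistance

    def test_well_magnitude_monotone_in_rb(self, electrode, grid):
        """|Z_well| never decreases as the paracellular barrier tightens.

        Swept over the barrier-dominated regime (0.01-20 ohm cm^2).  Once
        Rb exceeds the transcellular shunt scale (|Zm| ~ 3 ohm cm^2 at
        64 kHz) current reroutes through the membranes, |Z| saturates
        toward |Zn + Zm| and shows a sub-0.25% non-monotone ripple; that
        saturation is model physics, so monotonicity is asserted where the
        paracellular term dominates.
        """
        for f in grid:
            mags = [abs(well_impedance(electrode, BarrierParams(rb=rb, alpha=8.0, cm=1.5), f))
                    for rb in np.logspace(-2, np.log10(20), 25)]
            assert np.all(np.diff(mags) >= -1e-9 * np.asarray(mags[1:]))

    def test_capacitance_rises_as_coverage_falls(self, electrode):
        """At 64 kHz the series-C reading is a coverage/spreading proxy."""
        p = BarrierParams(rb=4.0, alpha=8.0, cm=1.5)
        f = 64000.0
        caps = [series_rc(complex(well_impedance(electrode.with_coverage(phi), p, f)), f).capacitance
                for phi in (1.0, 0.8, 0.6, 0.4, 0.2, 0.0)]
        assert np.all(np.diff(caps) > 0)


class TestSeriesRc:
    def test_unit_omega_example(self):
        r = series_rc(50 - 1000j, 1.0 / (2 * math.pi))
        assert r.resistance == 50.0
        assert r.capacitance == pytest.approx(1e-3, rel=1e-12)

    def test_purely_real_reading_rejected_with_context(self):
        with pytest.raises(NonCapacitiveError) as exc:
            series_rc(100.0 + 0j, 4000.0, well="W001", time_h=1.5)
        assert exc.value.well == "W001"
        assert exc.value.frequency_hz == 4000.0

    @given(
        r=st.floats(1e-3, 1e6),
        c=st.floats(1e-12, 1e-3),
        f=st.floats(1.0, 1e6),
    )
    def test_round_trip_is_identity(self, r, c, f):
        z = r + 1.0 / (1j * 2 * math.pi * f * c)
        got = series_rc(z, f)
        assert got.resistance == pytest.approx(r, rel=1e-9)
        assert got.capacitance == pytest.approx(c, rel=1e-9)


class TestBesselRatio:
    @pytest.mark.parametrize("z", [
        0.5 + 0.0j, 2.0 - 3.0j, -4.0 + 1.0j, 10.0 + 10.0j, 0.01 - 0.02j,
        19.0 * np.exp(1j * 3.0), 15.0 * np.exp(-1j * 2.5),
    ])
    def test_matches_high_precision_series(self, z):
        assert bessel_ratio(z) == pytest.approx(mp_bessel_ratio(z), rel=1e-10)

    def test_origin_limit(self):
        assert bessel_ratio(0.0) == pytest.approx(1.0, rel=1e-14)
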