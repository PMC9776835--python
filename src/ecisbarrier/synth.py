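"""Synthetic multi-well ECIS study generator.

The generator emulates the drug-response study this package is built to
analyse: confluent human retinal endothelial monolayers on a 96-well
microelectrode array, treated at t = 0 with mitochondrial OxPhos inhibitors
and monitored for 30 h at nine AC frequencies (250-64,000 Hz), n = 6 wells
per arm.  Each treatment arm is a set of ground-truth trajectories for the
barrier state (Rb, alpha, Cm) and electrode coverage phi; wells draw a
lognormal baseline jitter, the trajectories are pushed through the forward
model on a 0.25 h grid, and 1% multiplicative Gaussian noise is applied
independently to the real and imaginary parts of every impedance reading.

Arm phenotypes (all timings are ground-truth breakpoints):

* ``vehicle`` - flat trajectories.
* ``rotenone`` 1/10 uM - complex I inhibition: Rb = 0 immediately after
  treatment; coverage declines dose-dependently with a transient shoulder
  (momentary spreading maximum, deceleration, steady increase in C).
* ``fccp`` 10 uM - OxPhos uncoupling, high dose: Rb = 0 immediately; the
  post-treatment (alpha, Cm) plateau is solved numerically so the
  normalized 64 kHz capacitance plateaus at 6.0x vehicle.
* ``fccp`` 1 uM - Rb dips to zero, rebounds, and makes its final sustained
  return to zero at 2.5 h; alpha dips ~7% within (0, 2.5) h recovering at
  2.5 h; Cm is elevated; the capacitance path is pinned to reach the
  10 uM plateau level at t = 20 h.
* ``oligomycin`` 1 uM - Rb dips mid-experiment, re-approaches vehicle, and
  reaches zero only at 29 h (28-30 h window); capacitance ~ vehicle.
* ``oligomycin`` 10 uM - Rb reaches zero at 3.4 h (3.2-3.6 h window); the
  total resistance reaches its minimum at 12-15 h; capacitance reaches the
  high-dose FCCP plateau level near 20 h.

Where the narrative gives a range the defaults target the midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .model import (
    BarrierParams,
    ElectrodeModel,
    FrequencyGrid,
    naked_impedance,
    series_rc,
    well_impedance,
)

__all__ = [
    "Trajectory",
    "ArmSpec",
    "SimConfig",
    "BASELINE",
    "default_arms",
    "simulate_dataset",
    "simulate_ldh",
    "capacitance_ratio",
]

#: Baseline barrier state of a confluent, untreated monolayer.  These are
#: plausible endothelial values chosen as the generator's working point (no
#: tabulated baselines exist for this cell type), documented in the methods
#: note.
BASELINE = {"rb": 4.0, "alpha": 8.0, "cm": 1.5}


@dataclass(frozen=True)
class Trajectory:
    """Piecewise-smooth trajectory through (time, value) breakpoints.

    Monotone cubic (PCHIP) interpolation between breakpoints: smooth ramps
    without overshoot, so a segment pinned at zero stays exactly zero.
    """

    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size or t.size < 2:
            raise ValueError("need >= 2 matching breakpoints")
        if np.any(np.diff(t) <= 0):
            raise ValueError("breakpoint times must be strictly ascending")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    @classmethod
    def constant(cls, value: float, horizon: float = 30.0) -> "Trajectory":
        return cls((0.0, horizon), (value, value))

    def __call__(self, t) -> np.ndarray:
        interp = PchipInterpolator(np.asarray(self.times), np.asarray(self.values),
                                   extrapolate=False)
        t = np.asarray(t, dtype=float)
        out = interp(np.clip(t, self.times[0], self.times[-1]))
        return out

    def scaled(self, factor: float) -> "Trajectory":
        return Trajectory(self.times, tuple(v * factor for v in self.values))


@dataclass(frozen=True)
class ArmSpec:
    """One treatment arm: label, ground-truth trajectories and effect sizes."""

    label: str
    rb: Trajectory
    alpha: Trajectory
    cm: Trajectory
    phi: Trajectory
    n_wells: int = 6
    baseline_cv: float = 0.05
    ldh_effect_24h: float = 0.0
    ldh_effect_48h: float = 0.0

    def __post_init__(self) -> None:
        if self.n_wells < 2:
            raise ValueError("n_wells must be >= 2")
        if not (0.0 <= self.baseline_cv < 1.0):
            raise ValueError("baseline_cv must lie in [0, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Acquisition settings of the simulated study."""

    dt: float = 0.25
    horizon: float = 30.0
    grid: FrequencyGrid = field(default_factory=FrequencyGrid.default)
    noise_sd: float = 0.01
    seed: int = 0
    electrode: ElectrodeModel = field(default_factory=ElectrodeModel)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.horizon <= 0:
            raise ValueError("dt and horizon must be positive")

    def time_grid(self) -> np.ndarray:
        n = int(round(self.horizon / self.dt))
        return np.linspace(0.0, n * self.dt, n + 1)


def capacitance_ratio(params: BarrierParams, model: ElectrodeModel,
                      baseline: BarrierParams | None = None,
                      f: float = 64000.0) -> float:
    """Series-capacitance ratio of a barrier state versus the baseline state.

    This is the noise-free normalized capacitance a well would show at
    frequency ``f`` after moving from ``baseline`` to ``params``.
    """
    if baseline is None:
        baseline = BarrierParams(**BASELINE)
    c1 = series_rc(complex(well_impedance(model, params, f)), f).capacitance
    c0 = series_rc(complex(well_impedance(model, baseline, f)), f).capacitance
    return c1 / c0


def _solve_alpha_for_ratio(target: float, cm: float, model: ElectrodeModel,
                           rb: float = 0.0) -> float:
    """Alpha (at given Rb, Cm) whose 64 kHz capacitance ratio equals target."""

    def gap(a: float) -> float:
        return capacitance_ratio(BarrierParams(rb=rb, alpha=a, cm=cm), model) - target

    return brentq(gap, 1e-6, BASELINE["alpha"], xtol=1e-10)


def default_arms(electrode: ElectrodeModel | None = None,
                 n_wells: int = 6) -> list[ArmSpec]:
    """The seven default treatment arms, fully parameterized.

    The high-dose FCCP plateau state is solved so its 64 kHz normalized
    capacitance is exactly 6.0x the vehicle baseline; the low-dose FCCP
    alpha trajectory passes through that same plateau alpha at t = 20 h
    (with identical Cm from 10 h on), so its capacitance catches up with
    the high-dose plateau at 20 h by construction.
    """
    model = electrode or ElectrodeModel()
    rb0, a0, cm0 = BASELINE["rb"], BASELINE["alpha"], BASELINE["cm"]
    cm_hi = 3.0  # uF/cm^2, elevated membrane capacitance after uncoupling
    a6 = _solve_alpha_for_ratio(6.0, cm_hi, model)

    flat_phi = Trajectory.constant(1.0)
    arms = [
        ArmSpec(
            label="vehicle",
            rb=Trajectory.constant(rb0),
            alpha=Trajectory.constant(a0),
            cm=Trajectory.constant(cm0),
            phi=flat_phi, n_wells=n_wells,
        ),
        ArmSpec(
            label="fccp_1uM",
            # collapse, rebound, final sustained return to zero at 2.5 h
            rb=Trajectory((0.0, 0.25, 0.6, 1.0, 1.6, 2.25, 2.5, 30.0),
                          (rb0, 0.0, 1.0, 2.0, 1.5, 0.4, 0.0, 0.0)),
            # ~7% dip on (0, 2.5) h, recovered at 2.5 h, then the slow
            # adhesion loss that drives the capacitance catch-up at 20 h
            alpha=Trajectory((0.0, 0.5, 1.5, 2.4, 2.5, 8.0, 14.0, 20.0, 25.0, 30.0),
                             (a0, 0.93 * a0, 0.93 * a0, 0.995 * a0, a0,
                              6.4, 4.4, a6, 0.80 * a6, 0.75 * a6)),
            cm=Trajectory((0.0, 0.5, 2.5, 6.0, 10.0, 30.0),
                          (cm0, 1.9, 2.0, 2.5, cm_hi, cm_hi)),
            phi=flat_phi, n_wells=n_wells,
            ldh_effect_24h=0.0, ldh_effect_48h=0.0,
        ),
        ArmSpec(
            label="fccp_10uM",
            rb=Trajectory((0.0, 0.25, 30.0), (rb0, 0.0, 0.0)),
            alpha=Trajectory((0.0, 0.5, 1.0, 30.0), (a0, 2.0 * a6, a6, a6)),
            cm=Trajectory((0.0, 0.75, 30.0), (cm0, cm_hi, cm_hi)),
            phi=flat_phi, n_wells=n_wells,
            ldh_effect_24h=0.30, ldh_effect_48h=0.45,
        ),
        ArmSpec(
            label="oligomycin_1uM",
            # shallow dip, recovery toward vehicle, zero only at 29 h
            rb=Trajectory((0.0, 4.0, 10.0, 18.0, 26.0, 27.5, 29.0, 30.0),
                          (rb0, 3.2, 2.6, 3.0, 3.7, 2.0, 0.0, 0.0)),
            alpha=Trajectory.constant(a0),
            cm=Trajectory.constant(cm0),
            phi=flat_phi, n_wells=n_wells,
        ),
        ArmSpec(
            label="oligomycin_10uM",
            # barrier collapse complete at 3.4 h (3.2-3.6 h window)
            rb=Trajectory((0.0, 0.75, 2.4, 3.4, 30.0),
                          (rb0, 2.8, 1.2, 0.0, 0.0)),
            # adhesion decline drives R to its minimum at ~13.5 h
            alpha=Trajectory((0.0, 3.4, 8.0, 13.5, 20.0, 30.0),
                             (a0, 0.97 * a0, 5.5, 3.2, 2.3, 2.1)),
            # Cm rise brings the capacitance to the FCCP plateau near 20 h
            cm=Trajectory((0.0, 3.4, 13.0, 20.0, 30.0),
                          (cm0, 1.6, 2.2, cm_hi, cm_hi)),
            phi=flat_phi, n_wells=n_wells,
            ldh_effect_24h=0.30, ldh_effect_48h=0.45,
        ),
        ArmSpec(
            label="rotenone_1uM",
            rb=Trajectory((0.0, 0.25, 30.0), (rb0, 0.0, 0.0)),
            alpha=Trajectory((0.0, 2.0, 10.0, 30.0), (a0, 6.0, 4.0, 3.0)),
            cm=Trajectory((0.0, 5.0, 30.0), (cm0, 1.8, 2.0)),
            # transient spreading shoulder, then steady coverage loss
            phi=Trajectory((0.0, 1.0, 2.5, 5.0, 30.0),
                           (1.0, 0.93, 0.95, 0.90, 0.75)),
            n_wells=n_wells,
            ldh_effect_24h=0.01, ldh_effect_48h=0.20,
        ),
        ArmSpec(
            label="rotenone_10uM",
            rb=Trajectory((0.0, 0.25, 30.0), (rb0, 0.0, 0.0)),
            alpha=Trajectory((0.0, 2.0, 10.0, 30.0), (a0, 5.0, 3.0, 2.0)),
            cm=Trajectory((0.0, 5.0, 30.0), (cm0, 1.9, 2.2)),
            phi=Trajectory((0.0, 1.0, 2.5, 5.0, 30.0),
                           (1.0, 0.85, 0.88, 0.80, 0.60)),
            n_wells=n_wells,
            ldh_effect_24h=0.01, ldh_effect_48h=0.25,
        ),
    ]
    return arms


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean lognormal multiplier with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass(frozen=True)
class SimResult:
    """Simulated study: noisy measurements plus exact ground truth."""

    impedance: pd.DataFrame    # well, group, time_h, frequency_hz, z_real_ohm, z_imag_ohm
    ground_truth: pd.DataFrame  # well, group, time_h, rb, alpha, cm, phi
    reference: pd.DataFrame    # cell-free reference spectrum: frequency_hz, z_real_ohm, z_imag_ohm


def simulate_dataset(arms: list[ArmSpec] | None = None,
                     config: SimConfig | None = None) -> SimResult:
    """Simulate the full multi-well study.

    Per well: baseline (Rb, alpha, Cm) are jittered by a unit-mean lognormal
    factor with the arm's CV (zero segments stay exactly zero), trajectories
    are evaluated on the time grid, well impedance is computed at every
    frequency, and multiplicative Gaussian noise of sd ``noise_sd`` is
    applied independently to real and imaginary parts.  A noise-free
    cell-free reference spectrum for the same electrode accompanies the
    dataset.  Identical (arms, config) give byte-identical tables.
    """
    arms = arms if arms is not None else default_arms()
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    times = config.time_grid()
    freqs = config.grid.as_array()
    model = config.electrode

    imp_rows = []
    gt_rows = []
    widx = 0
    for arm in arms:
        jit = {k: _lognormal_factor(rng, arm.baseline_cv, arm.n_wells)
               for k in ("rb", "alpha", "cm")}
        for w in range(arm.n_wells):
            well = f"W{widx:03d}"
            widx += 1
            rb_t = arm.rb(times) * jit["rb"][w]
            a_t = arm.alpha(times) * jit["alpha"][w]
            cm_t = arm.cm(times) * jit["cm"][w]
            phi_t = np.clip(arm.phi(times), 0.0, 1.0)
            z = np.empty((times.size, freqs.size), dtype=complex)
            for i, t in enumerate(times):
                p = BarrierParams(rb=float(rb_t[i]), alpha=float(a_t[i]),
                                  cm=float(cm_t[i]))
                z[i] = well_impedance(model.with_coverage(float(phi_t[i])), p, freqs)
            if config.noise_sd:
                z = (z.real * (1.0 + config.noise_sd * rng.standard_normal(z.shape))
                     + 1j * z.imag * (1.0 + config.noise_sd * rng.standard_normal(z.shape)))
            imp_rows.append(pd.DataFrame({
                "well": well,
                "group": arm.label,
                "time_h": np.repeat(times, freqs.size),
                "frequency_hz": np.tile(freqs, times.size),
                "z_real_ohm": z.real.ravel(),
                "z_imag_ohm": z.imag.ravel(),
            }))
            gt_rows.append(pd.DataFrame({
                "well": well, "group": arm.label, "time_h": times,
                "rb": rb_t, "alpha": a_t, "cm": cm_t, "phi": phi_t,
            }))
    z_ref = naked_impedance(model, freqs) / model.electrode_area + model.series_resistance
    reference = pd.DataFrame({
        "frequency_hz": freqs,
        "z_real_ohm": z_ref.real,
        "z_imag_ohm": z_ref.imag,
    })
    return SimResult(impedance=pd.concat(imp_rows, ignore_index=True),
                     ground_truth=pd.concat(gt_rows, ignore_index=True),
                     reference=reference)


def simulate_ldh(arms: list[ArmSpec] | None = None,
                 config: SimConfig | None = None,
                 *, vehicle_mean: float = 0.25, noise_sd: float = 0.03,
                 background: float = 0.05,
                 background_sd: float = 0.005) -> pd.DataFrame:
    """Simulate the LDH plate at 24 h and 48 h.

    Corrected vehicle signal has mean ``vehicle_mean`` absorbance units;
    each arm adds its configured effect size at each timepoint.  Returns a
    tidy table (well, group, timepoint_h, a490, a680).
    """
    arms = arms if arms is not None else default_arms()
    config = config or SimConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x1d4]))
    rows = []
    for tp, attr in ((24.0, "ldh_effect_24h"), (48.0, "ldh_effect_48h")):
        widx = 0
        for arm in arms:
            effect = getattr(arm, attr)
            for w in range(arm.n_wells):
                a680 = max(0.0, rng.normal(background, background_sd))
                signal = max(0.0, rng.normal(vehicle_mean + effect, noise_sd))
                rows.append(dict(well=f"L{widx:03d}", group=arm.label,
                                 timepoint_h=tp, a490=a680 + signal, a680=a680))
                widx += 1
    return pd.DataFrame(rows)
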