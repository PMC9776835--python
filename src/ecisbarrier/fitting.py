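"""Inverse problem: recover (Rb, alpha, Cm) from multi-frequency spectra.

Each time point of each well is fitted independently.  The objective follows
classic barrier-function practice: the measured well spectrum and a cell-free
reference spectrum are both reduced to series-equivalent (R, C) per
frequency, and the fit minimises the squared log-ratios

    ln(R_meas/R_ref) - ln(R_model/R_naked)   and the same for C,

summed over the frequency grid, with the forward model evaluated at full
coverage (phi = 1; fitting assumes a confluent layer).  Working in log-ratio
space makes the objective dimensionless, weights the R and C residual
families equally, and cancels electrode-to-electrode gain.

When the fitted Rb falls below ``eps_rb`` the barrier term is
indistinguishable from zero and alpha/Cm lose identifiability; the fit is
then flagged ``rb_zero`` and alpha/Cm are reported as undefined rather than
as arbitrary numbers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy.optimize import least_squares

from .model import (
    BarrierParams,
    ComplexSpectrum,
    ElectrodeModel,
    NonCapacitiveError,
    membrane_impedance,
    naked_impedance,
    gk_covered_impedance,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "TerminationReason",
    "fit_barrier_params",
    "declare_rb_zero",
    "fit_timecourse",
]


class TerminationReason(str, Enum):
    OK = "ok"
    RB_ZERO = "rb_zero"
    NON_CAPACITIVE = "non_capacitive"
    NO_CONVERGENCE = "no_convergence"


@dataclass(frozen=True)
class FitOptions:
    """Options for the per-time-point fit.

    Bounds are in log10 space on (Rb / ohm cm^2, alpha / ohm^0.5 cm,
    Cm / uF cm^-2).  The multi-start set is a fixed 2x2x2 log grid so runs
    are reproducible without a seed.
    """

    eps_rb: float = 0.05
    log_bounds: tuple[tuple[float, float], ...] = (
        (-4.0, 3.0),   # Rb
        (-2.0, 2.0),   # alpha
        (-1.0, 1.3),   # Cm
    )
    start_grid: tuple[tuple[float, ...], ...] = (
        (1e-3, 5.0),   # Rb starts
        (4.0, 12.0),   # alpha starts
        (1.0, 2.5),    # Cm starts
    )
    xtol: float = 1e-12
    ftol: float = 1e-14
    gtol: float = 1e-12
    # warm-started fits fall back to the full multi-start set when their
    # residual exceeds this multiple of the previous time point's rss
    warm_rss_factor: float = 4.0

    def starts(self) -> list[np.ndarray]:
        return [np.log10(np.array(p)) for p in itertools.product(*self.start_grid)]


@dataclass(frozen=True)
class FitResult:
    """Outcome of one per-time-point fit."""

    params: BarrierParams | None
    rss: float
    n_freq_used: int
    converged: bool
    termination_reason: TerminationReason

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be >= 0")
        if not self.converged and self.params is not None and self.params.alpha_cm_defined:
            raise ValueError("non-converged fits must not carry defined alpha/cm")
        if self.termination_reason is TerminationReason.RB_ZERO:
            if self.params is None or self.params.rb != 0 or self.params.alpha_cm_defined:
                raise ValueError("rb_zero results must have Rb = 0 and alpha/cm undefined")


def _log_rc(spectrum: ComplexSpectrum) -> np.ndarray:
    r, c = spectrum.series_rc_arrays()
    return np.concatenate([np.log(r), np.log(c)])


def _predicted_log_rc(model: ElectrodeModel, rb: float, alpha: float, cm: float,
                      f: np.ndarray) -> np.ndarray:
    """log series R and C of the covered well (phi = 1) on grid ``f``."""
    zn = naked_impedance(model, f)
    zm = membrane_impedance(cm, f)
    params = BarrierParams(rb=rb, alpha=alpha, cm=cm)
    z_spec = gk_covered_impedance(zn, zm, params)
    zw = z_spec / model.electrode_area + model.series_resistance
    r = zw.real
    c = -1.0 / (2.0 * np.pi * f * zw.imag)
    if np.any(zw.imag >= 0) or np.any(r <= 0):
        raise NonCapacitiveError("model prediction left the capacitive regime")
    return np.concatenate([np.log(r), np.log(c)])


def _naked_log_rc(model: ElectrodeModel, f: np.ndarray) -> np.ndarray:
    zn = naked_impedance(model, f) / model.electrode_area + model.series_resistance
    r = zn.real
    c = -1.0 / (2.0 * np.pi * f * zn.imag)
    return np.concatenate([np.log(r), np.log(c)])


def fit_barrier_params(measured: ComplexSpectrum, reference: ComplexSpectrum,
                       model: ElectrodeModel, opts: FitOptions | None = None,
                       *, warm_start: BarrierParams | None = None) -> FitResult:
    """Fit (Rb, alpha, Cm) to one measured spectrum.

    ``measured`` and ``reference`` (cell-free well) must share a grid of at
    least three frequencies.  Returns the best local solution over the fixed
    multi-start set (or a warm start when supplied), with the Rb = 0
    identifiability rule already applied.
    """
    opts = opts or FitOptions()
    if measured.grid != reference.grid:
        raise ValueError("measured and reference spectra must share a frequency grid")
    f = measured.grid.as_array()
    if f.size < 3:
        raise ValueError("need at least 3 frequencies to fit 3 parameters")
    try:
        target = _log_rc(measured) - _log_rc(reference)
    except NonCapacitiveError:
        return FitResult(params=None, rss=np.inf, n_freq_used=int(f.size),
                         converged=False,
                         termination_reason=TerminationReason.NON_CAPACITIVE)
    naked_pred = _naked_log_rc(model, f)

    lb = np.array([b[0] for b in opts.log_bounds])
    ub = np.array([b[1] for b in opts.log_bounds])

    def residuals(u: np.ndarray) -> np.ndarray:
        rb, alpha, cm = 10.0 ** u
        try:
            pred = _predicted_log_rc(model, rb, alpha, cm, f) - naked_pred
        except NonCapacitiveError:
            return np.full(2 * f.size, 1e3)
        return pred - target

    def run(x0: np.ndarray):
        return least_squares(residuals, np.clip(x0, lb, ub), bounds=(lb, ub),
                             method="trf", xtol=opts.xtol, ftol=opts.ftol,
                             gtol=opts.gtol)

    attempts = []
    if warm_start is not None and warm_start.cm > 0:
        w = np.log10([max(warm_start.rb, 10.0 ** lb[0]),
                      max(warm_start.alpha, 10.0 ** lb[1]),
                      warm_start.cm])
        attempts.append(run(w))
    if not attempts or not attempts[0].success:
        attempts.extend(run(x0) for x0 in opts.starts())
    best = min(attempts, key=lambda r: r.cost)
    if not best.success:
        return FitResult(params=None, rss=float(2 * best.cost),
                         n_freq_used=int(f.size), converged=False,
                         termination_reason=TerminationReason.NO_CONVERGENCE)
    rb, alpha, cm = 10.0 ** best.x
    result = FitResult(
        params=BarrierParams(rb=rb, alpha=alpha, cm=cm),
        rss=float(2 * best.cost),
        n_freq_used=int(f.size),
        converged=True,
        termination_reason=TerminationReason.OK,
    )
    return declare_rb_zero(result, opts.eps_rb)


def declare_rb_zero(result: FitResult, eps_rb: float = 0.05) -> FitResult:
    """Apply the Rb = 0 identifiability rule.

    A fitted Rb below ``eps_rb`` (ohm cm^2) is indistinguishable from an
    absent paracellular barrier; the result is rewritten with Rb = 0 and
    alpha/Cm marked undefined (their numeric values are retained for warm
    starts but must not be reported).  With ``eps_rb = 0`` only exact
    boundary solutions are flagged.
    """
    if result.params is None or not result.converged:
        return result
    rb = result.params.rb
    flagged = rb < eps_rb or (eps_rb == 0 and rb == 0)
    if not flagged:
        return result
    params = BarrierParams(rb=0.0, alpha=result.params.alpha, cm=result.params.cm,
                           rb_is_zero=True, alpha_cm_defined=False)
    return replace(result, params=params, termination_reason=TerminationReason.RB_ZERO)


def fit_timecourse(times: np.ndarray, spectra: list[ComplexSpectrum],
                   reference: ComplexSpectrum, model: ElectrodeModel,
                   opts: FitOptions | None = None) -> list[FitResult]:
    """Fit every time point of one well independently.

    ``spectra[i]`` is the measured spectrum at ``times[i]`` (hours,
    ascending).  Each point is warm-started from the previous point's
    parameters with an automatic fall-back to the full multi-start set when
    the warm fit converges poorly.  Failed points are flagged in their
    FitResult; the series never aborts.
    """
    opts = opts or FitOptions()
    times = np.asarray(times, dtype=float)
    if times.size != len(spectra):
        raise ValueError("times and spectra must have equal length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time points must be strictly ascending")
    results: list[FitResult] = []
    prev: FitResult | None = None
    for spec in spectra:
        warm = prev.params if (prev is not None and prev.converged) else None
        res = fit_barrier_params(spec, reference, model, opts, warm_start=warm)
        if (warm is not None and res.converged and prev is not None
                and np.isfinite(prev.rss)
                and res.rss > opts.warm_rss_factor * prev.rss + 1e-9):
            # warm basin looks poor relative to the neighbouring point:
            # redo from the full start set and keep the better solution
            cold = fit_barrier_params(spec, reference, model, opts)
            if cold.converged and cold.rss < res.rss:
                res = cold
        results.append(res)
        prev = res
    return results
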