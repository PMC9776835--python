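"""Curve analytics: normalization, AUC, endpoints, zero-crossing, termination.

Every analysed quantity (Z, R, C, Rb, alpha, Cm) is a scalar time course per
well.  Treatment is applied at t = 0 and all normalization is to the value
at the reference time (t = 0 by convention), following the Zt/Z0 convention
of barrier-function assays.  Curves may carry invalid points: alpha and Cm
are undefined wherever the fitted Rb is zero, so those curves terminate
early and all analytics respect the valid mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TimeCourse",
    "NormalizedCurve",
    "AucResult",
    "ZeroReferenceError",
    "normalize",
    "auc",
    "endpoint",
    "first_zero_time",
    "terminate_dependent_curves",
    "detect_confluence",
    "analysis_frequency",
    "surface_matrix",
    "DEFAULT_ANALYSIS_FREQUENCIES",
]

#: Optimum analysis frequencies: the total resistance peaks near 4 kHz and
#: the capacitance/spreading signal saturates at the top of the grid (64 kHz).
DEFAULT_ANALYSIS_FREQUENCIES = {"resistance": 4000.0, "capacitance": 64000.0}


class ZeroReferenceError(ValueError):
    """Raised when a curve cannot be normalized because its reference is zero."""


@dataclass(frozen=True)
class TimeCourse:
    """Scalar quantity versus time for one well.

    ``mask`` marks valid points; undefined points (e.g. alpha after barrier
    loss) are carried as masked, never as zeros.
    """

    times: np.ndarray
    values: np.ndarray
    well: str = ""
    quantity: str = ""
    unit: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be matching 1-D arrays")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly ascending")
        m = (np.ones(t.shape, dtype=bool) if self.mask is None
             else np.asarray(self.mask, dtype=bool))
        if m.shape != t.shape:
            raise ValueError("mask length must equal values length")
        m = m & np.isfinite(v)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "mask", m)

    @property
    def valid_times(self) -> np.ndarray:
        return self.times[self.mask]

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass(frozen=True)
class NormalizedCurve(TimeCourse):
    """A TimeCourse divided by its value at the reference time."""

    t_ref: float = 0.0
    ref_value: float = 1.0


@dataclass(frozen=True)
class AucResult:
    """Trapezoidal area plus the span actually integrated."""

    area: float
    t_start: float
    t_end: float


def normalize(curve: TimeCourse, t_ref: float = 0.0) -> NormalizedCurve:
    """Divide a curve by its value at ``t_ref`` (the treatment instant).

    The reference time must be a sampled, valid point with nonzero value;
    a curve already at zero at the reference cannot be normalized and the
    raw curve should be reported instead.
    """
    idx = np.flatnonzero(np.isclose(curve.times, t_ref))
    if idx.size == 0:
        raise ValueError(f"reference time {t_ref} h is not a sample point")
    i = int(idx[0])
    if not curve.mask[i] or curve.values[i] == 0:
        raise ZeroReferenceError(
            f"cannot normalize {curve.quantity or 'curve'} of well "
            f"{curve.well or '?'}: reference value at t={t_ref} h is zero/undefined"
        )
    ref = float(curve.values[i])
    return NormalizedCurve(
        times=curve.times, values=curve.values / ref, well=curve.well,
        quantity=f"normalized {curve.quantity}".strip(), unit="fold",
        mask=curve.mask, t_ref=float(t_ref), ref_value=ref,
    )


def auc(curve: TimeCourse, t_start: float, t_end: float) -> AucResult:
    """Trapezoidal area under the curve over [t_start, t_end].

    Early-terminated curves are integrated only over their valid span; the
    realized span is returned with the area.  Window edges inside the valid
    span are included by linear interpolation.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    t, v = curve.valid_times, curve.valid_values
    if t.size == 0:
        raise ValueError("curve has no valid points")
    lo = max(t_start, float(t[0]))
    hi = min(t_end, float(t[-1]))
    if hi <= lo:
        raise ValueError(
            f"window [{t_start}, {t_end}] h does not overlap the valid span "
            f"[{t[0]}, {t[-1]}] h"
        )
    inside = (t > lo) & (t < hi)
    tt = np.concatenate([[lo], t[inside], [hi]])
    vv = np.concatenate([[np.interp(lo, t, v)], v[inside], [np.interp(hi, t, v)]])
    return AucResult(area=float(np.trapezoid(vv, tt)), t_start=lo, t_end=hi)


def endpoint(curve: TimeCourse, t: float) -> float:
    """Value at time ``t``: exact sample if on the grid, else linear interp.

    Times outside the valid span (including after early termination) are an
    error, never an extrapolation.
    """
    tt, vv = curve.valid_times, curve.valid_values
    if tt.size == 0 or t < tt[0] or t > tt[-1]:
        raise ValueError(
            f"t={t} h is outside the valid span of {curve.quantity or 'curve'}"
            f" ({'empty' if tt.size == 0 else f'[{tt[0]}, {tt[-1]}] h'})"
        )
    exact = np.flatnonzero(np.isclose(tt, t))
    if exact.size:
        return float(vv[int(exact[0])])
    return float(np.interp(t, tt, vv))


def first_zero_time(rb_curve: TimeCourse, eps: float = 0.05,
                    rebound_factor: float = 5.0) -> float | None:
    """Earliest sustained return of an Rb curve to zero.

    Returns the earliest time t > 0 at which ``Rb(t) <= eps`` with no later
    *rebound*, or None if the barrier never collapses.  ``eps`` is in the
    units of the curve (raw ohm cm^2, or fold for a normalized curve).

    "Sustained" is operationalized with a hysteresis threshold: an
    excursion after the candidate time counts as a rebound only if it
    reaches ``rebound_factor * eps``; smaller exceedances are treated as
    estimation jitter (per-time-point fitted Rb has an irreducible noise
    floor once the true barrier is gone, so a strict never-again-above-eps
    scan would be dominated by isolated noise spikes).  With
    ``rebound_factor = 1`` this is the strict scan; on clean curves the two
    agree.
    """
    t, v = rb_curve.valid_times, rb_curve.valid_values
    post = t > 0
    t, v = t[post], v[post]
    if t.size == 0:
        return None
    at_zero = v <= eps
    if not at_zero.any():
        return None
    rebound = v >= rebound_factor * eps
    if rebound.any():
        last_rebound = int(np.flatnonzero(rebound)[-1])
        later = np.flatnonzero(at_zero & (np.arange(t.size) > last_rebound))
        return float(t[later[0]]) if later.size else None
    return float(t[int(np.flatnonzero(at_zero)[0])])


def terminate_dependent_curves(alpha_curve: TimeCourse, cm_curve: TimeCourse,
                               rb_zero_time: float | None
                               ) -> tuple[TimeCourse, TimeCourse]:
    """Mask alpha and Cm invalid for all t >= the Rb-zero time.

    The covered-electrode model cannot constrain alpha or Cm once the
    paracellular barrier term vanishes, so their curves terminate at the
    sustained Rb-zero time.
    """
    if rb_zero_time is None:
        return alpha_curve, cm_curve
    out = []
    for c in (alpha_curve, cm_curve):
        keep = c.times < rb_zero_time
        out.append(replace(c, mask=c.mask & keep))
    return out[0], out[1]


def detect_confluence(c_curve: TimeCourse, threshold_nf: float = 20.0,
                      dwell_h: float = 2.0) -> float | None:
    """Detect monolayer confluence from the raw 64 kHz capacitance (nF).

    Confluence is declared at the earliest time by which the capacitance has
    stayed below ``threshold_nf`` continuously for at least ``dwell_h``
    hours; returns None if that never happens.
    """
    t, v = c_curve.valid_times, c_curve.valid_values
    below = v < threshold_nf
    start = None
    for i in range(t.size):
        if below[i]:
            if start is None:
                start = t[i]
            if t[i] - start >= dwell_h:
                return float(start + dwell_h)
        else:
            start = None
    return None


def analysis_frequency(quantity: str,
                       overrides: dict[str, float] | None = None) -> float:
    """Frequency (Hz) at which a quantity is extracted from the spectrum.

    Defaults: 4000 Hz for the total resistance (near its maximum) and
    64,000 Hz for the capacitance (cell-spreading proxy); both overridable
    through configuration.
    """
    table = dict(DEFAULT_ANALYSIS_FREQUENCIES)
    if overrides:
        table.update(overrides)
    if quantity not in table:
        raise ValueError(f"unknown quantity {quantity!r}; expected one of {sorted(table)}")
    return float(table[quantity])


def surface_matrix(times: np.ndarray, frequencies: np.ndarray,
                   z_abs: np.ndarray) -> "pandas.DataFrame":
    """Normalized |Z| surface over (frequency x time), ready for plotting.

    ``z_abs`` has shape (n_freq, n_times); every row is divided by its value
    at t = 0.  Returned as a DataFrame indexed by frequency (Hz) with time
    (h) columns; take log10 of the index for the conventional display axis.
    """
    import pandas as pd

    z = np.asarray(z_abs, dtype=float)
    times = np.asarray(times, dtype=float)
    frequencies = np.asarray(frequencies, dtype=float)
    if z.shape != (frequencies.size, times.size):
        raise ValueError("z_abs must have shape (n_freq, n_times)")
    i0 = int(np.flatnonzero(np.isclose(times, 0.0))[0])
    ref = z[:, i0][:, None]
    if np.any(ref == 0):
        raise ZeroReferenceError("zero |Z| at the reference time")
    return pd.DataFrame(z / ref, index=frequencies, columns=times)
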