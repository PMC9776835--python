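"""High-level study pipeline: decompose, fit, analyse, compare.

These functions chain the package's layers over the tidy tables defined in
:mod:`ecisbarrier.io`: series-RC decomposition of every reading, per-well
Giaever-Keese fits, normalized-curve analytics (AUC windows, endpoints,
barrier-collapse times, curve termination) and group statistics.  They are
what the command-line interface and the reproduction script call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitting import FitOptions, fit_timecourse
from .groupstats import ComparisonResult, GroupSummary, compare_groups
from .model import ComplexSpectrum, ElectrodeModel, FrequencyGrid
from .timecourse import (
    NormalizedCurve,
    TimeCourse,
    auc,
    first_zero_time,
    normalize,
    terminate_dependent_curves,
)

__all__ = [
    "decompose",
    "well_curve",
    "normalized_well_curves",
    "arm_mean_curve",
    "fit_study",
    "rb_zero_times",
    "fits_to_curves",
    "plateau_level",
    "crossing_time",
    "summarize_auc",
    "compare_summary",
    "surface_matrix_from_impedance",
    "DEFAULT_WINDOWS",
]

#: AUC reporting windows (h): the short FCCP window, the oligomycin
#: high-dose termination window and the full record.
DEFAULT_WINDOWS = ((0.0, 2.5), (0.0, 3.6), (0.0, 30.0))


def decompose(impedance: pd.DataFrame) -> pd.DataFrame:
    """Series-RC decomposition of every reading in a long impedance table.

    Adds ``r_ohm`` and ``c_nf`` columns.  Non-capacitive rows (Im Z >= 0)
    get NaN in both, so downstream curves carry them as invalid points.
    """
    im = impedance["z_imag_ohm"].to_numpy()
    f = impedance["frequency_hz"].to_numpy()
    capacitive = im < 0
    r = np.where(capacitive, impedance["z_real_ohm"].to_numpy(), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(capacitive, -1.0 / (2.0 * np.pi * f * im), np.nan)
    out = impedance.copy()
    out["r_ohm"] = r
    out["c_nf"] = c * 1e9
    return out


def well_curve(decomposed: pd.DataFrame, well: str, quantity: str,
               frequency_hz: float) -> TimeCourse:
    """Extract one well's R (ohm) or C (nF) time course at one frequency."""
    col = {"resistance": "r_ohm", "capacitance": "c_nf"}[quantity]
    sub = decomposed[(decomposed["well"] == well)
                     & (decomposed["frequency_hz"] == frequency_hz)]
    if sub.empty:
        raise ValueError(f"no rows for well {well!r} at {frequency_hz:g} Hz")
    sub = sub.sort_values("time_h")
    unit = "ohm" if quantity == "resistance" else "nF"
    return TimeCourse(times=sub["time_h"].to_numpy(),
                      values=sub[col].to_numpy(),
                      well=well, quantity=quantity, unit=unit)


def normalized_well_curves(decomposed: pd.DataFrame, quantity: str,
                           frequency_hz: float,
                           groups: list[str] | None = None
                           ) -> dict[str, NormalizedCurve]:
    """Normalized (t=0 reference) curves for every well, keyed by well id."""
    sub = decomposed
    if groups is not None:
        sub = sub[sub["group"].isin(groups)]
    return {w: normalize(well_curve(sub, w, quantity, frequency_hz))
            for w in sub["well"].unique()}


def arm_mean_curve(curves: dict[str, NormalizedCurve],
                   membership: dict[str, str], group: str) -> TimeCourse:
    """Pointwise mean over the wells of one arm (mask-aware)."""
    wells = [w for w, g in membership.items() if g == group and w in curves]
    if not wells:
        raise ValueError(f"no wells for group {group!r}")
    times = curves[wells[0]].times
    stack = np.full((len(wells), times.size), np.nan)
    for i, w in enumerate(wells):
        c = curves[w]
        if not np.array_equal(c.times, times):
            raise ValueError("wells must share a time grid")
        stack[i, c.mask] = c.values[c.mask]
    mean = np.nanmean(stack, axis=0)
    return TimeCourse(times=times, values=mean, well=f"mean({group})",
                      quantity=next(iter(curves.values())).quantity, unit="fold",
                      mask=~np.isnan(mean))


def fit_study(impedance: pd.DataFrame, reference: pd.DataFrame,
              model: ElectrodeModel, opts: FitOptions | None = None,
              groups: list[str] | None = None) -> pd.DataFrame:
    """Per-well, per-time-point barrier fits over (part of) a study.

    Returns the tidy fits table (well, group, time_h, rb_ohm_cm2,
    alpha_ohm05_cm, cm_uf_cm2, rss, flag).  alpha/Cm are NaN wherever the
    fit declared Rb = 0 or failed; the sustained-termination audit is
    applied afterwards by :func:`fits_to_curves`.
    """
    opts = opts or FitOptions()
    freqs = np.sort(reference["frequency_hz"].unique())
    grid = FrequencyGrid(tuple(freqs))
    ref_sorted = reference.sort_values("frequency_hz")
    ref_spec = ComplexSpectrum(grid, (ref_sorted["z_real_ohm"]
                                      + 1j * ref_sorted["z_imag_ohm"]).to_numpy())
    sub = impedance if groups is None else impedance[impedance["group"].isin(groups)]
    rows = []
    for (well, group), wdf in sub.groupby(["well", "group"], sort=False):
        wdf = wdf.sort_values(["time_h", "frequency_hz"])
        times = wdf["time_h"].unique()
        z = (wdf["z_real_ohm"] + 1j * wdf["z_imag_ohm"]).to_numpy().reshape(
            times.size, freqs.size)
        spectra = [ComplexSpectrum(grid, z[i]) for i in range(times.size)]
        results = fit_timecourse(times, spectra, ref_spec, model, opts)
        for t, res in zip(times, results):
            p = res.params
            defined = (p is not None and p.alpha_cm_defined and res.converged)
            rows.append(dict(
                well=well, group=group, time_h=float(t),
                rb_ohm_cm2=(p.rb if p is not None and res.converged else np.nan),
                alpha_ohm05_cm=(p.alpha if defined else np.nan),
                cm_uf_cm2=(p.cm if defined else np.nan),
                rss=res.rss if np.isfinite(res.rss) else np.nan,
                flag=res.termination_reason.value,
            ))
    return pd.DataFrame(rows)


def fits_to_curves(fits: pd.DataFrame, well: str, eps: float = 0.05
                   ) -> dict[str, TimeCourse]:
    """One well's fitted-parameter curves with the termination audit applied.

    Returns raw ``rb`` plus ``alpha``/``cm`` masked from the sustained
    Rb-zero time on, and ``rb_norm`` (Rb normalized to its t = 0 value) when
    the baseline admits normalization.  ``eps`` is applied on the normalized
    curve when available, else on raw Rb.
    """
    sub = fits[fits["well"] == well].sort_values("time_h")
    if sub.empty:
        raise ValueError(f"no fits for well {well!r}")
    t = sub["time_h"].to_numpy()
    rb = TimeCourse(times=t, values=sub["rb_ohm_cm2"].to_numpy(),
                    well=well, quantity="Rb", unit="ohm cm^2")
    alpha = TimeCourse(times=t, values=sub["alpha_ohm05_cm"].to_numpy(),
                       well=well, quantity="alpha", unit="ohm^0.5 cm")
    cm = TimeCourse(times=t, values=sub["cm_uf_cm2"].to_numpy(),
                    well=well, quantity="Cm", unit="uF/cm^2")
    out: dict[str, TimeCourse] = {"rb": rb}
    try:
        rb_norm = normalize(rb)
        out["rb_norm"] = rb_norm
        zero_t = first_zero_time(rb_norm, eps)
    except Exception:
        zero_t = first_zero_time(rb, eps)
    out["rb_zero_time"] = zero_t  # type: ignore[assignment]
    alpha, cm = terminate_dependent_curves(alpha, cm, zero_t)
    out["alpha"] = alpha
    out["cm"] = cm
    return out


def rb_zero_times(fits: pd.DataFrame, eps: float = 0.05) -> pd.DataFrame:
    """Sustained Rb-zero time per well (NaN when the barrier never collapses)."""
    rows = []
    for well, sub in fits.groupby("well", sort=False):
        curves = fits_to_curves(fits, well, eps)
        zt = curves["rb_zero_time"]
        rows.append(dict(well=well, group=sub["group"].iloc[0],
                         rb_zero_time_h=(np.nan if zt is None else float(zt))))
    return pd.DataFrame(rows)


def plateau_level(curve: TimeCourse, span_h: float = 5.0) -> float:
    """Mean value over the final ``span_h`` hours of the valid record."""
    t, v = curve.valid_times, curve.valid_values
    if t.size == 0:
        raise ValueError("empty curve")
    sel = t >= t[-1] - span_h
    return float(np.mean(v[sel]))


def crossing_time(curve: TimeCourse, level: float) -> float | None:
    """Earliest time the curve reaches ``level`` (linear interpolation)."""
    t, v = curve.valid_times, curve.valid_values
    at_or_above = v >= level
    if not at_or_above.any():
        return None
    i = int(np.argmax(at_or_above))
    if i == 0:
        return float(t[0])
    t0, t1, v0, v1 = t[i - 1], t[i], v[i - 1], v[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (level - v0) * (t1 - t0) / (v1 - v0))


def summarize_auc(curves: dict[str, NormalizedCurve], membership: dict[str, str],
                  windows=DEFAULT_WINDOWS) -> pd.DataFrame:
    """Per-well AUC over each reporting window plus the realized span."""
    rows = []
    for w, c in curves.items():
        for lo, hi in windows:
            try:
                res = auc(c, lo, hi)
            except ValueError:
                continue
            rows.append(dict(well=w, group=membership[w], window=f"{lo:g}-{hi:g}h",
                             auc=res.area, span_start_h=res.t_start,
                             span_end_h=res.t_end))
    return pd.DataFrame(rows)


def compare_summary(summary: pd.DataFrame, value_col: str,
                    posthoc: str = "tukey") -> ComparisonResult:
    """ANOVA + post hoc over a per-well summary table with a group column."""
    groups = [GroupSummary(g, sub[value_col].to_numpy())
              for g, sub in summary.groupby("group", sort=False)]
    return compare_groups(groups, posthoc=posthoc)


def surface_matrix_from_impedance(impedance: pd.DataFrame,
                                  group: str) -> pd.DataFrame:
    """Arm-mean normalized |Z| surface over (frequency x time).

    Every well's |Z| is normalized per frequency to its t = 0 value, then
    averaged over the arm's wells.  Matches the 1-D normalized curves when a
    single frequency row is extracted.
    """
    sub = impedance[impedance["group"] == group].copy()
    if sub.empty:
        raise ValueError(f"no rows for group {group!r}")
    sub["z_abs"] = np.hypot(sub["z_real_ohm"], sub["z_imag_ohm"])
    ref = (sub[sub["time_h"] == 0.0]
           .set_index(["well", "frequency_hz"])["z_abs"])
    sub["norm"] = sub["z_abs"] / ref.loc[
        pd.MultiIndex.from_frame(sub[["well", "frequency_hz"]])].to_numpy()
    mat = sub.pivot_table(index="frequency_hz", columns="time_h", values="norm",
                          aggfunc="mean")
    return mat
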