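"""Forward models of cell-free and cell-covered microelectrode impedance.

The measurement this package analyses is the complex impedance ``Z(f, t)`` of
an endothelial monolayer grown on a gold microelectrode.  Three building
blocks describe the measured well:

* a **cell-free (naked) electrode**, modelled as a constant-phase element
  (CPE), ``Zn = A (j omega)^-beta`` in specific units (ohm cm^2);
* a **cell membrane**, modelled as a pure capacitor ``Cm`` (uF/cm^2); apical
  and basal membranes act in series, hence the factor 2 in ``Zm``;
* the **Giaever-Keese covered-electrode model**, which couples the naked
  electrode, the membrane, the cell-cell (paracellular) resistance ``Rb``
  (ohm cm^2) and the cell-substrate constraint parameter ``alpha``
  (ohm^1/2 cm) into the specific impedance ``Zc`` of a confluent layer.

A measured well mixes covered and naked electrode area in parallel
(coverage fraction ``phi``), is scaled by the electrode area, and carries a
series solution/lead resistance.  The series-equivalent (R, C) reading the
instrument reports is recovered by :func:`series_rc`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import special

__all__ = [
    "FrequencyGrid",
    "ElectrodeModel",
    "BarrierParams",
    "ComplexSpectrum",
    "RCReading",
    "NonCapacitiveError",
    "naked_impedance",
    "membrane_impedance",
    "bessel_ratio",
    "gk_covered_impedance",
    "well_impedance",
    "series_rc",
]


class NonCapacitiveError(ValueError):
    """Raised when a reading has non-negative reactance and no series C exists.

    Carries the (well, time, frequency) context when available so a failing
    point in a long recording can be located.
    """

    def __init__(self, message: str, well: str | None = None,
                 time_h: float | None = None, frequency_hz: float | None = None):
        super().__init__(message)
        self.well = well
        self.time_h = time_h
        self.frequency_hz = frequency_hz


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly ascending, strictly positive AC frequency grid in Hz."""

    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D sequence")
        if not np.all(f > 0):
            raise ValueError("all frequencies must be strictly positive")
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly ascending")
        object.__setattr__(self, "frequencies", tuple(float(x) for x in f))

    @classmethod
    def default(cls) -> "FrequencyGrid":
        """Nine-frequency octave grid 250 * 2^k Hz, k = 0..8 (250-64,000 Hz)."""
        return cls(tuple(250.0 * 2 ** k for k in range(9)))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.frequencies, dtype=float)

    def __len__(self) -> int:
        return len(self.frequencies)

    def __iter__(self):
        return iter(self.frequencies)


@dataclass(frozen=True)
class ElectrodeModel:
    """Parametric description of the cell-free electrode and the well.

    Parameters
    ----------
    cpe_magnitude:
        Specific CPE coefficient ``A`` in ohm cm^2 s^-beta; the naked
        electrode impedance is ``A (j omega)^-beta``.
    cpe_exponent:
        CPE exponent ``beta`` in (0, 1]; 1 reduces to an ideal capacitor.
    series_resistance:
        Well-level solution plus lead resistance in ohm.
    electrode_area:
        Active electrode area in cm^2.
    coverage_fraction:
        Fraction ``phi`` of the electrode area occluded by cells, in [0, 1].

    Defaults are calibrated so that a confluent vehicle well reads ~1-2 kohm
    at 4000 Hz and a naked well reads ~40 nF at 64 kHz (so the 20 nF
    confluence criterion separates naked from covered electrodes).  The area
    default is a documented convention, not an instrument datum.
    """

    cpe_magnitude: float = 5.0e4
    cpe_exponent: float = 0.95
    series_resistance: float = 300.0
    electrode_area: float = 3.9e-3
    coverage_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.cpe_exponent <= 1.0):
            raise ValueError("cpe_exponent must lie in (0, 1]")
        if self.cpe_magnitude <= 0:
            raise ValueError("cpe_magnitude must be positive")
        if self.electrode_area <= 0:
            raise ValueError("electrode_area must be positive")
        if self.series_resistance < 0:
            raise ValueError("series_resistance must be non-negative")
        if not (0.0 <= self.coverage_fraction <= 1.0):
            raise ValueError("coverage_fraction must lie in [0, 1]")

    def with_coverage(self, phi: float) -> "ElectrodeModel":
        return replace(self, coverage_fraction=phi)


@dataclass(frozen=True)
class BarrierParams:
    """Giaever-Keese barrier state of one well at one time point.

    ``rb`` is the paracellular resistance (ohm cm^2), ``alpha`` the
    cell-substrate constraint parameter (ohm^1/2 cm) and ``cm`` the membrane
    capacitance (uF/cm^2).  When the fitted ``rb`` is zero the model loses
    identifiability for ``alpha`` and ``cm``; ``rb_is_zero`` marks that state
    and forces ``alpha_cm_defined`` to False.
    """

    rb: float
    alpha: float
    cm: float
    rb_is_zero: bool = False
    alpha_cm_defined: bool = True

    def __post_init__(self) -> None:
        if self.rb < 0:
            raise ValueError("rb must be >= 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.alpha_cm_defined and not self.cm > 0:
            raise ValueError("cm must be > 0 when defined")
        if self.rb_is_zero and self.alpha_cm_defined:
            raise ValueError("rb_is_zero implies alpha/cm undefined")


@dataclass(frozen=True)
class RCReading:
    """Series-equivalent resistance (ohm) and capacitance (F) of a reading."""

    resistance: float
    capacitance: float

    def __post_init__(self) -> None:
        if self.resistance < 0:
            raise ValueError("series resistance must be >= 0")
        if not self.capacitance > 0:
            raise ValueError("series capacitance must be > 0")

    @property
    def capacitance_nf(self) -> float:
        return self.capacitance * 1e9


@dataclass(frozen=True)
class ComplexSpectrum:
    """Complex impedance on a frequency grid, at well or specific level."""

    grid: FrequencyGrid
    z: np.ndarray
    level: str = "well"  # "well" (ohm) or "specific" (ohm cm^2)

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=complex)
        if z.shape != (len(self.grid),):
            raise ValueError("impedance vector must match the frequency grid")
        if self.level not in ("well", "specific"):
            raise ValueError("level must be 'well' or 'specific'")
        object.__setattr__(self, "z", z)

    def series_rc_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized series-RC decomposition over the whole grid."""
        f = self.grid.as_array()
        im = self.z.imag
        if np.any(im >= 0):
            bad = f[im >= 0][0]
            raise NonCapacitiveError(
                f"non-capacitive reading at {bad:g} Hz", frequency_hz=float(bad)
            )
        r = self.z.real
        c = -1.0 / (2.0 * np.pi * f * im)
        return r, c


def naked_impedance(model: ElectrodeModel, f) -> complex | np.ndarray:
    """Specific impedance of the cell-free electrode, ``A (j omega)^-beta``.

    Accepts a scalar frequency or an array; returns ohm cm^2 with negative
    imaginary part (principal branch of the complex power).
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be strictly positive")
    omega = 2.0 * np.pi * f
    zn = np.asarray(model.cpe_magnitude * (1j * omega) ** (-model.cpe_exponent))
    return zn if zn.ndim else complex(zn)


def membrane_impedance(cm: float, f) -> complex | np.ndarray:
    """Specific transcellular impedance of two membranes in series.

    ``cm`` is the single-membrane capacitance in uF/cm^2; apical and basal
    membranes in series give ``Zm = 2 / (j omega Cm)``, purely imaginary.
    """
    if not cm > 0:
        raise ValueError("cm must be strictly positive")
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be strictly positive")
    omega = 2.0 * np.pi * f
    zm = np.asarray(2.0 / (1j * omega * cm * 1e-6))
    return zm if zm.ndim else complex(zm)


# Below this |z| the scaled-Bessel quotient is replaced by its Taylor series;
# the truncation error ~|z|^4/192 is < 1e-13 at the threshold.
_BESSEL_SERIES_CUTOFF = 1e-3


def bessel_ratio(z) -> complex | np.ndarray:
    """Evaluate ``(z/2) I0(z) / I1(z)`` for complex ``z``.

    This is the quotient through which the modified Bessel functions of the
    first kind enter the covered-electrode model.  Exponentially scaled
    Bessel functions are used so the quotient stays finite for large |z|;
    the removable singularity at the origin is handled by the series limit
    ``1 + z^2/8 + O(z^4)``.
    """
    z = np.asarray(z, dtype=complex)
    out = np.empty_like(z)
    small = np.abs(z) < _BESSEL_SERIES_CUTOFF
    zs = z[small]
    out[small] = 1.0 + zs * zs / 8.0
    zl = z[~small]
    if zl.size:
        i0 = special.ive(0, zl)
        i1 = special.ive(1, zl)
        if np.any(i1 == 0):
            raise FloatingPointError(
                f"I1 vanished off the origin at z={zl[i1 == 0][0]!r}"
            )
        out[~small] = 0.5 * zl * i0 / i1
    return out if out.ndim else complex(out)


def gk_covered_impedance(zn, zm, params: BarrierParams) -> complex | np.ndarray:
    """Specific impedance of the cell-covered electrode (Giaever-Keese).

    Couples the naked-electrode impedance ``zn``, the transcellular membrane
    impedance ``zm``, the paracellular resistance ``Rb`` and the
    cell-substrate parameter ``alpha``:

        1/Zc = (1/Zn) [ Zn/(Zn+Zm)
                        + (Zm/(Zn+Zm)) / ( (g/2) I0(g)/I1(g) + Rb (1/Zn + 1/Zm) ) ]

    with ``g = alpha sqrt(1/Zn + 1/Zm)`` on the principal branch.  At
    ``Rb = alpha = 0`` the cell layer is electrically invisible and
    ``Zc == Zn`` exactly.
    """
    zn = np.asarray(zn, dtype=complex)
    zm = np.asarray(zm, dtype=complex)
    inv_sum = 1.0 / zn + 1.0 / zm
    gamma = params.alpha * np.sqrt(inv_sum)
    denom = bessel_ratio(gamma) + params.rb * inv_sum
    bracket = zn / (zn + zm) + (zm / (zn + zm)) / denom
    zc = np.asarray(zn / bracket)
    return zc if zc.ndim else complex(zc)


def well_impedance(model: ElectrodeModel, params: BarrierParams, f) -> complex | np.ndarray:
    """Measured well-level impedance in ohm.

    Parallel mixing of covered and naked electrode area with coverage
    fraction ``phi``, scaled by electrode area, plus the series resistance:

        Z_well = [ phi/Zc + (1-phi)/Zn ]^-1 / area + Rs
    """
    phi = model.coverage_fraction
    zn = naked_impedance(model, f)
    zm = membrane_impedance(params.cm, f)
    zc = gk_covered_impedance(zn, zm, params)
    z_spec = 1.0 / (phi / zc + (1.0 - phi) / zn)
    zw = np.asarray(z_spec / model.electrode_area + model.series_resistance)
    return zw if zw.ndim else complex(zw)


def series_rc(z: complex, f: float, *, well: str | None = None,
              time_h: float | None = None) -> RCReading:
    """Series-equivalent decomposition ``Z = R + 1/(j 2 pi f C)``.

    Requires a capacitive reading (``Im Z < 0``); otherwise raises
    :class:`NonCapacitiveError` carrying whatever context was supplied.
    """
    if f <= 0:
        raise ValueError("frequency must be strictly positive")
    z = complex(z)
    if z.imag >= 0:
        raise NonCapacitiveError(
            f"non-capacitive reading Im(Z)={z.imag:g} >= 0 at {f:g} Hz"
            + (f" (well {well}, t={time_h} h)" if well is not None else ""),
            well=well, time_h=time_h, frequency_hz=f,
        )
    return RCReading(resistance=z.real, capacitance=-1.0 / (2.0 * math.pi * f * z.imag))
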