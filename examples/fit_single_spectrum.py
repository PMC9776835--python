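"""Inverse problem: recover (Rb, alpha, Cm) from one noisy spectrum.

Synthesizes a 9-frequency spectrum for a known barrier state, adds 1%
multiplicative noise, and fits it against the cell-free reference.
"""

import numpy as np

from ecisbarrier import (
    BarrierParams,
    ComplexSpectrum,
    ElectrodeModel,
    FrequencyGrid,
    fit_barrier_params,
    naked_impedance,
    well_impedance,
)

electrode = ElectrodeModel()
grid = FrequencyGrid.default()
f = grid.as_array()
truth = BarrierParams(rb=4.0, alpha=8.0, cm=1.5)

rng = np.random.default_rng(0)
z = well_impedance(electrode, truth, f)
z = (z.real * (1 + 0.01 * rng.standard_normal(f.size))
     + 1j * z.imag * (1 + 0.01 * rng.standard_normal(f.size)))
measured = ComplexSpectrum(grid, z)
reference = ComplexSpectrum(
    grid, naked_impedance(electrode, f) / electrode.electrode_area
    + electrode.series_resistance)

result = fit_barrier_params(measured, reference, electrode)
p = result.params
print(f"truth:  Rb = {truth.rb:.3f} ohm cm^2, alpha = {truth.alpha:.3f} "
      f"ohm^0.5 cm, Cm = {truth.cm:.3f} uF/cm^2")
print(f"fitted: Rb = {p.rb:.3f} ohm cm^2, alpha = {p.alpha:.3f} "
      f"ohm^0.5 cm, Cm = {p.cm:.3f} uF/cm^2")
print(f"rss = {result.rss:.2e}, status = {result.termination_reason.value}")
print()
print("At 1% instrument noise the three barrier parameters come back within")
print("a few percent; Rb is the softest direction of the fit.")
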