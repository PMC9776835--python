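"""Forward model: what a naked and a confluent well look like.

Builds the default electrode, evaluates the cell-free (naked) and the
cell-covered well impedance across the 9-frequency grid, and prints the
series-equivalent resistance and capacitance the instrument would report.
"""

from ecisbarrier import (
    BarrierParams,
    ElectrodeModel,
    FrequencyGrid,
    series_rc,
    well_impedance,
)

electrode = ElectrodeModel()
vehicle = BarrierParams(rb=4.0, alpha=8.0, cm=1.5)  # confluent monolayer

print(f"{'f (Hz)':>8} | {'naked R (ohm)':>13} {'naked C (nF)':>12} | "
      f"{'covered R (ohm)':>15} {'covered C (nF)':>14}")
for f in FrequencyGrid.default():
    z_naked = complex(well_impedance(electrode.with_coverage(0.0), vehicle, f))
    z_cov = complex(well_impedance(electrode, vehicle, f))
    rc_n, rc_c = series_rc(z_naked, f), series_rc(z_cov, f)
    print(f"{f:8.0f} | {rc_n.resistance:13.0f} {rc_n.capacitance_nf:12.1f} | "
          f"{rc_c.resistance:15.0f} {rc_c.capacitance_nf:14.2f}")

print()
print("The covered-to-naked resistance ratio peaks near 4 kHz (the optimum")
print("frequency for the barrier signal), and the covered 64 kHz capacitance")
print("sits far below the naked ~41 nF -- under the 20 nF criterion that")
print("marks a confluent monolayer.")
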