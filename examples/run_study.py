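"""A small end-to-end study: simulate, decompose, fit, time the collapse.

Simulates the vehicle and the two FCCP arms (3 wells each to keep this
quick), extracts normalized 64 kHz capacitance curves, and fits the
low-dose FCCP wells to time the final sustained collapse of the
paracellular barrier.
"""

import dataclasses

from ecisbarrier import FitOptions, SimConfig, default_arms, simulate_dataset
from ecisbarrier.pipeline import (
    arm_mean_curve,
    crossing_time,
    decompose,
    fit_study,
    normalized_well_curves,
    plateau_level,
    rb_zero_times,
)

config = SimConfig(seed=0)
arms = [dataclasses.replace(a, n_wells=3) for a in default_arms()
        if a.label in ("vehicle", "fccp_1uM", "fccp_10uM")]
sim = simulate_dataset(arms, config)
print(f"simulated {sim.impedance['well'].nunique()} wells, "
      f"{len(sim.impedance)} impedance rows")

rc = decompose(sim.impedance)
membership = dict(rc.groupby("well")["group"].first())
curves = normalized_well_curves(rc, "capacitance", 64000.0)
veh = arm_mean_curve(curves, membership, "vehicle")
hi = arm_mean_curve(curves, membership, "fccp_10uM")
lo = arm_mean_curve(curves, membership, "fccp_1uM")

level = plateau_level(hi)
print(f"normalized 64 kHz capacitance plateau, high dose vs vehicle: "
      f"{level / plateau_level(veh):.2f}-fold")
print(f"low dose reaches that level at t = {crossing_time(lo, level):.2f} h")

fits = fit_study(sim.impedance, sim.reference, config.electrode,
                 FitOptions(), groups=["fccp_1uM"])
zt = rb_zero_times(fits)
print("low-dose Rb final return to zero, per well (h):",
      zt["rb_zero_time_h"].tolist())
print()
print("The high-dose uncoupler lifts the spreading capacitance ~6-fold at")
print("once; the low dose takes ~20 h to catch up, and its barrier (Rb)")
print("makes a transient rebound before collapsing for good at ~2.5 h.")
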