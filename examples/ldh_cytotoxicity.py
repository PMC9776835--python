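"""LDH cytotoxicity analysis of the simulated plate.

Simulates the 24/48 h LDH plate for all seven arms, corrects the
background (A490 - A680), normalizes to vehicle and runs ANOVA + Tukey.
"""

from ecisbarrier import (
    SimConfig,
    default_arms,
    ldh_group_analysis,
    significant_vs_vehicle,
    simulate_ldh,
)

plate = simulate_ldh(default_arms(), SimConfig(seed=0))
results = ldh_group_analysis(plate, vehicle_label="vehicle")

for timepoint, res in sorted(results.items()):
    flags = significant_vs_vehicle(res)
    toxic = sorted(g for g, sig in flags.items() if sig)
    print(f"t = {timepoint:.0f} h:  ANOVA F = {res.f_statistic:.1f}, "
          f"p = {res.p_value:.2e}")
    print(f"  arms with significant LDH release vs vehicle: {toxic or 'none'}")

print()
print("Only the high-dose uncoupler and ATP-synthase arms are cytotoxic at")
print("24 h; the complex-I arms release LDH only by 48 h -- so their early")
print("barrier collapse is not a cell-death artifact.")
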