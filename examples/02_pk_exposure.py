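"""Plasma and tumor exposure of capmatinib 400 mg BID, human and mouse.

Simulates two weeks of twice-daily oral dosing with the one-compartment
model from the drug library, then derives mouse parameters by reverse
allometric scaling (clearance ~ weight^0.75, volume ~ weight^1).
"""

from metqsp import load_drug_library, reverse_allometric, simulate_pk

lib = load_drug_library()
rec = lib["capmatinib"]
reg = rec.default_regimen.repeated_for(14 * 24.0)
trace = simulate_pk(rec.pk, reg, 14 * 24.0, drug="capmatinib")

day14 = trace.time_h >= 13 * 24.0
cmax = trace.plasma_nM[day14].max()
cmin = trace.plasma_nM[day14].min()
print(f"capmatinib 400 mg BID, day 14: Cmax {cmax:.0f} nM, Cmin {cmin:.0f} nM")
print(f"tumor:plasma partition {rec.pk.kp_tumor}: tumor Cmax "
      f"{rec.pk.kp_tumor * cmax:.0f} nM")

mouse = rec.mouse_pk()
print(f"\nreverse allometric scaling human -> mouse (70 kg -> 20 g):")
print(f"  CL {rec.pk.CL:.1f} -> {mouse.CL:.4f} L/h   "
      f"Vc {rec.pk.Vc:.0f} -> {mouse.Vc:.4f} L")
print("absorption (ka) and bioavailability (F) are species-invariant.")
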