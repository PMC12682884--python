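"""Global sensitivity of day-90 xenograft outputs by LHS + PRCC.

Samples growth-relevant parameters log-uniformly over 1/3-3x their
baselines (Latin hypercube, scaled-down n = 120) and computes partial rank
correlation coefficients of (a) untreated day-90 tumor volume and (b)
day-90 percent diameter change under capmatinib.  Positive coefficients
drive growth; negative coefficients restrain it.
"""

import numpy as np

from metqsp import load_drug_library, simulate_pk
from metqsp.fixtures import mouse_xenograft_params
from metqsp.pk import DoseRegimen
from metqsp.sensitivity import run_paper_scenarios

base = mouse_xenograft_params()
rec = load_drug_library()["capmatinib"]
reg = DoseRegimen(10.0, "BID", per_kg=True).repeated_for(90 * 24.0)
exposure = {"capmatinib": simulate_pk(rec.mouse_pk(), reg, 90 * 24.0,
                                      drug="capmatinib").smoothed()}

names = ["kt_14_MET", "kd_14_MET", "kp_14_MET", "kdp_14_MET",
         "kt_akt_cell", "kt_erk_cell", "kd_cell"]
res_untreated, res_treated = run_paper_scenarios(
    base, names, rec.actions, exposure, n=120, seed=0,
)

for res in (res_untreated, res_treated):
    print(f"\n{res.output_label}:")
    t = res.table.sort_values("prcc", key=np.abs, ascending=False)
    for _, row in t.iterrows():
        mark = "*" if row["significant"] else " "
        print(f"  {row['parameter']:<14} PRCC {row['prcc']:+.2f} "
              f"(p={row['p_value']:.2g}){mark}")
print("\n* Bonferroni-significant at alpha = 0.05; MET synthesis drives "
      "growth (+), MET degradation and cell death restrain it (-).")
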