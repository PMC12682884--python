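# Drug library: 16 agents across three mechanism classes.
# PK parameter values are literature-informed placeholders (the engine, not
# the values, is the deliverable); action constants are model-scale values.
# Units: ka 1/h, Vc/Vp L, CL/Q L/h, molecular_weight g/mol, kon nM^-1 h^-1,
# koff 1/h, ic50/ec50 nM, emax 1/h, doses mg (per_m2 -> mg/m^2).

crizotinib:
  class: tki
  actions:
    - {mechanism: met_tki_binding, kon: 5.0e-4, kon_oe: 4.0e-4, koff: 0.1}
    - {mechanism: kinase_hill_inhibition, target: ALK, ic50: 80.0, hill: 1.0}
    - {mechanism: kinase_hill_inhibition, target: ROS1, ic50: 60.0, hill: 1.0}
  pk: {n_compartments: 1, route: oral, ka: 0.6, Vc: 1000.0, CL: 60.0, F: 0.43,
       molecular_weight: 450.3, kp_tumor: 0.8}
  default_regimen: {amount: 250.0, schedule: BID}

tepotinib:
  class: tki
  actions:
    - {mechanism: met_tki_binding, kon: 1.5e-3, kon_oe: 1.2e-3, koff: 0.1}
  pk: {n_compartments: 1, route: oral, ka: 0.3, Vc: 1000.0, CL: 22.0, F: 0.72,
       molecular_weight: 492.6, kp_tumor: 0.8}
  default_regimen: {amount: 500.0, schedule: QD}

capmatinib:
  class: tki
  actions:
    - {mechanism: met_tki_binding, kon: 2.0e-3, kon_oe: 1.5e-3, koff: 0.1}
  pk: {n_compartments: 1, route: oral, ka: 1.0, Vc: 164.0, CL: 24.0, F: 0.7,
       molecular_weight: 412.4, kp_tumor: 0.8}
  default_regimen: {amount: 400.0, schedule: BID}

savolitinib:
  class: tki
  actions:
    - {mechanism: met_tki_binding, kon: 1.0e-3, kon_oe: 8.0e-4, koff: 0.1}
  pk: {n_compartments: 1, route: oral, ka: 1.2, Vc: 200.0, CL: 35.0, F: 0.65,
       molecular_weight: 345.4, kp_tumor: 0.8}
  default_regimen: {amount: 600.0, schedule: QD}

cabozantinib:
  class: tki
  actions:
    - {mechanism: met_tki_binding, kon: 8.0e-4, kon_oe: 6.0e-4, koff: 0.1}
  pk: {n_compartments: 2, route: oral, ka: 0.5, Vc: 120.0, Vp: 200.0, CL: 2.2,
       Q: 10.0, F: 0.5, molecular_weight: 501.5, kp_tumor: 0.6}
  default_regimen: {amount: 60.0, schedule: QD}
  reverse_allometric_mouse: true

erlotinib:
  class: tki
  actions:
    - {mechanism: kinase_hill_inhibition, target: EGFR, ic50: 50.0, hill: 1.0}
  pk: {n_compartments: 1, route: oral, ka: 0.9, Vc: 232.0, CL: 4.5, F: 0.6,
       molecular_weight: 393.4, kp_tumor: 0.8}
  default_regimen: {amount: 150.0, schedule: QD}

gefitinib:
  class: tki
  actions:
    - {mechanism: kinase_hill_inhibition, target: EGFR, ic50: 400.0, hill: 1.0}
  pk: {n_compartments: 1, route: oral, ka: 0.7, Vc: 1400.0, CL: 30.0, F: 0.6,
       molecular_weight: 446.9, kp_tumor: 0.8}
  default_regimen: {amount: 250.0, schedule: QD}

GDC0941:
  class: kinase_inhibitor
  actions:
    - {mechanism: kinase_hill_inhibition, target: PI3K, ic50: 150.0, hill: 1.0}
  pk: {n_compartments: 1, route: oral, ka: 0.8, Vc: 200.0, CL: 20.0, F: 0.6,
       molecular_weight: 513.6, kp_tumor: 0.8}
  default_regimen: {amount: 340.0, schedule: QD}
  reverse_allometric_mouse: true

MK2206:
  class: kinase_inhibitor
  actions:
    - {mechanism: kinase_hill_inhibition, target: AKT, ic50: 200.0, hill: 1.0}
  pk: {n_compartments: 1, route: oral, ka: 0.4, Vc: 600.0, CL: 12.0, F: 0.6,
       molecular_weight: 408.4, kp_tumor: 0.8}
  default_regimen: {amount: 135.0, schedule: custom, interval_h: 168.0}

trametinib:
  class: kinase_inhibitor
  actions:
    - {mechanism: kinase_hill_inhibition, target: MEK, ic50: 25.0, hill: 1.0}
  pk: {n_compartments: 1, route: oral, ka: 0.5, Vc: 214.0, CL: 5.0, F: 0.72,
       molecular_weight: 615.4, kp_tumor: 0.8}
  default_regimen: {amount: 2.0, schedule: QD}
  reverse_allometric_mouse: true

BVD523:
  class: kinase_inhibitor
  actions:
    - {mechanism: kinase_hill_inhibition, target: ERK, ic50: 150.0, hill: 1.0}
  pk: {n_compartments: 1, route: oral, ka: 0.8, Vc: 300.0, CL: 50.0, F: 0.6,
       molecular_weight: 433.3, kp_tumor: 0.8}
  default_regimen: {amount: 600.0, schedule: BID}

cisplatin:
  class: chemo
  actions:
    - {mechanism: chemo_cell_kill, emax: 0.025, ec50: 4000.0, hill: 1.0}
  pk: {n_compartments: 1, route: iv_infusion, Vc: 20.0, CL: 25.0, F: 1.0,
       molecular_weight: 300.0, kp_tumor: 0.7, infusion_duration_h: 1.0}
  default_regimen: {amount: 75.0, schedule: Q3W, per_m2: true}

carboplatin:
  class: chemo
  actions:
    - {mechanism: chemo_cell_kill, emax: 0.02, ec50: 12000.0, hill: 1.0}
  pk: {n_compartments: 1, route: iv_infusion, Vc: 17.0, CL: 7.0, F: 1.0,
       molecular_weight: 371.25, kp_tumor: 0.7, infusion_duration_h: 1.0}
  default_regimen: {amount: 400.0, schedule: Q3W, per_m2: true}

pemetrexed:
  class: chemo
  actions:
    - {mechanism: chemo_cell_kill, emax: 0.03, ec50: 300.0, hill: 1.0}
  pk: {n_compartments: 1, route: iv_infusion, Vc: 16.0, CL: 5.0, F: 1.0,
       molecular_weight: 427.4, kp_tumor: 0.7, infusion_duration_h: 0.25}
  default_regimen: {amount: 500.0, schedule: Q3W, per_m2: true}

docetaxel:
  class: chemo
  actions:
    - {mechanism: chemo_cell_kill, emax: 0.035, ec50: 50.0, hill: 1.0}
  pk: {n_compartments: 2, route: iv_infusion, Vc: 10.0, Vp: 100.0, CL: 36.0,
       Q: 20.0, F: 1.0, molecular_weight: 807.9, kp_tumor: 0.7,
       infusion_duration_h: 1.0}
  default_regimen: {amount: 75.0, schedule: Q3W, per_m2: true}

gemcitabine:
  class: chemo
  actions:
    - {mechanism: chemo_cell_kill, emax: 0.03, ec50: 100.0, hill: 1.0}
  pk: {n_compartments: 1, route: iv_infusion, Vc: 18.0, CL: 150.0, F: 1.0,
       molecular_weight: 263.2, kp_tumor: 0.7, infusion_duration_h: 0.5}
  default_regimen: {amount: 1250.0, schedule: Q3W, per_m2: true}
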