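# Methods

## Signaling model

One cancer clone is a well-mixed reaction system in copies/cell (ligands
and drugs in nM, time in hours), integrated with LSODA at relative
tolerance 1e-8 and per-species absolute tolerance 1e-10·max(|y₀|, 1).
Receptor modules (MET, EGFR, ALK, ROS1) carry synthesis, degradation,
ligand binding (HGF, EGF as external forcing concentrations — assay media
and plasma are treated as undepleted reservoirs), phosphorylation /
dephosphorylation, and drug interactions.  The two proliferative cascades
(PI3K→AKT, RAS→MEK→ERK) are conserved active/inactive pairs whose
activation rate is proportional to a weighted sum of all active receptor
copies (crosstalk weights default to 1).

Design choices where the mechanism literature gives a taxonomy but not an
equation list:

- **Reduced network.** The model covers every mechanism class —
  four receptor pathways, two cascades, three drug-action classes — with
  21 base species per clone (plus one receptor–drug complex species per
  MET TKI per receptor pool).  Structural fidelity was preferred over
  species count.
- **Three MET pools.** Wild-type MET: phosphorylated forms recruit Cbl
  and degrade ~10× faster (the `cbl_degradation_factor`), which produces
  the HGF-induced loss of total MET.  Exon-14-skipped MET: the Cbl route
  is absent and basal degradation is slower (`kd_14_MET < kd_MET` is a
  hard invariant), giving receptor accumulation and prolonged
  phosphorylation.  Amplified surplus pool: synthesised at
  `(amplification − 1)·kt_MET` with its own degradation (`kd_oe_MET`) and
  its own TKI on-rate (`kon_oe`).
- **Ligand-independent auto-activation** is second order in free MET
  (rate `k_auto·[MET_free]²`, a dimerisation surrogate), so amplification
  raises basal phospho-MET superlinearly — doubling synthesis more than
  doubles basal signal.
- **TKI binding** targets un-phosphorylated, ligand-free receptor only
  (ATP-pocket competition surrogate); bound receptor cannot
  phosphorylate and turns over at the pool's basal degradation rate.
  Whether TKIs also bind phosphorylated receptor is left out of the
  model; with fast dephosphorylation the free pool dominates anyway.
- **ALK/ROS1 aberrations** are clone flags enabling first-order
  constitutive autophosphorylation.
- Ligand ng/mL→nM conversion uses fixed molecular weights (HGF 83 kDa,
  EGF 6.2 kDa).

Steady states (`equilibrate`) integrate the drug-free, ligand-free system
in doubling chunks until `max |dy/dt| < 1e-9·max(y, 1)`, and are the
initial condition for every perturbation.  The reference (A549-like) cell
is anchored to measured abundances — 13,590 MET and 158,834 EGFR
receptors per cell — by a fixed-point calibration of the synthesis rates
(basal auto-activation flux feeds back on the total, so `kt = kd·target`
alone would be slightly off).  Default downstream rate constants were
chosen once so that the wild-type clone is basally quiet (fAKT ≈ 0.13)
while the aberrant clones signal strongly (fAKT ≈ 0.6), the separation
that makes MET-targeted therapy selective in the model.

## Pharmacokinetics

Linear compartmental models are integrated per single dose (LSODA, rtol
1e-10) and superposed over the schedule, evaluated exactly at the
requested sample times (dense-grid interpolation only beyond 200k sample
points).  Tumor concentration is `kp_tumor × plasma`.  mg/m² doses use a
1.8 m² body surface area for virtual patients; mg/kg doses use 70 kg
(human) or 20 g (mouse).  Reverse allometry scales clearances by
(W_m/W_h)^0.75 and volumes by (W_m/W_h)^1.0, leaving ka and F unchanged;
it is the default route to mouse PK for every library drug.  Infusions
are zero-order over the stated duration (default 1 h for chemotherapy).
Per-drug PK values in `data/drugs.yaml` are literature-informed
placeholders — the engine, not the values, is the deliverable.

For simulations spanning months, exposure may be daily-averaged
(`ExposureTrace.smoothed`): receptor–drug binding equilibrates within
hours of each dose while tumor burden responds over weeks, so the
within-day concentration oscillation is exchanged for its 24-h moving
average (knots every 2 h during accumulation, every 24 h after).  The
trial and organoid-projection layers use this by default; cell-level
simulations never do.

## Tumor growth

Each clone's per-capita rate is
`(k0 + kt_akt_cell·fAKT + kt_erk_cell·fERK)·(1 − V/V_max) − kd_cell −
Σ kill(C)`, linear in the active fractions (no saturation — this keeps
PRCC interpretation clean), with logistic crowding shared through the
total volume.  Cell counts map to volume at 1e6 cells/mm³ and to
spherical diameter.  V_max: mouse 2000 mm³; patient 1e6 mm³ (non-binding
over trial horizons); in vitro effectively unbounded.  Note the untreated
asymptote is `V_max·(1 − kd/g)`, not V_max itself; the xenograft
reference parameterization (`mouse_xenograft_params`) uses negligible
spontaneous death (kd = 2e-4 h⁻¹), as xenograft lines are
proliferation-dominated, so the untreated arm plateaus at the cap (within
2 %).  Patient-level clones keep a substantive death rate (0.004 h⁻¹), so
suppressing signaling turns growth negative and tumors regress under
effective therapy.

In-vitro viability reuses the clone ODEs at constant drug concentration
and normalises treated to untreated cell count at the assay endpoint; for
pure cell-kill (chemotherapy-only) wells this reduces exactly to
`exp(−kill(C)·t)` and that closed form is used.

## Calibration

Observables are compared after the source experiment's normalisation
(to-max or to-control); objectives are weighted SSE with model output
interpolated onto the data grid, default weight 1/(points per set) so
every dataset counts equally regardless of sampling density.  The
optimizer is a generalized pattern search: coordinate poll on a
normalised box (log-scale for rate constants), mesh doubling on success
(capped at the initial 0.25 of box width), halving on failure, stopping
at 1e-6 of box width or the evaluation budget; deterministic given its
seed (which only shuffles poll order).  No gradients are needed, which
matters for stiff-ODE objectives.  Uncertainty is assessed only by
repeated-seed scatter; there is no posterior.

## Virtual patients and trials

A patient = independent log-normal multipliers (σ = 0.4, clipped to
[1/3, 3]) on MET activation, AKT/ERK activation, and per-clone growth and
death rates, for a two-clone tumor (aberrant + "normal cancer cell").
The normal clone's proliferation is largely MET-independent (higher k0),
so it competes with the aberrant clone on comparable terms; it is also
the reservoir of TKI-insensitive growth that limits response depth.
Each draw grows from equal seed counts (5e5 cells each) at the clones'
steady-state exponential rates — crowding is negligible below the
threshold — until total burden reaches a 30 mm-diameter baseline; the
hitting time sets that patient's clone ratio.  Screening rejects draws
that cannot reach threshold within 5 years.  Treatment simulations then
integrate the full coupled system; since a patient's course is
deterministic given the arm, each cohort member is simulated once and the
repeated trial runs resample the cached best responses.

RECIST v1.1 on percent diameter change: PR ≤ −30, PD ≥ +20, CR
operationalized as ≤ −99.5 (the ODE never reaches exactly zero); the
absolute-5-mm PD rule is omitted because waterfalls are pure percentages.
Assessments default to every 6 weeks for 12 months.  ORR per run is the
CR+PR fraction; over the repeated runs a KS test against a normal with
the sample moments picks the interval branch (mean ± 1.96·sd if not
rejected at α = 0.05, else 2.5/97.5 percentiles), clipped to [0, 100].
Prevalence weighting toward a clinical training waterfall is binned
importance resampling (10 %-wide best-change bins); training mass in bins
with no cohort member is spread uniformly with a warning.

## Sensitivity analysis

LHS draws are log-uniform within multiplicative ranges (default 1/3–3×
baseline, one point per equiprobable stratum; "5000 iterations" is read
as 5000 total samples).  PRCC comes from the precision matrix of the
joint rank-correlation matrix; an explicit residualization implementation
(`prcc_bruteforce`) exists purely as an independent cross-check and the
two agree to 1e-10.  p-values use the t approximation with n − p − 2
degrees of freedom; "significant" means Bonferroni-corrected α = 0.05
across the tested parameters.  The packaged scenarios score day-90
untreated tumor volume and day-90 percent diameter change under
capmatinib at the mouse level.

## Organoid personalization

Day-7 viability panels on the assay's concentration grids (e.g. 0, 0.01,
0.1, 0.3163, 1, 3.163, 10 μM) are fitted by the same pattern search over
three handles: growth multiplier [1/3, 3], amplification factor [1, 20],
and per-drug potency [0.01, 100] (potency scales kon up or IC50/EC50
down).  Amplification and potency trade off against each other in a
viability curve, so a quadratic penalty on log(growth) and
log(amplification) (weight 0.05) pulls the under-determined handles
toward baseline — the fitted potencies carry the identifiable signal.
Flat panels pin potency at the lower bound with a recorded warning.
Combination wells apply both actions simultaneously through the shared
ODE (independent action; no interaction parameter).  Drugs without a
library PK entry can be fitted generically but clinical projection
refuses them explicitly.  Projections run ≥ 3 months on a weekly grid and
annotate the −30/+20 % thresholds; dose-reduction scans are
full-factorial over the fraction grid, sorted by response.

## Synthetic data

Every generator simulates the mechanistic model under a known truth and
applies mean-one multiplicative lognormal noise (σ² = ln(1+CV²)), so
replicate averages converge on the noiseless curve; consumer tests are
parameter-recovery or distribution-match assertions against the carried
truth record.  The generators emulate assay structure (normalisation,
grids, per-animal curves, truncated-normal waterfall mixtures) but not
real-data pathologies — batch effects, heteroscedastic digitization
error, censoring — so passing recovery tests demonstrates correctness of
the inference machinery, not field performance on literature data.

## Problem sizes and determinism

Package defaults favour interactive use: example cohorts of ~24 patients
with 20 repeated runs, PRCC designs of 100–200 samples, and fitting
budgets of a few hundred evaluations; all sizes scale up by argument
(5000-patient cohorts and 5000-sample designs are the same code path).
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; CLI runs write a manifest with the options,
seed, and SHA-256 of every output so identical configuration reproduces
identical tables.

## Known limitations

- No receptor trafficking compartments, autocrine ligand loops, or
  resistance-mutation kinetics; no spatial structure, immune compartment,
  or metastasis.
- No nonlinear clearance or inter-occasion PK variability.
- Survival-type endpoints (duration of response, OS) are out of scope;
  the trial engine scores best response only.
- Rate-constant defaults are calibrated to qualitative behavior classes
  (transient vs sustained phosphorylation, selective TKI effect), not to
  a specific published dataset; quantitative clinical ORRs are therefore
  illustrative, and orderings (dose, combination, clone sensitivity) are
  the meaningful outputs.
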