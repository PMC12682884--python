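"""Virtual-patient cohorts, RECIST scoring, and repeated virtual clinical trials.

Virtual patients are sampled by drawing independent log-normal multipliers
(clipped to a plausibility envelope, default 1/3-3x) on the activation rates
of MET, AKT and ERK and on clone growth/death rates, for a tumor containing
one MET-aberrant clone (exon-14-skipped or amplified) plus a normal cancer
clone.  Each draw is grown from seed counts until the tumor reaches a
threshold burden, which becomes that patient's baseline, so clone ratios
differ patient to patient.  Treatment simulations score best percent
diameter change on a periodic assessment grid against RECIST v1.1 cut-offs
(PR at -30%, PD at +20%); per-run objective response rate (ORR) is the CR+PR
fraction, and repeated resampled runs yield a 95% prediction interval after
a Kolmogorov-Smirnov check of normality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .library import DrugRecord
from .network import CloneParameters, build_network, equilibrate
from .pk import DoseRegimen, simulate_pk
from .tumor import (
    CELL_DENSITY_PER_MM3,
    ClonePopulation,
    GrowthCoupling,
    TumorState,
    diameter_to_volume,
    per_capita_growth,
    simulate_tumor,
    total_volume_series,
)

__all__ = [
    "VariabilitySpec",
    "VirtualPatient",
    "Cohort",
    "TreatmentArm",
    "TrialResult",
    "generate_cohort",
    "classify_recist",
    "simulate_patient_response",
    "run_trial",
    "prevalence_weighted_resample",
    "orr_prediction_interval",
    "TrialError",
]

RECIST_PR_THRESHOLD = -30.0     # percent diameter change
RECIST_PD_THRESHOLD = 20.0
RECIST_CR_THRESHOLD = -99.5     # operational near-disappearance cut-off

DEFAULT_THRESHOLD_DIAMETER_MM = 30.0
SCREEN_MAX_GROWTH_YEARS = 5.0

# multiplier key -> (clone selector, parameter names); "aberrant"/"wild_type"/"both"
VARIED_PARAMETERS: dict[str, tuple[str, tuple[str, ...]]] = {
    "met_activation": ("aberrant", ("kp_MET", "kp_14_MET", "k_auto_MET")),
    "akt_activation": ("both", ("kact_AKT",)),
    "erk_activation": ("both", ("kact_ERK",)),
    "growth_aberrant": ("aberrant", ("k0_cell", "kt_akt_cell", "kt_erk_cell")),
    "growth_wild_type": ("wild_type", ("k0_cell", "kt_akt_cell", "kt_erk_cell")),
    "death_aberrant": ("aberrant", ("kd_cell",)),
    "death_wild_type": ("wild_type", ("kd_cell",)),
}


class TrialError(ValueError):
    pass


@dataclass
class VariabilitySpec:
    """Log-normal interindividual variability, clipped to a range envelope."""

    sigma: Mapping[str, float] = field(
        default_factory=lambda: {k: 0.4 for k in VARIED_PARAMETERS}
    )
    clip_low: float = 1.0 / 3.0
    clip_high: float = 3.0

    def __post_init__(self) -> None:
        for k in self.sigma:
            if k not in VARIED_PARAMETERS:
                raise TrialError(f"unknown varied parameter {k!r}")
            if self.sigma[k] < 0:
                raise TrialError("sigma must be >= 0")
        if not 0 < self.clip_low <= 1 <= self.clip_high:
            raise TrialError("clip range must bracket 1")

    def draw(self, rng: np.random.Generator) -> dict[str, float]:
        return {
            k: float(np.clip(rng.lognormal(0.0, s), self.clip_low, self.clip_high))
            for k, s in self.sigma.items()
        }


@dataclass
class VirtualPatient:
    """One sampled patient: multipliers, clone mix at threshold, baseline burden."""

    id: int
    multipliers: dict[str, float]
    aberrant_kind: str
    aberrant_params: CloneParameters
    wild_type_params: CloneParameters
    clone_cells: tuple[float, float]       # (aberrant, wild_type) at baseline
    baseline_volume_mm3: float
    time_to_threshold_h: float
    growth_rates: tuple[float, float]      # untreated per-capita rates (1/h)
    signaling_states: tuple[dict, dict] | None = None  # cached drug-free steady states
    weight: float = 1.0

    @property
    def aberrant_fraction(self) -> float:
        tot = sum(self.clone_cells)
        return self.clone_cells[0] / tot if tot > 0 else 0.0


@dataclass
class Cohort:
    kind: str                      # "METex14" | "MET_amplified"
    patients: list[VirtualPatient]
    seed: int
    threshold_diameter_mm: float
    n_rejected: int = 0

    def __len__(self) -> int:
        return len(self.patients)


def _untreated_rate(params: CloneParameters) -> tuple[float, dict[str, float]]:
    """Per-capita net growth at the clone's drug-free signaling steady state.

    Below the patient-level carrying capacity the crowding term is
    negligible, so untreated growth to threshold is exponential per clone.
    Returns the rate and the steady state (reused as the treatment
    simulation's initial signaling condition).
    """
    net = build_network(params)
    ss = equilibrate(net)
    frac = {}
    for kin, key in (("AKT", "fAKT"), ("ERK", "fERK")):
        tot = sum(ss[s] for s in net.groups[kin])
        act = sum(ss[s] for s in net.active_species[kin])
        frac[key] = act / tot if tot > 0 else 0.0
    rate = per_capita_growth(frac, GrowthCoupling.from_clone(params), 0.0, np.inf)
    return rate, ss


def generate_cohort(
    base_aberrant: CloneParameters,
    base_wild_type: CloneParameters,
    n: int,
    kind: str,
    variability: VariabilitySpec | None = None,
    threshold_diameter_mm: float = DEFAULT_THRESHOLD_DIAMETER_MM,
    seed: int = 0,
    seed_cells: tuple[float, float] = (5.0e5, 5.0e5),
) -> Cohort:
    """Sample ``n`` screened virtual patients of the given population kind.

    Screening rejects draws whose untreated tumor cannot reach the threshold
    burden within five simulated years.  Rejection above 99% is a
    configuration error.
    """
    if kind not in ("METex14", "MET_amplified"):
        raise TrialError("kind must be 'METex14' or 'MET_amplified'")
    expected = "ex14" if kind == "METex14" else "amplified"
    if base_aberrant.clone_kind != expected:
        raise TrialError(f"{kind} cohort needs an {expected!r} aberrant clone")
    variability = variability or VariabilitySpec()
    rng = np.random.default_rng(seed)
    threshold_cells = diameter_to_volume(threshold_diameter_mm) * CELL_DENSITY_PER_MM3
    t_max = SCREEN_MAX_GROWTH_YEARS * 365.0 * 24.0

    patients: list[VirtualPatient] = []
    n_rejected = 0
    pid = 0
    while len(patients) < n:
        if n_rejected > 99 * max(n, 1) and not patients:
            raise TrialError("screening rejected >99% of draws; check variability spec")
        mult = variability.draw(rng)
        pa, pw = _apply_multipliers(base_aberrant, base_wild_type, mult)
        (ga, ss_a), (gw, ss_w) = _untreated_rate(pa), _untreated_rate(pw)
        t_star = _time_to_threshold(seed_cells, (ga, gw), threshold_cells, t_max)
        if t_star is None:
            n_rejected += 1
            continue
        cells = (
            seed_cells[0] * np.exp(ga * t_star),
            seed_cells[1] * np.exp(gw * t_star),
        )
        patients.append(
            VirtualPatient(
                id=pid,
                multipliers=mult,
                aberrant_kind=expected,
                aberrant_params=pa,
                wild_type_params=pw,
                clone_cells=cells,
                baseline_volume_mm3=sum(cells) / CELL_DENSITY_PER_MM3,
                time_to_threshold_h=t_star,
                growth_rates=(ga, gw),
                signaling_states=(ss_a, ss_w),
            )
        )
        pid += 1
    return Cohort(kind, patients, seed, threshold_diameter_mm, n_rejected)


def _apply_multipliers(
    base_aberrant: CloneParameters,
    base_wild_type: CloneParameters,
    mult: Mapping[str, float],
) -> tuple[CloneParameters, CloneParameters]:
    ab: dict[str, float] = {}
    wt: dict[str, float] = {}
    for key, m in mult.items():
        sel, names = VARIED_PARAMETERS[key]
        for name in names:
            if sel in ("aberrant", "both"):
                ab[name] = ab.get(name, 1.0) * m
            if sel in ("wild_type", "both"):
                wt[name] = wt.get(name, 1.0) * m
    return base_aberrant.with_overrides(ab), base_wild_type.with_overrides(wt)


def _time_to_threshold(seed_cells, rates, threshold_cells, t_max) -> float | None:
    def total(t):
        # cap the exponent: only the bracketing sign matters far above threshold
        return sum(n0 * np.exp(min(g * t, 500.0)) for n0, g in zip(seed_cells, rates))

    if total(0.0) >= threshold_cells:
        return 0.0
    if total(t_max) < threshold_cells:
        return None
    return float(optimize.brentq(lambda t: total(t) - threshold_cells, 0.0, t_max))


def classify_recist(best_change_pct: float) -> str:
    """RECIST v1.1 class from the best percent diameter change."""
    if not np.isfinite(best_change_pct):
        raise TrialError("best change must be finite")
    if best_change_pct <= RECIST_CR_THRESHOLD:
        return "CR"
    if best_change_pct <= RECIST_PR_THRESHOLD:
        return "PR"
    if best_change_pct >= RECIST_PD_THRESHOLD:
        return "PD"
    return "SD"


@dataclass
class TreatmentArm:
    """One regimen set: drugs given simultaneously at their regimens."""

    name: str
    components: list[tuple[DrugRecord, DoseRegimen]]

    def __post_init__(self) -> None:
        if not self.components:
            raise TrialError("treatment arm needs at least one component")


def simulate_patient_response(
    patient: VirtualPatient,
    arm: TreatmentArm,
    duration_h: float = 24.0 * 365,
    assessment_interval_h: float = 24.0 * 42,
    rtol: float = 1.0e-6,
    extend_dosing: bool = True,
    smooth_exposure_h: float | None = 24.0,
) -> tuple[float, pd.Series]:
    """Best percent diameter change of one patient under one arm.

    Dosing continues through the trial duration (``extend_dosing``), as in
    treat-until-progression protocols; exposure is daily-averaged by
    default (burden responds on a weeks timescale).  Returns (best change
    over the assessment grid, the full percent-change series on that grid).
    """
    if duration_h < assessment_interval_h:
        raise TrialError("duration shorter than one assessment interval")
    exposures = {}
    for rec, reg in arm.components:
        tr = simulate_pk(
            rec.pk,
            reg.repeated_for(duration_h) if extend_dosing else reg,
            duration_h,
            drug=rec.name,
        )
        exposures[rec.name] = tr.smoothed(smooth_exposure_h) if smooth_exposure_h else tr
    actions = [a for rec, _ in arm.components for a in rec.actions]
    state = TumorState(
        [
            ClonePopulation(patient.aberrant_params, patient.clone_cells[0], drugs=actions),
            ClonePopulation(patient.wild_type_params, patient.clone_cells[1], drugs=actions),
        ]
    )
    grid = np.arange(0.0, duration_h + 1e-9, assessment_interval_h)
    traj = simulate_tumor(
        state, exposures=exposures, horizon_h=duration_h, level="patient",
        t_eval=grid, rtol=rtol,
        initial_signaling=patient.signaling_states,
    )
    v = total_volume_series(traj)
    pct = 100.0 * (np.cbrt(v / patient.baseline_volume_mm3) - 1.0)
    best = float(pct.iloc[1:].min())  # baseline itself is not an assessment
    return best, pct


@dataclass
class TrialResult:
    arm: str
    patient_best_change: np.ndarray        # per cohort patient (deterministic)
    per_run_orr: np.ndarray                # % per repeated run
    ks_p_value: float
    prediction_interval: tuple[float, float]
    waterfall: pd.DataFrame                # run-0 sample, sorted descending
    rank_range: pd.DataFrame               # per-rank min/max best change across runs

    @property
    def mean_orr(self) -> float:
        return float(self.per_run_orr.mean())


def run_trial(
    cohort: Cohort,
    arm: TreatmentArm,
    duration_h: float = 24.0 * 365,
    assessment_interval_h: float = 24.0 * 42,
    n_trial: int | None = None,
    runs: int = 100,
    seed: int = 0,
    training_waterfall: np.ndarray | None = None,
    rtol: float = 1.0e-6,
    _precomputed_best: np.ndarray | None = None,
) -> TrialResult:
    """Run ``runs`` resampled virtual trials of one arm on a cohort.

    Each run samples ``n_trial`` patients (uniformly, or prevalence-weighted
    toward a training waterfall when given) and records each sampled
    patient's best RECIST response.  Patient time courses are deterministic
    given the arm, so each cohort member is simulated once and runs resample
    the cached responses.
    """
    if len(cohort) == 0:
        raise TrialError("empty cohort")
    n_trial = n_trial or len(cohort)
    if n_trial > len(cohort):
        raise TrialError("n_trial exceeds cohort size")

    if _precomputed_best is not None:
        best = np.asarray(_precomputed_best, dtype=float)
        if best.shape != (len(cohort),):
            raise TrialError("precomputed responses must match cohort size")
    else:
        best = np.array(
            [
                simulate_patient_response(
                    p, arm, duration_h, assessment_interval_h, rtol=rtol
                )[0]
                for p in cohort.patients
            ]
        )

    rng = np.random.default_rng(seed)
    if training_waterfall is not None:
        weights = prevalence_weighted_resample(best, np.asarray(training_waterfall))
    else:
        weights = np.full(len(best), 1.0 / len(best))

    orrs = np.empty(runs)
    sorted_samples = np.empty((runs, n_trial))
    first_sample = None
    for r in range(runs):
        idx = rng.choice(len(best), size=n_trial, replace=True, p=weights)
        sample = best[idx]
        if r == 0:
            first_sample = idx
        responders = np.sum(sample <= RECIST_PR_THRESHOLD)
        orrs[r] = 100.0 * responders / n_trial
        sorted_samples[r] = np.sort(sample)[::-1]

    lo, hi, ks_p = orr_prediction_interval(orrs)
    wf = pd.DataFrame(
        {
            "patient": first_sample,
            "best_change_pct": best[first_sample],
        }
    ).sort_values("best_change_pct", ascending=False, kind="mergesort")
    wf["recist"] = [classify_recist(b) for b in wf["best_change_pct"]]
    wf = wf.reset_index(drop=True)
    rank_range = pd.DataFrame(
        {
            "rank": np.arange(n_trial),
            "min_change_pct": sorted_samples.min(axis=0),
            "max_change_pct": sorted_samples.max(axis=0),
        }
    )
    return TrialResult(
        arm=arm.name,
        patient_best_change=best,
        per_run_orr=orrs,
        ks_p_value=ks_p,
        prediction_interval=(lo, hi),
        waterfall=wf,
        rank_range=rank_range,
    )


def prevalence_weighted_resample(
    cohort_best_change: np.ndarray,
    training_waterfall: np.ndarray,
    bin_width: float = 10.0,
) -> np.ndarray:
    """Importance weights matching the cohort's best-change histogram to training.

    Both distributions are binned in ``bin_width``-percent bins over
    [-100, 100]; each patient's weight is the training mass of its bin
    divided by the cohort mass.  Training mass falling in bins with no
    cohort member triggers a warning and is spread uniformly.  Weights sum
    to one.
    """
    best = np.asarray(cohort_best_change, dtype=float)
    train = np.clip(np.asarray(training_waterfall, dtype=float), -100.0, 100.0)
    if train.size == 0:
        raise TrialError("training waterfall is empty")
    edges = np.arange(-100.0, 100.0 + bin_width, bin_width)
    t_hist, _ = np.histogram(train, bins=edges)
    t_prob = t_hist / t_hist.sum()
    idx = np.clip(np.digitize(np.clip(best, -100.0, 100.0), edges) - 1, 0, len(t_prob) - 1)
    c_counts = np.bincount(idx, minlength=len(t_prob))
    covered = c_counts > 0
    missing_mass = t_prob[~covered].sum()
    if missing_mass > 0:
        warnings.warn(
            f"{missing_mass:.1%} of training mass falls in best-change bins with "
            "no cohort member; spreading it uniformly",
            stacklevel=2,
        )
    w = np.where(
        c_counts[idx] > 0, t_prob[idx] / np.maximum(c_counts[idx], 1), 0.0
    )
    w += missing_mass / len(best)
    total = w.sum()
    if total <= 0:
        warnings.warn("degenerate prevalence weights; falling back to uniform", stacklevel=2)
        return np.full(len(best), 1.0 / len(best))
    return w / total


def orr_prediction_interval(
    orr_samples: np.ndarray, level: float = 0.95
) -> tuple[float, float, float]:
    """(lo, hi, KS p-value) prediction interval for the per-run ORR sample.

    A Kolmogorov-Smirnov test against a normal with the sample's moments
    decides the branch: the normal-theory interval mean +/- z*sd when
    normality is not rejected (alpha = 0.05), otherwise empirical
    2.5/97.5-style percentiles.  Bounds are clipped to [0, 100].
    """
    x = np.asarray(orr_samples, dtype=float)
    if x.size < 2:
        raise TrialError("need at least two ORR samples")
    mu, sd = float(x.mean()), float(x.std(ddof=1))
    if sd == 0.0:
        return float(np.clip(mu, 0, 100)), float(np.clip(mu, 0, 100)), 1.0
    ks_p = float(stats.kstest(x, "norm", args=(mu, sd)).pvalue)
    alpha = 1.0 - level
    if ks_p >= 0.05:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        lo, hi = mu - z * sd, mu + z * sd
    else:
        lo, hi = np.percentile(x, [100 * alpha / 2.0, 100 * (1 - alpha / 2.0)])
    return float(np.clip(lo, 0, 100)), float(np.clip(hi, 0, 100)), ks_p
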