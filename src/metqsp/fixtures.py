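"""Ground-truth-known synthetic datasets for every calibration data class.

Each generator simulates the mechanistic model under a known ("truth")
parameterization and corrupts the output with multiplicative lognormal
noise (mean-one, so large-replicate averages converge on the noiseless
curve).  Fixtures replace digitized literature measurements: signaling
time courses, viability dose-responses, mouse tumor-growth-inhibition
curves, PDO panels, and clinical training waterfalls.  Every bundle
carries its truth record so consumer tests are parameter-recovery or
distribution-match assertions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import ObservationSet
from .network import (
    CloneParameters,
    DrugAction,
    LigandStimulus,
    build_network,
    equilibrate,
    readout,
    simulate_timecourse,
)
from .pdo import PDODataset, PatientModel, apply_potency, simulate_pdo_viability
from .tumor import (
    CELL_DENSITY_PER_MM3,
    ClonePopulation,
    TumorState,
    simulate_tumor,
    total_volume_series,
)

__all__ = [
    "FixtureBundle",
    "mouse_xenograft_params",
    "noise_factors",
    "gen_signaling",
    "gen_tgi",
    "gen_training_waterfall",
    "gen_pdo",
    "FixtureError",
]


class FixtureError(ValueError):
    pass


def mouse_xenograft_params(base: CloneParameters | None = None) -> CloneParameters:
    """Reference xenograft clone: proliferation-dominated growth.

    Xenograft lines grow with negligible spontaneous death relative to
    signaling-driven proliferation, so the untreated logistic plateau sits
    at the volume cap.
    """
    p = base or CloneParameters(clone_kind="ex14")
    return replace(p, kd_cell=2.0e-4)


def noise_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal factors with coefficient of variation cv."""
    if cv < 0:
        raise FixtureError("noise CV must be >= 0")
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, size)


@dataclass
class FixtureBundle:
    """Truth record plus generated tables, reproducible from its seed."""

    truth: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    cv: float = 0.0
    seed: int = 0

    def write(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "truth.json").write_text(json.dumps(self.truth, indent=2, default=float))
        for name, df in self.tables.items():
            df.to_csv(d / f"{name}.csv", index=False)


def gen_signaling(
    truth: CloneParameters,
    stimuli: Sequence[LigandStimulus],
    timepoints_h: np.ndarray,
    nodes: Sequence[str] = ("MET", "AKT", "ERK"),
    cv: float = 0.1,
    seed: int = 0,
) -> list[ObservationSet]:
    """Max-normalised noisy node time courses under ligand stimulation."""
    rng = np.random.default_rng(seed)
    timepoints_h = np.asarray(timepoints_h, dtype=float)
    net = build_network(truth)
    ss = equilibrate(net)
    traj = simulate_timecourse(net, ss, stimuli=stimuli,
                               horizon_h=float(timepoints_h[-1]),
                               t_eval=timepoints_h)
    cond = "+".join(f"{s.ligand}{s.concentration_ng_per_ml:g}" for s in stimuli) or "basal"
    out = []
    for node in nodes:
        series = readout(traj, net, node, "active_fraction").to_numpy()
        m = series.max()
        values = (series / m if m > 0 else series) * noise_factors(rng, cv, len(series))
        out.append(
            ObservationSet(
                observable=f"p{node}", condition=cond, x=timepoints_h,
                values=values, mode="to_max",
            )
        )
    return out


def gen_tgi(
    truth: CloneParameters,
    exposures: Mapping[str, object] | None,
    drugs: Sequence[DrugAction] = (),
    n_animals: int = 6,
    horizon_h: float = 24.0 * 60,
    n_timepoints: int = 13,
    start_volume_mm3: float = 100.0,
    cv: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-animal mouse TGI curves, volumes normalised to their start.

    One deterministic model curve per arm; animal-level noise is
    multiplicative on each measurement.
    """
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, horizon_h, n_timepoints)
    state = TumorState(
        [ClonePopulation(truth, start_volume_mm3 * CELL_DENSITY_PER_MM3, drugs=list(drugs))]
    )
    traj = simulate_tumor(state, exposures=exposures, horizon_h=horizon_h,
                          level="mouse", t_eval=grid, rtol=1e-6)
    v = total_volume_series(traj).to_numpy()
    rel = v / v[0]
    rows = []
    for animal in range(n_animals):
        noisy = rel * noise_factors(rng, cv, len(rel))
        noisy[0] = 1.0  # normalised to its own start by construction
        for t, val in zip(grid, noisy):
            rows.append({"time_h": t, "animal": animal, "relative_volume": val})
    return pd.DataFrame(rows)


def gen_training_waterfall(
    n: int,
    mixture: Sequence[tuple[float, float, float]],
    seed: int = 0,
) -> np.ndarray:
    """Best-change vector from a truncated-normal mixture over [-100, 100].

    ``mixture`` is a list of (weight, mean, sd); sd = 0 gives a point mass.
    """
    if n < 1:
        raise FixtureError("n must be >= 1")
    w = np.array([m[0] for m in mixture], dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise FixtureError("mixture weights must be nonnegative, not all zero")
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    comps = rng.choice(len(mixture), size=n, p=w)
    out = np.empty(n)
    for i, c in enumerate(comps):
        _, mu, sd = mixture[c]
        if sd == 0:
            out[i] = mu
        else:
            x = rng.normal(mu, sd)
            while not -100.0 <= x <= 100.0:
                x = rng.normal(mu, sd)
            out[i] = x
    return np.clip(out, -100.0, 100.0)


def gen_pdo(
    truth: PatientModel,
    drug_actions: Mapping[str, Sequence[DrugAction]],
    grid_uM: np.ndarray,
    cv: float = 0.1,
    seed: int = 0,
) -> PDODataset:
    """Noisy day-7 PDO viability panel generated from a known patient model."""
    rng = np.random.default_rng(seed)
    grid_uM = np.asarray(grid_uM, dtype=float)
    params = truth.clone_parameters()
    curves = {}
    for key, actions in drug_actions.items():
        acts = [apply_potency(a, truth.potency.get(a.drug, 1.0)) for a in actions]
        via = simulate_pdo_viability(params, acts, grid_uM)
        noisy = via * noise_factors(rng, cv, len(via))
        if grid_uM[0] == 0:
            noisy[0] = via[0]  # control well defines the normalisation
        curves[key] = (grid_uM, noisy)
    return PDODataset(patient_id=truth.patient_id, curves=curves)
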