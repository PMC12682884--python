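"""Clone-resolved tumor growth coupled to intracellular signaling.

Each clone carries its own signaling network; its per-capita growth rate is
a linear function of the clone's active AKT and ERK fractions, damped by a
shared logistic crowding term, minus death and any chemotherapy kill:

    g = (k0 + kt_akt_cell*fAKT + kt_erk_cell*fERK) * (1 - V/Vmax)
        - kd_cell - sum_chemo Emax*C^h / (EC50^h + C^h)

Cell counts map to volume through a fixed packing density and to an
equivalent spherical diameter, the quantity scored clinically.  Simulation
levels differ only in the carrying capacity: in vitro growth is effectively
unbounded over assay durations, mouse xenografts cap at 2000 mm^3, and the
patient-level cap is set far above trial-horizon burdens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import (
    CloneParameters,
    DrugAction,
    LigandStimulus,
    ReactionNetwork,
    build_network,
    equilibrate,
    _ligand_forcing,
    _drug_forcing,
)

__all__ = [
    "CELL_DENSITY_PER_MM3",
    "LEVEL_VMAX_MM3",
    "ClonePopulation",
    "TumorState",
    "GrowthCoupling",
    "per_capita_growth",
    "chemo_kill_rate",
    "simulate_tumor",
    "total_volume_series",
    "viability",
    "percent_diameter_change",
    "volume_to_diameter",
    "diameter_to_volume",
]

CELL_DENSITY_PER_MM3 = 1.0e6   # cells per mm^3 of tumor
LEVEL_VMAX_MM3 = {
    "in_vitro": 1.0e12,        # non-binding over assay durations
    "mouse": 2000.0,           # xenograft plateau
    "patient": 1.0e6,          # non-binding over trial horizons
}


def volume_to_diameter(v_mm3):
    """Equivalent spherical diameter (mm) of a volume (mm^3)."""
    return np.cbrt(6.0 * np.asarray(v_mm3, dtype=float) / np.pi)


def diameter_to_volume(d_mm):
    return np.pi * np.asarray(d_mm, dtype=float) ** 3 / 6.0


@dataclass
class GrowthCoupling:
    """Signaling-to-proliferation coupling for one clone."""

    k0: float = 0.002            # basal growth, 1/h
    kt_akt_cell: float = 0.012   # 1/h per unit active-AKT fraction
    kt_erk_cell: float = 0.008   # 1/h per unit active-ERK fraction
    kd_cell: float = 0.004       # death, 1/h

    def __post_init__(self) -> None:
        for n in ("k0", "kt_akt_cell", "kt_erk_cell", "kd_cell"):
            if getattr(self, n) < 0:
                raise ValueError(f"{n} must be >= 0")

    @classmethod
    def from_clone(cls, p: CloneParameters) -> "GrowthCoupling":
        return cls(p.k0_cell, p.kt_akt_cell, p.kt_erk_cell, p.kd_cell)


@dataclass
class ClonePopulation:
    """One clone inside the tumor: its parameters, drugs seen, and cell count."""

    params: CloneParameters
    n_cells: float
    drugs: Sequence[DrugAction] = ()
    coupling: GrowthCoupling | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("cell count must be >= 0")
        if self.coupling is None:
            self.coupling = GrowthCoupling.from_clone(self.params)


@dataclass
class TumorState:
    """Multi-clone tumor snapshot."""

    clones: list[ClonePopulation]
    vmax_mm3: float = LEVEL_VMAX_MM3["patient"]

    @property
    def total_cells(self) -> float:
        return float(sum(c.n_cells for c in self.clones))

    @property
    def volume_mm3(self) -> float:
        return self.total_cells / CELL_DENSITY_PER_MM3

    @property
    def diameter_mm(self) -> float:
        return float(volume_to_diameter(self.volume_mm3))


def chemo_kill_rate(drugs: Sequence[DrugAction], conc_nM: Mapping[str, float]) -> float:
    """Summed Hill kill terms of all chemo drugs at the given concentrations."""
    kill = 0.0
    for d in drugs:
        if d.mechanism != "chemo_cell_kill":
            continue
        c = float(conc_nM.get(d.drug, 0.0))
        if c > 0:
            kill += d.emax * c**d.hill / (d.ec50**d.hill + c**d.hill)
    return kill


def per_capita_growth(
    signaling: Mapping[str, float],
    coupling: GrowthCoupling,
    v_mm3: float,
    vmax_mm3: float,
    chemo_kill: float = 0.0,
) -> float:
    """Net per-capita growth rate (1/h) of a clone.

    ``signaling`` supplies the clone's active fractions ``fAKT`` and ``fERK``.
    """
    fakt, ferk = signaling.get("fAKT", 0.0), signaling.get("fERK", 0.0)
    crowd = max(0.0, 1.0 - v_mm3 / vmax_mm3)
    grow = (coupling.k0 + coupling.kt_akt_cell * fakt + coupling.kt_erk_cell * ferk)
    return grow * crowd - coupling.kd_cell - chemo_kill


class _CloneBlock:
    """Cached network + state slicing for one clone in the joint ODE."""

    def __init__(self, clone: ClonePopulation, offset: int):
        self.clone = clone
        self.net: ReactionNetwork = build_network(clone.params, clone.drugs)
        self.offset = offset
        n = self.net.n_species
        self.sl = slice(offset, offset + n)
        akt = self.net.groups["AKT"]
        erk = self.net.groups["ERK"]
        idx = self.net.index
        self.akt_idx = [idx(s) for s in akt]
        self.erk_idx = [idx(s) for s in erk]
        self.akt_act = [idx(s) for s in self.net.active_species["AKT"]]
        self.erk_act = [idx(s) for s in self.net.active_species["ERK"]]
        self.size = n

    def fractions(self, y_block: np.ndarray) -> dict[str, float]:
        def frac(act, grp):
            tot = float(y_block[grp].sum())
            return float(y_block[act].sum()) / tot if tot > 0 else 0.0

        return {
            "fAKT": frac(self.akt_act, self.akt_idx),
            "fERK": frac(self.erk_act, self.erk_idx),
        }


def simulate_tumor(
    initial: TumorState,
    exposures: Mapping[str, object] | None = None,
    stimuli: Sequence[LigandStimulus] = (),
    horizon_h: float = 24.0 * 90,
    level: str = "patient",
    t_eval: np.ndarray | None = None,
    initial_signaling: Sequence[Mapping[str, float]] | None = None,
    rtol: float = 1.0e-6,
) -> pd.DataFrame:
    """Integrate the coupled signaling + population system for every clone.

    Each clone's signaling species and its cell count evolve jointly; the
    logistic crowding term is shared through the total volume.  Signaling
    starts from each clone's drug-free steady state unless
    ``initial_signaling`` provides explicit states.  Returns a tidy table
    (time_h, clone, clone_kind, cells, volume_mm3 of the whole tumor,
    diameter_mm, fAKT, fERK).
    """
    if level not in LEVEL_VMAX_MM3:
        raise ValueError(f"level must be one of {sorted(LEVEL_VMAX_MM3)}")
    vmax = initial.vmax_mm3 if level == "patient" else LEVEL_VMAX_MM3[level]
    if level == "patient":
        vmax = initial.vmax_mm3
    clones = initial.clones
    if not clones:
        raise ValueError("tumor must contain at least one clone")

    blocks: list[_CloneBlock] = []
    off = 0
    for c in clones:
        b = _CloneBlock(c, off)
        blocks.append(b)
        off += b.size
    n_sig = off
    n_tot = n_sig + len(clones)

    y0 = np.zeros(n_tot)
    for i, b in enumerate(blocks):
        if initial_signaling is not None:
            sig0 = b.net.state_vector(initial_signaling[i])
        else:
            sig0 = b.net.state_vector(equilibrate(b.net))
        y0[b.sl] = sig0
        y0[n_sig + i] = clones[i].n_cells

    lig = [_ligand_forcing(b.net, stimuli) for b in blocks]
    drg = _drug_forcing(exposures)

    def rhs(t, y):
        dy = np.empty_like(y)
        conc = drg(t) if drg is not None else {}
        v = max(0.0, y[n_sig:].sum()) / CELL_DENSITY_PER_MM3
        for i, b in enumerate(blocks):
            yb = y[b.sl]
            dy[b.sl] = b.net.rhs(t, yb, lig[i], drg)
            kill = chemo_kill_rate(b.clone.drugs, conc)
            g = per_capita_growth(b.fractions(yb), b.clone.coupling, v, vmax, kill)
            dy[n_sig + i] = g * max(0.0, y[n_sig + i])
        return dy

    if t_eval is None:
        t_eval = np.linspace(0.0, horizon_h, 181)
    t_eval = np.asarray(t_eval, dtype=float)
    atol = np.full(n_tot, 1.0e-8)
    atol[:n_sig] = 1.0e-10 * np.maximum(np.abs(y0[:n_sig]), 1.0)
    atol[n_sig:] = 1.0e-6 * np.maximum(y0[n_sig:].max(), 1.0)
    sol = solve_ivp(rhs, (float(t_eval[0]), float(t_eval[-1])), y0,
                    method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"tumor simulation failed at t={sol.t[-1]:.3g} h: {sol.message}")

    rows = []
    counts = np.maximum(sol.y[n_sig:, :], 0.0)
    vol = counts.sum(axis=0) / CELL_DENSITY_PER_MM3
    dia = volume_to_diameter(vol)
    for i, b in enumerate(blocks):
        for j, t in enumerate(sol.t):
            fr = b.fractions(sol.y[b.sl, j])
            rows.append(
                {
                    "time_h": t,
                    "clone": i,
                    "clone_kind": clones[i].params.clone_kind,
                    "cells": counts[i, j],
                    "volume_mm3": vol[j],
                    "diameter_mm": dia[j],
                    "fAKT": fr["fAKT"],
                    "fERK": fr["fERK"],
                }
            )
    return pd.DataFrame(rows)


def total_volume_series(traj: pd.DataFrame) -> pd.Series:
    """Whole-tumor volume (mm^3) indexed by time, from a simulate_tumor table."""
    g = traj.groupby("time_h")["volume_mm3"].first()
    return g


def viability(
    treated: pd.DataFrame, control: pd.DataFrame, t_assay_h: float
) -> float:
    """Treated/control total cell count at the assay endpoint.

    Both trajectories must cover ``t_assay_h``; counts are interpolated onto
    it.  Mirrors normalisation of drug-treated growth to untreated growth
    over the same period.
    """

    def count_at(traj):
        g = traj.groupby("time_h")["cells"].sum()
        if t_assay_h > g.index.max() + 1e-9:
            raise ValueError("trajectory does not cover the assay endpoint")
        return float(np.interp(t_assay_h, g.index.to_numpy(), g.to_numpy()))

    c = count_at(control)
    if c <= 0:
        raise ZeroDivisionError("control cell count is zero at the assay endpoint")
    return count_at(treated) / c


def percent_diameter_change(traj: pd.DataFrame, baseline_v_mm3: float) -> pd.Series:
    """Percent diameter change vs baseline volume: 100*((V/V0)^(1/3) - 1)."""
    if baseline_v_mm3 <= 0:
        raise ValueError("baseline volume must be > 0")
    v = total_volume_series(traj)
    return 100.0 * (np.cbrt(v / baseline_v_mm3) - 1.0)
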