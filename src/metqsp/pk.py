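"""Compartmental pharmacokinetics: plasma and tumor drug exposure.

One- and two-compartment linear ODE models with oral first-order, IV bolus,
or zero-order infusion input, simulated dose-by-dose with a stiff solver.
Tumor exposure is proportional to plasma exposure through a calibrated
partition coefficient.  Reverse allometric scaling derives mouse parameters
from human ones (clearances by weight^0.75, volumes by weight^1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "PKParameters",
    "DoseRegimen",
    "ExposureTrace",
    "simulate_pk",
    "reverse_allometric",
    "tumor_exposure",
    "constant_exposure",
    "PKError",
    "DEFAULT_BSA_M2",
    "DEFAULT_WEIGHTS_KG",
]

DEFAULT_BSA_M2 = 1.8           # body surface area for mg/m2 dosing, virtual patients
DEFAULT_WEIGHTS_KG = {"human": 70.0, "mouse": 0.020}

SCHEDULE_INTERVALS_H = {"QD": 24.0, "BID": 12.0, "Q3W": 504.0}


class PKError(ValueError):
    """Invalid PK configuration."""


@dataclass
class PKParameters:
    """Linear compartmental PK parameters for one drug in one species."""

    n_compartments: int = 1
    route: str = "oral"            # oral | iv_bolus | iv_infusion
    ka: float = 1.0                # 1/h, oral absorption
    Vc: float = 50.0               # L (central)
    Vp: float = 50.0               # L (peripheral, 2-compartment only)
    CL: float = 10.0               # L/h
    Q: float = 5.0                 # L/h inter-compartmental
    F: float = 1.0                 # bioavailability
    species: str = "human"
    molecular_weight: float = 400.0  # g/mol
    kp_tumor: float = 1.0          # tumor:plasma partition coefficient
    infusion_duration_h: float = 1.0

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2):
            raise PKError("n_compartments must be 1 or 2")
        if self.route not in ("oral", "iv_bolus", "iv_infusion"):
            raise PKError(f"unknown route {self.route!r}")
        if self.species not in DEFAULT_WEIGHTS_KG:
            raise PKError(f"species must be one of {sorted(DEFAULT_WEIGHTS_KG)}")
        for name in ("ka", "Vc", "Vp", "CL", "Q", "F", "molecular_weight",
                     "kp_tumor", "infusion_duration_h"):
            if getattr(self, name) <= 0:
                raise PKError(f"{name} must be > 0")
        if self.F > 1.0:
            raise PKError("bioavailability F must be <= 1")

    @property
    def ke(self) -> float:
        """Elimination rate constant from the central compartment (1/h)."""
        return self.CL / self.Vc


@dataclass
class DoseRegimen:
    """A repeated dosing schedule.

    ``amount`` is in mg, or mg/m^2 when ``per_m2`` is set (converted with
    ``bsa_m2``), or mg/kg when ``per_kg`` is set (converted with the
    species' body weight).
    """

    amount: float
    schedule: str = "QD"           # QD | BID | Q3W | custom
    n_doses: int = 1
    start_h: float = 0.0
    interval_h: float | None = None  # required for schedule == "custom"
    per_m2: bool = False
    per_kg: bool = False
    bsa_m2: float | None = None

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise PKError("dose amount must be >= 0")
        if self.schedule not in SCHEDULE_INTERVALS_H and self.schedule != "custom":
            raise PKError(f"unknown schedule {self.schedule!r}")
        if self.schedule == "custom":
            if self.interval_h is None or self.interval_h <= 0:
                raise PKError("custom schedule requires interval_h > 0")
        if self.n_doses < 1:
            raise PKError("n_doses must be >= 1")
        if self.per_m2 and self.per_kg:
            raise PKError("dose cannot be both per m^2 and per kg")

    @property
    def interval(self) -> float:
        return (
            self.interval_h
            if self.schedule == "custom"
            else SCHEDULE_INTERVALS_H[self.schedule]
        )

    def dose_times(self, horizon_h: float) -> np.ndarray:
        t = self.start_h + self.interval * np.arange(self.n_doses)
        return t[t <= horizon_h]

    def dose_mg(self, params: PKParameters) -> float:
        if self.per_m2:
            bsa = self.bsa_m2 if self.bsa_m2 is not None else DEFAULT_BSA_M2
            if params.species != "human":
                raise PKError("mg/m^2 dosing requires human parameters")
            return self.amount * bsa
        if self.per_kg:
            return self.amount * DEFAULT_WEIGHTS_KG[params.species]
        return self.amount

    def scaled(self, fraction: float) -> "DoseRegimen":
        """Same schedule at ``fraction`` of the dose (dose-reduction scans)."""
        if fraction < 0:
            raise PKError("dose fraction must be >= 0")
        return replace(self, amount=self.amount * fraction)

    def repeated_for(self, horizon_h: float) -> "DoseRegimen":
        """Copy with enough doses to keep dosing through ``horizon_h``."""
        needed = int(np.floor((horizon_h - self.start_h) / self.interval)) + 1
        return replace(self, n_doses=max(self.n_doses, max(needed, 1)))


@dataclass
class ExposureTrace:
    """Time-resolved plasma and tumor concentration (nM) for one drug."""

    time_h: np.ndarray
    plasma_nM: np.ndarray
    tumor_nM: np.ndarray
    drug: str = ""

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.plasma_nM = np.asarray(self.plasma_nM, dtype=float)
        self.tumor_nM = np.asarray(self.tumor_nM, dtype=float)
        if not (self.time_h.shape == self.plasma_nM.shape == self.tumor_nM.shape):
            raise PKError("time/plasma/tumor grids must share one shape")
        if np.any(self.plasma_nM < -1e-9) or np.any(self.tumor_nM < -1e-9):
            raise PKError("concentrations must be nonnegative")

    def plasma_at(self, t) :
        return np.interp(t, self.time_h, self.plasma_nM, left=0.0, right=self.plasma_nM[-1])

    def tumor_at(self, t):
        return np.interp(t, self.time_h, self.tumor_nM, left=0.0, right=self.tumor_nM[-1])

    def auc_plasma(self) -> float:
        return float(np.trapezoid(self.plasma_nM, self.time_h))

    def auc_tumor(self) -> float:
        return float(np.trapezoid(self.tumor_nM, self.time_h))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.time_h, "plasma_nM": self.plasma_nM, "tumor_nM": self.tumor_nM}
        )

    def smoothed(self, window_h: float = 24.0) -> "ExposureTrace":
        """Moving-average exposure over ``window_h`` (trial-scale forcing).

        Within-day concentration swings equilibrate with receptor binding
        in hours while tumor burden responds over weeks, so long
        simulations may exchange the oscillating profile for its daily
        average without changing week-scale dynamics; this also removes
        the stiffness that repeated dose fronts impose on the solver.
        """
        if window_h <= 0:
            raise PKError("window must be > 0")
        if len(self.time_h) < 3:
            return self
        dt = np.min(np.diff(self.time_h))
        grid = np.arange(self.time_h[0], self.time_h[-1] + dt / 2, dt)
        k = max(1, int(round(window_h / dt)))
        kern = np.ones(k) / k
        # resample the averaged profile coarsely: fewer piecewise-linear
        # kinks lets an adaptive solver take long steps between them;
        # dense over the accumulation phase, one knot per window afterwards
        t0, t1 = grid[0], grid[-1]
        dense_end = min(t0 + 5.0 * window_h, t1)
        coarse = np.unique(
            np.concatenate(
                [
                    np.arange(t0, dense_end, window_h / 12.0),
                    np.arange(dense_end, t1, window_h),
                    [t1],
                ]
            )
        )
        out = []
        for ch in (self.plasma_nM, self.tumor_nM):
            y = np.interp(grid, self.time_h, ch)
            pad = np.concatenate([np.full(k - 1, y[0]), y])
            avg = np.convolve(pad, kern, mode="valid")
            out.append(np.interp(coarse, grid, avg))
        return ExposureTrace(coarse, out[0], out[1], drug=self.drug)


def _single_dose_amounts(params: PKParameters, dose_mg: float,
                         t: np.ndarray) -> np.ndarray:
    """Central-compartment amount (mg) after one dose at t=0, by ODE integration."""
    p = params
    ke = p.CL / p.Vc
    if p.n_compartments == 1:
        k12 = k21 = 0.0
    else:
        k12, k21 = p.Q / p.Vc, p.Q / p.Vp

    infusing = p.route == "iv_infusion"
    rate_in = dose_mg / p.infusion_duration_h if infusing else 0.0

    def rhs(tt, y):
        depot, c, per = y
        inp = p.ka * depot
        if infusing and tt < p.infusion_duration_h:
            inp += rate_in
        return [
            -p.ka * depot,
            inp - (ke + k12) * c + k21 * per,
            k12 * c - k21 * per,
        ]

    if p.route == "oral":
        y0 = [dose_mg * p.F, 0.0, 0.0]
    elif p.route == "iv_bolus":
        y0 = [0.0, dose_mg, 0.0]
    else:
        y0 = [0.0, 0.0, 0.0]

    tmax = float(t[-1]) if len(t) else 0.0
    if tmax == 0.0:
        return np.zeros_like(t)
    sol = solve_ivp(
        rhs, (0.0, tmax), y0, method="LSODA", t_eval=t,
        rtol=1e-10, atol=1e-12 * max(dose_mg, 1.0),
        max_step=p.infusion_duration_h if infusing else np.inf,
    )
    if not sol.success:
        raise PKError(f"PK integration failed: {sol.message}")
    return sol.y[1]


def simulate_pk(
    params: PKParameters,
    regimen: DoseRegimen,
    horizon_h: float,
    drug: str = "",
    n_points: int | None = None,
) -> ExposureTrace:
    """Simulate plasma (and tumor) concentration under a dosing regimen.

    Linear kinetics: the multiple-dose profile is the superposition of
    single-dose profiles, each obtained by ODE integration.
    """
    if horizon_h <= 0:
        raise PKError("horizon must be > 0")
    if n_points is None:
        n_points = max(200, int(horizon_h * 4))
    t = np.linspace(0.0, horizon_h, n_points)
    dose_mg = regimen.dose_mg(params)
    plasma_mg = np.zeros_like(t)
    if dose_mg > 0:
        times = regimen.dose_times(horizon_h)
        # identical doses: integrate one post-dose profile, evaluated at the
        # union of all shifted sample times (exact superposition, no
        # interpolation error)
        masks = [t >= t0 for t0 in times]
        shifted = np.concatenate(
            [t[m] - t0 for t0, m in zip(times, masks)]
        )
        uniq, inv = np.unique(shifted, return_inverse=True)
        if uniq.size <= 200_000:
            base = _single_dose_amounts(params, dose_mg, uniq)
            pos = 0
            for m in masks:
                k = int(m.sum())
                plasma_mg[m] += base[inv[pos:pos + k]]
                pos += k
        else:
            # long many-dose schedules: dense-grid profile + interpolation
            base_t = np.linspace(0.0, horizon_h, 200_001)
            base = _single_dose_amounts(params, dose_mg, base_t)
            for t0, m in zip(times, masks):
                plasma_mg[m] += np.interp(t[m] - t0, base_t, base)
    conc_nM = plasma_mg / params.Vc / params.molecular_weight * 1.0e6  # mg/L -> nM
    return ExposureTrace(t, conc_nM, params.kp_tumor * conc_nM, drug=drug)


def tumor_exposure(trace: ExposureTrace, kp_tumor: float) -> ExposureTrace:
    """Re-derive the tumor channel as ``kp_tumor`` times plasma, elementwise."""
    if kp_tumor <= 0:
        raise PKError("kp_tumor must be > 0")
    return ExposureTrace(trace.time_h, trace.plasma_nM, kp_tumor * trace.plasma_nM,
                         drug=trace.drug)


def constant_exposure(drug: str, conc_nM: float, horizon_h: float) -> ExposureTrace:
    """Flat exposure for in vitro assays (drug held constant in medium)."""
    if conc_nM < 0 or horizon_h <= 0:
        raise PKError("need conc >= 0 and horizon > 0")
    t = np.array([0.0, horizon_h])
    c = np.full(2, float(conc_nM))
    return ExposureTrace(t, c, c, drug=drug)


def reverse_allometric(
    human: PKParameters,
    weight_kg_from: float | None = None,
    weight_kg_to: float | None = None,
    clearance_exponent: float = 0.75,
    volume_exponent: float = 1.0,
) -> PKParameters:
    """Scale human PK parameters down to mouse (reverse allometry).

    Clearances (CL, Q) scale with (W_mouse/W_human)^0.75 and volumes
    (Vc, Vp) with exponent 1.0 by default; ka and F are species-invariant.
    """
    w_h = DEFAULT_WEIGHTS_KG["human"] if weight_kg_from is None else weight_kg_from
    w_m = DEFAULT_WEIGHTS_KG["mouse"] if weight_kg_to is None else weight_kg_to
    if w_h <= 0 or w_m <= 0:
        raise PKError("body weights must be > 0")
    ratio = w_m / w_h
    return replace(
        human,
        CL=human.CL * ratio**clearance_exponent,
        Q=human.Q * ratio**clearance_exponent,
        Vc=human.Vc * ratio**volume_exponent,
        Vp=human.Vp * ratio**volume_exponent,
        species="mouse" if ratio < 1 else "human",
    )
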