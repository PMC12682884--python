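"""Observation normalisation, model-data scoring, and direct-search fitting.

Observables are compared on the same scale the source experiments report:
time courses normalised to their maximum, treated conditions normalised to
control, or raw.  The objective is a weighted sum of squared residuals on
the normalised scale, with model output linearly interpolated onto each
observation grid.  Fitting uses a generalized pattern search (direct
search with mesh halving) so that stiff-ODE objectives need no gradients;
rate constants are searched on a log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ObservationSet",
    "FitSpec",
    "FitResult",
    "normalize",
    "objective",
    "fit_direct_search",
    "CalibrationError",
]


class CalibrationError(ValueError):
    pass


@dataclass
class ObservationSet:
    """One experimental series: an observable under one condition.

    ``x`` is a time (h) or concentration grid, strictly increasing.
    ``mode`` controls normalisation: ``to_max``, ``to_control`` (requires
    ``control_index``), or ``raw``.
    """

    observable: str
    condition: str
    x: np.ndarray
    values: np.ndarray
    mode: str = "raw"
    control_index: int = 0
    weight: float | None = None   # default 1/n points

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.values.shape:
            raise CalibrationError("x and values must be matching 1-D arrays")
        if np.any(np.diff(self.x) <= 0):
            raise CalibrationError(f"{self.observable}/{self.condition}: grid must be strictly increasing")
        if self.mode not in ("to_max", "to_control", "raw"):
            raise CalibrationError(f"unknown normalisation mode {self.mode!r}")

    @property
    def effective_weight(self) -> float:
        return self.weight if self.weight is not None else 1.0 / len(self.x)

    def normalized(self) -> np.ndarray:
        if self.mode == "raw":
            return self.values
        return normalize(self.values, self.mode, control_index=self.control_index)


def normalize(series, mode: str, control_index: int = 0, control: float | None = None):
    """Normalise a series to its maximum or to a control value.

    ``to_max`` divides by the series maximum (must be > 0); ``to_control``
    divides by ``control`` if given, else by the value at ``control_index``.
    """
    s = np.asarray(series, dtype=float)
    if mode == "raw":
        return s.copy()
    if mode == "to_max":
        m = s.max()
        if m <= 0:
            raise CalibrationError("to_max normalisation needs a positive maximum")
        return s / m
    if mode == "to_control":
        c = control if control is not None else s[control_index]
        if c <= 0:
            raise CalibrationError("to_control normalisation needs a positive control")
        return s / c
    raise CalibrationError(f"unknown normalisation mode {mode!r}")


def objective(
    model_outputs: Mapping[tuple[str, str], tuple[np.ndarray, np.ndarray]],
    observations: Sequence[ObservationSet],
    weights: Mapping[tuple[str, str], float] | None = None,
) -> float:
    """Weighted SSE between normalised model output and normalised data.

    ``model_outputs`` maps (observable, condition) -> (x_model, y_model);
    model series are normalised with the observation's own mode and
    interpolated onto the observation grid.
    """
    total = 0.0
    for obs in observations:
        key = (obs.observable, obs.condition)
        if key not in model_outputs:
            raise CalibrationError(f"missing model output for {key}")
        xm, ym = model_outputs[key]
        xm = np.asarray(xm, dtype=float)
        ym = np.asarray(ym, dtype=float)
        if obs.x[0] < xm[0] - 1e-9 or obs.x[-1] > xm[-1] + 1e-9:
            raise CalibrationError(
                f"model grid does not cover data grid for {key}: "
                f"[{xm[0]}, {xm[-1]}] vs [{obs.x[0]}, {obs.x[-1]}]"
            )
        ym_n = normalize(ym, obs.mode, control_index=int(np.argmin(np.abs(xm - obs.x[obs.control_index]))))
        yi = np.interp(obs.x, xm, ym_n)
        w = obs.effective_weight if weights is None else weights.get(key, obs.effective_weight)
        total += w * float(np.sum((yi - obs.normalized()) ** 2))
    return total


@dataclass
class FitSpec:
    """Free parameters (with box bounds), initial point, and search settings."""

    names: list[str]
    lower: np.ndarray
    upper: np.ndarray
    initial: np.ndarray
    log_scale: Sequence[bool] | bool = True
    max_evaluations: int = 2000
    initial_mesh: float = 0.25          # fraction of (transformed) box width
    min_mesh: float = 1.0e-6
    seed: int = 0

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        n = len(self.names)
        if not (self.lower.shape == self.upper.shape == self.initial.shape == (n,)):
            raise CalibrationError("names, bounds and initial must share length")
        if not np.all(np.isfinite(self.lower) & np.isfinite(self.upper)):
            raise CalibrationError("bounds must be finite")
        if np.any(self.lower >= self.upper):
            raise CalibrationError("need lower < upper for every parameter")
        if np.any((self.initial < self.lower) | (self.initial > self.upper)):
            raise CalibrationError("initial point must lie inside the box")
        if isinstance(self.log_scale, bool):
            self.log_scale = [self.log_scale] * n
        if any(self.log_scale) and np.any(self.lower[np.asarray(self.log_scale)] <= 0):
            raise CalibrationError("log-scale parameters need positive lower bounds")


@dataclass
class FitResult:
    parameters: dict[str, float]
    objective_value: float
    n_evaluations: int
    converged: bool
    improved: bool
    trace: list[float] = field(default_factory=list)
    message: str = ""


def fit_direct_search(
    spec: FitSpec, fun: Callable[[Mapping[str, float]], float]
) -> FitResult:
    """Generalized pattern search over the box in ``spec``.

    Coordinate poll (+/- each unit direction) on a normalised [0,1]^n
    domain (log-transformed where requested); the mesh doubles after a
    successful poll (capped at the initial mesh) and halves after an
    unsuccessful one, terminating at ``min_mesh`` or the evaluation budget.
    Deterministic given the spec (the seed only shuffles poll order).
    """
    rng = np.random.default_rng(spec.seed)
    logm = np.asarray(spec.log_scale, dtype=bool)
    with np.errstate(divide="ignore"):
        lo = np.where(logm, np.log(np.maximum(spec.lower, 1e-300)), spec.lower)
        hi = np.where(logm, np.log(np.maximum(spec.upper, 1e-300)), spec.upper)
    width = hi - lo

    def to_params(u: np.ndarray) -> dict[str, float]:
        z = lo + u * width
        x = np.where(logm, np.exp(z), z)
        return dict(zip(spec.names, x))

    def evaluate(u: np.ndarray) -> float:
        return float(fun(to_params(u)))

    u = (np.where(logm, np.log(spec.initial), spec.initial) - lo) / width
    n = len(spec.names)
    f = evaluate(u)
    f_init = f
    n_eval = 1
    trace = [f]
    mesh = spec.initial_mesh
    converged = False
    while n_eval < spec.max_evaluations:
        improved_here = False
        dirs = [(i, s) for i in range(n) for s in (+1.0, -1.0)]
        rng.shuffle(dirs)
        for i, s in dirs:
            if n_eval >= spec.max_evaluations:
                break
            cand = u.copy()
            cand[i] = min(1.0, max(0.0, cand[i] + s * mesh))
            if cand[i] == u[i]:
                continue
            fc = evaluate(cand)
            n_eval += 1
            if fc < f:
                u, f = cand, fc
                trace.append(f)
                improved_here = True
                break
        if improved_here:
            mesh = min(mesh * 2.0, spec.initial_mesh)
        else:
            mesh *= 0.5
            if mesh < spec.min_mesh:
                converged = True
                break
    improved = f < f_init
    msg = "converged to minimum mesh" if converged else "evaluation budget exhausted"
    if not improved:
        msg += "; no improvement over the initial point"
    return FitResult(
        parameters=to_params(u),
        objective_value=f,
        n_evaluations=n_eval,
        converged=converged,
        improved=improved,
        trace=trace,
        message=msg,
    )
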