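"""Global sensitivity analysis: Latin hypercube sampling + PRCC.

Parameters are sampled log-uniformly within multiplicative ranges (default
one-third to three times baseline) with one draw per equiprobable stratum
per parameter.  Partial rank correlation coefficients are computed from the
precision matrix of the rank-transformed design joined with the output;
p-values use the t approximation with n - p - 2 degrees of freedom.
Significance calls are Bonferroni-corrected across parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .network import CloneParameters
from .tumor import (
    CELL_DENSITY_PER_MM3,
    ClonePopulation,
    TumorState,
    simulate_tumor,
    total_volume_series,
)

__all__ = [
    "SamplingDesign",
    "PRCCResult",
    "lhs_sample",
    "prcc",
    "run_paper_scenarios",
    "day90_untreated_volume",
    "day90_treated_diameter_change",
    "SensitivityError",
]


class SensitivityError(ValueError):
    pass


@dataclass
class SamplingDesign:
    """LHS design over multiplicative parameter ranges."""

    names: list[str]
    baselines: np.ndarray
    low_factor: float = 1.0 / 3.0
    high_factor: float = 3.0
    n: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        self.baselines = np.asarray(self.baselines, dtype=float)
        if len(self.names) != len(self.baselines):
            raise SensitivityError("names and baselines must match")
        if np.any(self.baselines <= 0):
            raise SensitivityError("baselines must be > 0 for multiplicative ranges")
        if not 0 < self.low_factor < self.high_factor:
            raise SensitivityError("need 0 < low_factor < high_factor")
        if self.n < len(self.names) + 2:
            raise SensitivityError("n must be at least n_parameters + 2")


def lhs_sample(design: SamplingDesign) -> np.ndarray:
    """(n x p) parameter matrix; log-uniform marginals, one point per stratum."""
    sampler = qmc.LatinHypercube(d=len(design.names), seed=design.seed)
    u = sampler.random(design.n)
    lo = np.log(design.baselines * design.low_factor)
    hi = np.log(design.baselines * design.high_factor)
    return np.exp(lo + u * (hi - lo))


@dataclass
class PRCCResult:
    output_label: str
    table: pd.DataFrame  # parameter, prcc, p_value, significant

    def coefficient(self, name: str) -> float:
        row = self.table.loc[self.table["parameter"] == name]
        if row.empty:
            raise SensitivityError(f"unknown parameter {name!r}")
        return float(row["prcc"].iloc[0])

    def significant_parameters(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "parameter"])


def prcc(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    output_label: str = "output",
    alpha: float = 0.05,
) -> PRCCResult:
    """Partial rank correlation of each column of ``X`` with ``y``.

    Ranks replace values; the partial correlation between parameter i and
    the output, controlling for every other parameter, comes from the
    precision matrix of the joint rank-correlation matrix.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise SensitivityError("X must be (n x p) with len(y) == n")
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    const = [names[j] for j in range(p) if np.ptp(X[:, j]) == 0]
    if np.ptp(y) == 0:
        raise SensitivityError("output vector is constant")
    if const:
        raise SensitivityError(f"constant columns: {const}")

    R = np.column_stack([stats.rankdata(X[:, j]) for j in range(p)])
    ry = stats.rankdata(y)
    M = np.column_stack([R, ry])
    C = np.corrcoef(M, rowvar=False)
    try:
        P = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        corr = np.abs(C[:p, :p] - np.eye(p))
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        raise SensitivityError(
            f"singular rank design; most collinear columns: {names[i]}, {names[j]}"
        )
    coefs = np.array([-P[j, p] / np.sqrt(P[j, j] * P[p, p]) for j in range(p)])
    dof = n - p - 2
    if dof <= 0:
        raise SensitivityError("not enough samples for the t approximation")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coefs * np.sqrt(dof / np.maximum(1.0 - coefs**2, 1e-300))
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    table = pd.DataFrame(
        {
            "parameter": list(names),
            "prcc": coefs,
            "p_value": pvals,
            "significant": pvals < alpha / p,  # Bonferroni across parameters
        }
    )
    return PRCCResult(output_label=output_label, table=table)


def prcc_bruteforce(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Explicit rank-residualization PRCC (independent cross-check route).

    For each parameter, regress its ranks and the output's ranks on all
    other parameters' ranks (with intercept) and correlate the residuals.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    R = np.column_stack([stats.rankdata(X[:, j]) for j in range(p)])
    ry = stats.rankdata(y)
    out = np.empty(p)
    for j in range(p):
        others = np.column_stack([np.ones(n), np.delete(R, j, axis=1)])
        beta_x, *_ = np.linalg.lstsq(others, R[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(others, ry, rcond=None)
        rx = R[:, j] - others @ beta_x
        rr = ry - others @ beta_y
        out[j] = np.corrcoef(rx, rr)[0, 1]
    return out


# ---------------------------------------------------------------------------
# Scenario drivers: day-90 preclinical outputs


def day90_untreated_volume(
    params: CloneParameters, initial_volume_mm3: float = 100.0
) -> float:
    """Tumor volume (mm^3) on day 90 of untreated mouse-level growth."""
    state = TumorState(
        [ClonePopulation(params, initial_volume_mm3 * CELL_DENSITY_PER_MM3)]
    )
    traj = simulate_tumor(state, horizon_h=90 * 24.0, level="mouse",
                          t_eval=np.array([0.0, 90 * 24.0]), rtol=1e-6)
    return float(total_volume_series(traj).iloc[-1])


def day90_treated_diameter_change(
    params: CloneParameters,
    drug_actions: Sequence,
    exposures: Mapping[str, object],
    initial_volume_mm3: float = 100.0,
) -> float:
    """Percent diameter change on day 90 under treatment (mouse level)."""
    state = TumorState(
        [ClonePopulation(params, initial_volume_mm3 * CELL_DENSITY_PER_MM3, drugs=list(drug_actions))]
    )
    traj = simulate_tumor(state, exposures=exposures, horizon_h=90 * 24.0,
                          level="mouse", t_eval=np.array([0.0, 90 * 24.0]), rtol=1e-6)
    v = total_volume_series(traj)
    return float(100.0 * (np.cbrt(v.iloc[-1] / v.iloc[0]) - 1.0))


def run_paper_scenarios(
    base_params: CloneParameters,
    parameter_names: Sequence[str],
    capmatinib_actions: Sequence,
    capmatinib_exposure: Mapping[str, object],
    n: int = 5000,
    seed: int = 0,
    low_factor: float = 1.0 / 3.0,
    high_factor: float = 3.0,
) -> tuple[PRCCResult, PRCCResult]:
    """PRCC of day-90 untreated volume and day-90 treated diameter change.

    Varied parameters are fields of the clone's parameter set; each LHS row
    replaces those fields and re-simulates both scenarios.  Failed
    simulations are dropped with a count in the output labels.
    """
    from dataclasses import replace

    baselines = np.array([getattr(base_params, n_) for n_ in parameter_names])
    design = SamplingDesign(list(parameter_names), baselines, low_factor,
                            high_factor, n=n, seed=seed)
    X = lhs_sample(design)
    y_untreated = np.empty(n)
    y_treated = np.empty(n)
    ok = np.ones(n, dtype=bool)
    for i in range(n):
        try:
            p_i = replace(base_params, **dict(zip(parameter_names, X[i])))
            y_untreated[i] = day90_untreated_volume(p_i)
            y_treated[i] = day90_treated_diameter_change(
                p_i, capmatinib_actions, capmatinib_exposure
            )
        except Exception:
            ok[i] = False
    n_fail = int((~ok).sum())
    res_u = prcc(X[ok], y_untreated[ok], parameter_names,
                 output_label=f"day90_untreated_volume (n={ok.sum()}, failed={n_fail})")
    res_t = prcc(X[ok], y_treated[ok], parameter_names,
                 output_label=f"day90_capmatinib_diameter_change (n={ok.sum()}, failed={n_fail})")
    return res_u, res_t
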