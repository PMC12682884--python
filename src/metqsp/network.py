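"""Intracellular receptor-signaling ODE network for a single cancer-cell clone.

The network covers the four receptor tyrosine kinase pathways implicated in
MET-aberrant NSCLC (MET, EGFR, ALK, ROS1) and their convergence onto the two
proliferative cascades PI3K->AKT and RAS->MEK->ERK.  Reactions follow mass
action kinetics; small-molecule kinase inhibitors act through Hill-type rate
multipliers, while MET TKIs bind the receptor mechanistically (association /
dissociation with the ATP pocket of un-phosphorylated, ligand-free MET).

Three MET pools are carried so that the canonical aberrations are structural,
not parametric re-labels:

``MET``    wild-type receptor; phosphorylated forms recruit Cbl and are
           degraded at an enhanced rate (ubiquitin route).
``MET14``  exon-14-skipping receptor; the Cbl docking site is lost, so the
           enhanced-degradation channel is absent and the basal degradation
           rate is lower than wild type.
``METoe``  the surplus pool expressed under gene amplification, synthesised
           at ``(amplification_factor - 1) * kt_MET`` with its own
           degradation rate ``kd_oe_MET`` and its own TKI on-rate.

Ligand-independent MET auto-activation is second order in free receptor
(dimerisation-like), so amplification raises basal phospho-MET
superlinearly.  Ligands (HGF, EGF) are external forcing concentrations in
nM, not depleted state variables.  Units: copies/cell for intracellular
species, nM for ligands and drugs, hours for time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CloneParameters",
    "DrugAction",
    "LigandStimulus",
    "ReactionNetwork",
    "build_network",
    "equilibrate",
    "simulate_timecourse",
    "readout",
    "ligand_ng_per_ml_to_nM",
    "LIGAND_MW_DA",
    "NetworkError",
    "EquilibrationError",
]

# Fixed molecular weights used for the ng/mL -> nM ligand conversion.
LIGAND_MW_DA = {"HGF": 83_000.0, "EGF": 6_200.0}

CLONE_KINDS = ("wild_type", "ex14", "amplified")
DRUG_MECHANISMS = ("met_tki_binding", "kinase_hill_inhibition", "chemo_cell_kill")
HILL_TARGETS = ("MET", "EGFR", "ALK", "ROS1", "PI3K", "AKT", "MEK", "ERK")


class NetworkError(ValueError):
    """Invalid network construction input."""


class EquilibrationError(RuntimeError):
    """Steady state not reached within the allowed horizon."""


def ligand_ng_per_ml_to_nM(ligand: str, conc_ng_per_ml: float) -> float:
    """Convert a ligand concentration from ng/mL to nM via its molecular weight."""
    try:
        mw = LIGAND_MW_DA[ligand]
    except KeyError:
        raise NetworkError(f"unknown ligand {ligand!r}; known: {sorted(LIGAND_MW_DA)}")
    return conc_ng_per_ml * 1.0e3 / mw


@dataclass
class CloneParameters:
    """Rate constants and abundances for one cancer-cell clone.

    Rates are first order in h^-1 unless noted; synthesis rates are
    copies/cell/h; bimolecular on-rates are nM^-1 h^-1 (ligands/drugs) or
    (copies/cell)^-1 h^-1 (receptor dimerisation, cascade coupling).
    """

    clone_kind: str = "wild_type"

    # --- MET pools -------------------------------------------------------
    kt_MET: float = 1359.0
    kd_MET: float = 0.1
    kt_14_MET: float = 1359.0
    kd_14_MET: float = 0.0333          # ex14 degrades slower than wild type
    kd_oe_MET: float = 0.1             # amplified surplus pool
    kp_MET: float = 10.0               # ligand-driven phosphorylation
    kp_14_MET: float = 10.0
    kdp_MET: float = 2.0
    kdp_14_MET: float = 2.0
    k_auto_MET: float = 1.0e-6         # second-order ligand-free auto-activation
    cbl_degradation_factor: float = 10.0  # phospho-MET (wild-type/oe) Cbl route
    kon_HGF: float = 1.0
    koff_HGF: float = 0.5
    amplification_factor: float = 1.0  # >= 1; surplus synthesis (amp-1)*kt_MET

    # --- EGFR ------------------------------------------------------------
    kt_EGFR: float = 15883.4
    kd_EGFR: float = 0.1
    kp_EGFR: float = 10.0
    kdp_EGFR: float = 2.0
    kd_pEGFR_factor: float = 5.0       # internalisation of active EGFR
    kon_EGF: float = 1.0
    koff_EGF: float = 0.3

    # --- ALK / ROS1 (constitutive activation behind clone flags) ---------
    kt_ALK: float = 500.0
    kd_ALK: float = 0.05
    kp_ALK: float = 2.0                # first order, only if alk_mutant
    kdp_ALK: float = 2.0
    alk_mutant: bool = False
    kt_ROS1: float = 500.0
    kd_ROS1: float = 0.05
    kp_ROS1: float = 2.0               # first order, only if ros1_rearranged
    kdp_ROS1: float = 2.0
    ros1_rearranged: bool = False

    # --- downstream cascades (conserved totals) ---------------------------
    PI3K_total: float = 1.0e4
    AKT_total: float = 1.0e4
    RAS_total: float = 1.0e4
    MEK_total: float = 1.0e4
    ERK_total: float = 1.0e4
    kact_PI3K: float = 5.0e-4          # per active-receptor copy per h
    kdeact_PI3K: float = 1.0
    kact_AKT: float = 5.0e-4           # per active-PI3K copy per h
    kdeact_AKT: float = 1.0
    kact_RAS: float = 5.0e-4           # per active-receptor copy per h
    kdeact_RAS: float = 1.0
    kact_MEK: float = 5.0e-4           # per active-RAS copy per h
    kdeact_MEK: float = 1.0
    kact_ERK: float = 1.0e-4           # per active-MEK copy per h
    kdeact_ERK: float = 1.0

    # receptor -> cascade crosstalk weights (dimensionless, default 1)
    receptor_weights: dict = field(
        default_factory=lambda: {"MET": 1.0, "EGFR": 1.0, "ALK": 1.0, "ROS1": 1.0}
    )

    # --- growth coupling (consumed by the tumor module) -------------------
    k0_cell: float = 0.002
    kt_akt_cell: float = 0.012
    kt_erk_cell: float = 0.008
    kd_cell: float = 0.004

    def __post_init__(self) -> None:
        if self.clone_kind not in CLONE_KINDS:
            raise NetworkError(
                f"clone_kind must be one of {CLONE_KINDS}, got {self.clone_kind!r}"
            )
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                raise NetworkError(f"rate/abundance {f.name} must be >= 0, got {v}")
        if not self.kd_14_MET < self.kd_MET:
            raise NetworkError(
                "kd_14_MET must be < kd_MET: exon-14-skipped MET degrades slower "
                f"(got kd_14_MET={self.kd_14_MET}, kd_MET={self.kd_MET})"
            )
        if self.amplification_factor < 1.0:
            raise NetworkError("amplification_factor must be >= 1")

    def with_overrides(self, multipliers: Mapping[str, float]) -> "CloneParameters":
        """Return a copy with named parameters multiplied (virtual-patient use)."""
        changes = {}
        for name, m in multipliers.items():
            if not hasattr(self, name):
                raise NetworkError(f"unknown parameter {name!r}")
            if m < 0:
                raise NetworkError(f"multiplier for {name!r} must be >= 0")
            changes[name] = getattr(self, name) * m
        return replace(self, **changes)


@dataclass
class DrugAction:
    """Mechanism of action of one drug on the signaling/growth model.

    ``met_tki_binding``       mechanistic association/dissociation with free,
                              un-phosphorylated MET; ``kon`` targets the
                              wild-type/ex14 pools and ``kon_oe`` the
                              amplified surplus pool (both nM^-1 h^-1).
    ``kinase_hill_inhibition`` multiplies the target kinase's activation rate
                              by 1/(1 + (C/IC50)^h).
    ``chemo_cell_kill``       adds Emax*C^h/(EC50^h + C^h) to the cell death
                              rate (handled by the tumor module).
    """

    drug: str
    mechanism: str
    kon: float | None = None
    kon_oe: float | None = None
    koff: float | None = None
    target: str | None = None
    ic50: float | None = None
    hill: float = 1.0
    emax: float | None = None
    ec50: float | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in DRUG_MECHANISMS:
            raise NetworkError(
                f"unknown drug mechanism {self.mechanism!r} for {self.drug!r}; "
                f"must be one of {DRUG_MECHANISMS}"
            )
        if self.mechanism == "met_tki_binding":
            self._require_positive("kon", "kon_oe", "koff")
        elif self.mechanism == "kinase_hill_inhibition":
            if self.target not in HILL_TARGETS:
                raise NetworkError(
                    f"{self.drug}: hill-inhibition target must be in {HILL_TARGETS}"
                )
            self._require_positive("ic50", "hill")
        else:  # chemo_cell_kill
            self._require_positive("emax", "ec50", "hill")

    def _require_positive(self, *names: str) -> None:
        for n in names:
            v = getattr(self, n)
            if v is None or v <= 0:
                raise NetworkError(
                    f"{self.drug} ({self.mechanism}): constant {n!r} must be > 0, got {v}"
                )


@dataclass
class LigandStimulus:
    """A step input of growth-factor ligand, held constant after onset."""

    ligand: str
    concentration_ng_per_ml: float
    onset_h: float = 0.0

    def __post_init__(self) -> None:
        if self.ligand not in LIGAND_MW_DA:
            raise NetworkError(f"unknown ligand {self.ligand!r}")
        if self.concentration_ng_per_ml < 0:
            raise NetworkError("ligand concentration must be >= 0")

    @property
    def concentration_nM(self) -> float:
        return ligand_ng_per_ml_to_nM(self.ligand, self.concentration_ng_per_ml)


# ---------------------------------------------------------------------------
# Reaction bookkeeping


@dataclass
class _Reaction:
    name: str
    rate: float
    reactants: tuple[str, ...]      # species whose amounts multiply the rate
    products: tuple[str, ...]
    consumed: tuple[str, ...]       # subset of reactants actually consumed
    ligand: str | None = None       # rate *= ligand concentration (nM)
    drug: str | None = None         # rate *= drug concentration (nM)
    hill_tag: str | None = None     # rate *= product of Hill factors on tag
    factor: str | None = None       # rate *= named linear combination of y


class ReactionNetwork:
    """One clone's signaling system, compiled to vectorised ODE arrays."""

    def __init__(
        self,
        params: CloneParameters,
        drugs: Sequence[DrugAction],
        species: list[str],
        reactions: list[_Reaction],
        factors: dict[str, np.ndarray],
        groups: dict[str, list[str]],
    ):
        self.params = params
        self.drugs = list(drugs)
        self.species = species
        self.reactions = reactions
        self.groups = groups  # node -> member species (for readouts/conservation)
        self._index = {s: i for i, s in enumerate(species)}
        self._compile(factors)

    # -- compilation -------------------------------------------------------

    def _compile(self, factors: dict[str, np.ndarray]) -> None:
        n_s, n_r = len(self.species), len(self.reactions)
        self.stoich = np.zeros((n_s, n_r))
        self.k = np.empty(n_r)
        self._r1 = np.full(n_r, -1, dtype=int)
        self._r2 = np.full(n_r, -1, dtype=int)
        factor_names = sorted(factors)
        self._factor_matrix = (
            np.vstack([factors[n] for n in factor_names])
            if factor_names
            else np.zeros((0, n_s))
        )
        self._factor_idx = np.full(n_r, -1, dtype=int)
        self._ligand_names = sorted({r.ligand for r in self.reactions if r.ligand})
        self._drug_names = sorted({r.drug for r in self.reactions if r.drug})
        self._hill_tags = sorted({r.hill_tag for r in self.reactions if r.hill_tag})
        self._ligand_idx = np.full(n_r, -1, dtype=int)
        self._drug_idx = np.full(n_r, -1, dtype=int)
        self._tag_idx = np.full(n_r, -1, dtype=int)

        for j, r in enumerate(self.reactions):
            self.k[j] = r.rate
            if len(r.reactants) > 2:
                raise NetworkError(f"reaction {r.name}: at most bimolecular")
            if r.reactants:
                self._r1[j] = self._index[r.reactants[0]]
            if len(r.reactants) == 2:
                self._r2[j] = self._index[r.reactants[1]]
            for s in r.consumed:
                self.stoich[self._index[s], j] -= 1.0
            for s in r.products:
                self.stoich[self._index[s], j] += 1.0
            if r.factor is not None:
                self._factor_idx[j] = factor_names.index(r.factor)
            if r.ligand is not None:
                self._ligand_idx[j] = self._ligand_names.index(r.ligand)
            if r.drug is not None:
                self._drug_idx[j] = self._drug_names.index(r.drug)
            if r.hill_tag is not None:
                self._tag_idx[j] = self._hill_tags.index(r.hill_tag)

        # Hill inhibitors among this network's drugs, keyed by tag position.
        self._hill_drugs: list[list[DrugAction]] = [
            [
                d
                for d in self.drugs
                if d.mechanism == "kinase_hill_inhibition" and d.target == tag
            ]
            for tag in self._hill_tags
        ]

    # -- public surface ----------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise NetworkError(f"unknown species {name!r}")

    def state_vector(self, amounts: Mapping[str, float]) -> np.ndarray:
        y = np.zeros(self.n_species)
        for name, v in amounts.items():
            y[self.index(name)] = v
        return y

    def state_map(self, y: np.ndarray) -> dict[str, float]:
        return dict(zip(self.species, np.asarray(y, dtype=float)))

    def rhs(
        self,
        t: float,
        y: np.ndarray,
        ligand_conc: Callable[[float], np.ndarray] | None = None,
        drug_conc: Callable[[float], np.ndarray] | None = None,
    ) -> np.ndarray:
        v = self.k.copy()
        m1 = self._r1 >= 0
        v[m1] *= np.maximum(y[self._r1[m1]], 0.0)
        m2 = self._r2 >= 0
        v[m2] *= np.maximum(y[self._r2[m2]], 0.0)
        mf = self._factor_idx >= 0
        if mf.any():
            fvals = self._factor_matrix @ np.maximum(y, 0.0)
            v[mf] *= np.maximum(fvals[self._factor_idx[mf]], 0.0)
        if self._ligand_names:
            lc = (
                ligand_conc(t)
                if ligand_conc is not None
                else np.zeros(len(self._ligand_names))
            )
            ml = self._ligand_idx >= 0
            v[ml] *= lc[self._ligand_idx[ml]]
        if self._drug_names or self._hill_tags:
            dc = drug_conc(t) if drug_conc is not None else None
        if self._drug_names:
            md = self._drug_idx >= 0
            if dc is None:
                v[md] = 0.0
            else:
                v[md] *= np.array([dc.get(n, 0.0) for n in self._drug_names])[
                    self._drug_idx[md]
                ]
        if self._hill_tags:
            hf = np.ones(len(self._hill_tags))
            if dc is not None:
                for i, drugs in enumerate(self._hill_drugs):
                    for d in drugs:
                        c = dc.get(d.drug, 0.0)
                        if c > 0:
                            hf[i] *= 1.0 / (1.0 + (c / d.ic50) ** d.hill)
            mh = self._tag_idx >= 0
            v[mh] *= hf[self._tag_idx[mh]]
        return self.stoich @ v

    def ligand_names(self) -> list[str]:
        return list(self._ligand_names)

    def to_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Species and reaction listings (SBML-like tabular dump)."""
        sp = pd.DataFrame(
            {"species": self.species, "group": [self._group_of(s) for s in self.species]}
        )
        rx = pd.DataFrame(
            [
                {
                    "reaction": r.name,
                    "rate_constant": r.rate,
                    "reactants": "+".join(r.reactants) or "(source)",
                    "products": "+".join(r.products) or "(sink)",
                    "ligand": r.ligand or "",
                    "drug": r.drug or "",
                    "hill_tag": r.hill_tag or "",
                }
                for r in self.reactions
            ]
        )
        return sp, rx

    def _group_of(self, s: str) -> str:
        for g, members in self.groups.items():
            if s in members:
                return g
        return ""


# ---------------------------------------------------------------------------
# Network construction


def _met_pools(p: CloneParameters) -> list[tuple[str, float, float, float, float, float, bool]]:
    """(pool, kt, kd, kp, kdp, kd_phospho, cbl_route) per expressed MET pool."""
    cbl = p.cbl_degradation_factor
    pools = []
    if p.clone_kind == "ex14":
        pools.append(
            ("MET14", p.kt_14_MET, p.kd_14_MET, p.kp_14_MET, p.kdp_14_MET, p.kd_14_MET, False)
        )
    else:
        pools.append(("MET", p.kt_MET, p.kd_MET, p.kp_MET, p.kdp_MET, cbl * p.kd_MET, True))
        if p.clone_kind == "amplified":
            pools.append(
                (
                    "METoe",
                    (p.amplification_factor - 1.0) * p.kt_MET,
                    p.kd_oe_MET,
                    p.kp_MET,
                    p.kdp_MET,
                    cbl * p.kd_oe_MET,
                    True,
                )
            )
    return pools


def build_network(
    params: CloneParameters, drugs: Iterable[DrugAction] = ()
) -> ReactionNetwork:
    """Assemble the clone's reaction system from its parameters and drug actions.

    Chemo (``chemo_cell_kill``) drugs carry no signaling reactions; they are
    retained on the network so the tumor layer can read their kill terms.
    """
    p = params
    drugs = list(drugs)
    tkis = [d for d in drugs if d.mechanism == "met_tki_binding"]

    species: list[str] = []
    rx: list[_Reaction] = []
    groups: dict[str, list[str]] = {
        "MET": [],
        "EGFR": [],
        "ALK": [],
        "ROS1": [],
        "PI3K": [],
        "AKT": [],
        "RAS": [],
        "MEK": [],
        "ERK": [],
    }
    active: dict[str, list[str]] = {g: [] for g in groups}

    def add_species(name: str, group: str) -> str:
        species.append(name)
        groups[group].append(name)
        return name

    # ---- MET pools -------------------------------------------------------
    met_free: list[str] = []
    for pool, kt, kd, kp, kdp, kd_p, _cbl in _met_pools(p):
        X = add_species(pool, "MET")
        XL = add_species(f"{pool}_HGF", "MET")
        pX = add_species(f"p{pool}", "MET")
        pXL = add_species(f"p{pool}_HGF", "MET")
        active["MET"] += [pX, pXL]
        met_free.append(X)
        if kt > 0:
            rx.append(_Reaction(f"{pool}_synthesis", kt, (), (X,), ()))
        rx.append(_Reaction(f"{pool}_degradation", kd, (X,), (), (X,)))
        rx.append(_Reaction(f"{XL}_degradation", kd, (XL,), (), (XL,)))
        rx.append(_Reaction(f"{pX}_degradation", kd_p, (pX,), (), (pX,)))
        rx.append(_Reaction(f"{pXL}_degradation", kd_p, (pXL,), (), (pXL,)))
        rx.append(_Reaction(f"{pool}_HGF_on", p.kon_HGF, (X,), (XL,), (X,), ligand="HGF"))
        rx.append(_Reaction(f"{pool}_HGF_off", p.koff_HGF, (XL,), (X,), (XL,)))
        rx.append(
            _Reaction(f"{pool}_ligand_phosphorylation", kp, (XL,), (pXL,), (XL,), hill_tag="MET")
        )
        rx.append(_Reaction(f"{pXL}_dephosphorylation", kdp, (pXL,), (XL,), (pXL,)))
        rx.append(
            _Reaction(
                f"{pool}_auto_phosphorylation",
                p.k_auto_MET,
                (X,),
                (pX,),
                (X,),
                factor="free_MET",
                hill_tag="MET",
            )
        )
        rx.append(_Reaction(f"{pX}_dephosphorylation", kdp, (pX,), (X,), (pX,)))
        for d in tkis:
            XD = add_species(f"{pool}_{d.drug}", "MET")
            kon = d.kon_oe if pool == "METoe" else d.kon
            rx.append(_Reaction(f"{pool}_{d.drug}_on", kon, (X,), (XD,), (X,), drug=d.drug))
            rx.append(_Reaction(f"{pool}_{d.drug}_off", d.koff, (XD,), (X,), (XD,)))
            rx.append(_Reaction(f"{XD}_degradation", kd, (XD,), (), (XD,)))

    # ---- EGFR ------------------------------------------------------------
    E = add_species("EGFR", "EGFR")
    EL = add_species("EGFR_EGF", "EGFR")
    pEL = add_species("pEGFR_EGF", "EGFR")
    active["EGFR"].append(pEL)
    rx += [
        _Reaction("EGFR_synthesis", p.kt_EGFR, (), (E,), ()),
        _Reaction("EGFR_degradation", p.kd_EGFR, (E,), (), (E,)),
        _Reaction("EGFR_EGF_on", p.kon_EGF, (E,), (EL,), (E,), ligand="EGF"),
        _Reaction("EGFR_EGF_off", p.koff_EGF, (EL,), (E,), (EL,)),
        _Reaction("EGFR_EGF_degradation", p.kd_EGFR, (EL,), (), (EL,)),
        _Reaction(
            "EGFR_phosphorylation", p.kp_EGFR, (EL,), (pEL,), (EL,), hill_tag="EGFR"
        ),
        _Reaction("pEGFR_dephosphorylation", p.kdp_EGFR, (pEL,), (EL,), (pEL,)),
        _Reaction(
            "pEGFR_degradation", p.kd_pEGFR_factor * p.kd_EGFR, (pEL,), (), (pEL,)
        ),
    ]

    # ---- ALK / ROS1 ------------------------------------------------------
    for name, kt, kd, kp, kdp, on in (
        ("ALK", p.kt_ALK, p.kd_ALK, p.kp_ALK, p.kdp_ALK, p.alk_mutant),
        ("ROS1", p.kt_ROS1, p.kd_ROS1, p.kp_ROS1, p.kdp_ROS1, p.ros1_rearranged),
    ):
        R = add_species(name, name)
        pR = add_species(f"p{name}", name)
        active[name].append(pR)
        if kt > 0:
            rx.append(_Reaction(f"{name}_synthesis", kt, (), (R,), ()))
        rx.append(_Reaction(f"{name}_degradation", kd, (R,), (), (R,)))
        rx.append(_Reaction(f"p{name}_degradation", kd, (pR,), (), (pR,)))
        if on:
            rx.append(
                _Reaction(
                    f"{name}_constitutive_phosphorylation",
                    kp,
                    (R,),
                    (pR,),
                    (R,),
                    hill_tag=name,
                )
            )
        rx.append(_Reaction(f"p{name}_dephosphorylation", kdp, (pR,), (R,), (pR,)))

    # ---- downstream cascades (conserved pairs) ---------------------------
    cascade = [
        ("PI3K", p.kact_PI3K, p.kdeact_PI3K, "receptor_signal"),
        ("AKT", p.kact_AKT, p.kdeact_AKT, "aPI3K"),
        ("RAS", p.kact_RAS, p.kdeact_RAS, "receptor_signal"),
        ("MEK", p.kact_MEK, p.kdeact_MEK, "aRAS"),
        ("ERK", p.kact_ERK, p.kdeact_ERK, "aMEK"),
    ]
    for kin, kact, kdeact, driver in cascade:
        I = add_species(kin, kin)
        A = add_species(f"a{kin}", kin)
        active[kin].append(A)
        if driver == "receptor_signal":
            rx.append(
                _Reaction(
                    f"{kin}_activation", kact, (I,), (A,), (I,),
                    factor="receptor_signal", hill_tag=kin if kin in HILL_TARGETS else None,
                )
            )
        else:
            rx.append(
                _Reaction(
                    f"{kin}_activation", kact, (I, driver), (A,), (I,),
                    hill_tag=kin if kin in HILL_TARGETS else None,
                )
            )
        rx.append(_Reaction(f"{kin}_deactivation", kdeact, (A,), (I,), (A,)))

    # ---- linear-combination factors --------------------------------------
    index = {s: i for i, s in enumerate(species)}
    free_met = np.zeros(len(species))
    for s in met_free:
        free_met[index[s]] = 1.0
    signal = np.zeros(len(species))
    for rec in ("MET", "EGFR", "ALK", "ROS1"):
        w = p.receptor_weights.get(rec, 1.0)
        for s in active[rec]:
            signal[index[s]] = w
    factors = {"free_MET": free_met, "receptor_signal": signal}

    net = ReactionNetwork(p, drugs, species, rx, factors, groups)
    net.active_species = {g: list(v) for g, v in active.items()}
    return net


# ---------------------------------------------------------------------------
# Integration


def _default_initial(net: ReactionNetwork) -> np.ndarray:
    p = net.params
    amounts: dict[str, float] = {}
    for pool, kt, kd, *_ in _met_pools(p):
        amounts[pool] = kt / kd if kd > 0 else 0.0
    amounts["EGFR"] = p.kt_EGFR / p.kd_EGFR if p.kd_EGFR > 0 else 0.0
    amounts["ALK"] = p.kt_ALK / p.kd_ALK if p.kd_ALK > 0 else 0.0
    amounts["ROS1"] = p.kt_ROS1 / p.kd_ROS1 if p.kd_ROS1 > 0 else 0.0
    for kin in ("PI3K", "AKT", "RAS", "MEK", "ERK"):
        amounts[kin] = getattr(p, f"{kin}_total")
    return net.state_vector(amounts)


def _integrate(net, y0, t_span, t_eval, ligand_conc=None, drug_conc=None,
               rtol=1.0e-8, atol_scale=1.0e-10):
    from scipy.integrate import solve_ivp

    atol = atol_scale * np.maximum(np.abs(y0), 1.0)
    sol = solve_ivp(
        lambda t, y: net.rhs(t, y, ligand_conc, drug_conc),
        t_span,
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE solver failed at t={sol.t[-1] if sol.t.size else t_span[0]:.3g} h: "
            f"{sol.message}"
        )
    return sol


def equilibrate(
    net: ReactionNetwork,
    initial: Mapping[str, float] | np.ndarray | None = None,
    tol: float = 1.0e-9,
    max_horizon_h: float = 1.0e6,
    rtol: float = 1.0e-8,
) -> dict[str, float]:
    """Relax the drug-free, ligand-free network to its steady state.

    The returned state is the initial condition for every perturbation
    simulation.  Convergence criterion: ``max |dy/dt| < tol * max(y, 1)``
    componentwise.  Raises :class:`EquilibrationError` naming the worst
    species if the horizon is exhausted first.
    """
    if initial is None:
        y = _default_initial(net)
    elif isinstance(initial, np.ndarray):
        y = np.asarray(initial, dtype=float).copy()
    else:
        y = net.state_vector(initial)
    if np.any(y < 0):
        raise NetworkError("initial amounts must be >= 0")

    t, chunk = 0.0, 2000.0
    while t < max_horizon_h:
        sol = _integrate(net, y, (0.0, chunk), np.array([chunk]), rtol=rtol)
        y = np.maximum(sol.y[:, -1], 0.0)
        dy = net.rhs(0.0, y)
        if np.all(np.abs(dy) < tol * np.maximum(y, 1.0)):
            return net.state_map(y)
        t += chunk
        chunk = min(chunk * 2.0, max_horizon_h - t) or chunk
    rel = np.abs(net.rhs(0.0, y)) / np.maximum(y, 1.0)
    worst = net.species[int(np.argmax(rel))]
    raise EquilibrationError(
        f"no steady state within {max_horizon_h:.3g} h; worst species {worst!r} "
        f"(|dy/dt|/max(y,1) = {rel.max():.3g})"
    )


def _ligand_forcing(net: ReactionNetwork, stimuli: Sequence[LigandStimulus]):
    names = net.ligand_names()
    if not names:
        return None
    onsets = {n: [] for n in names}
    for s in stimuli:
        if s.ligand in onsets:
            onsets[s.ligand].append((s.onset_h, s.concentration_nM))

    def conc(t: float) -> np.ndarray:
        return np.array(
            [sum(c for t0, c in onsets[n] if t >= t0) for n in names]
        )

    return conc


def _drug_forcing(exposures: Mapping[str, "object"] | None):
    if not exposures:
        return None

    def conc(t: float) -> dict[str, float]:
        return {name: tr.tumor_at(t) for name, tr in exposures.items()}

    return conc


def simulate_timecourse(
    net: ReactionNetwork,
    initial: Mapping[str, float],
    stimuli: Sequence[LigandStimulus] = (),
    exposures: Mapping[str, "object"] | None = None,
    horizon_h: float = 48.0,
    t_eval: np.ndarray | None = None,
    rtol: float = 1.0e-8,
) -> pd.DataFrame:
    """Integrate the clone from ``initial`` under ligand steps and drug exposure.

    ``exposures`` maps drug name -> object with a ``tumor_at(t)`` method (an
    :class:`~metqsp.pk.ExposureTrace`).  Returns a wide table with a ``time``
    column and one column per species.
    """
    if t_eval is None:
        t_eval = np.linspace(0.0, horizon_h, 201)
    t_eval = np.asarray(t_eval, dtype=float)
    y0 = net.state_vector(initial) if not isinstance(initial, np.ndarray) else initial
    if np.any(y0 < 0):
        raise NetworkError("initial amounts must be >= 0")
    sol = _integrate(
        net,
        np.asarray(y0, dtype=float),
        (float(t_eval[0]), float(t_eval[-1])),
        t_eval,
        ligand_conc=_ligand_forcing(net, stimuli),
        drug_conc=_drug_forcing(exposures),
        rtol=rtol,
    )
    df = pd.DataFrame(sol.y.T, columns=net.species)
    df.insert(0, "time", sol.t)
    return df


def readout(
    trajectory: pd.DataFrame,
    net: ReactionNetwork,
    node: str,
    mode: str = "active_fraction",
) -> pd.Series:
    """Extract a node-level time series from a trajectory table.

    ``active_fraction`` is active/(active+inactive) within the node's
    conserved/receptor group; ``total`` sums every species in the group
    (free + ligand-bound + phosphorylated + drug-bound).
    """
    if node not in net.groups:
        raise NetworkError(f"unknown node {node!r}; known: {sorted(net.groups)}")
    members = net.groups[node]
    total = trajectory[members].sum(axis=1)
    if mode == "total":
        return pd.Series(total.to_numpy(), index=trajectory["time"], name=f"{node}_total")
    if mode == "active_fraction":
        act = trajectory[net.active_species[node]].sum(axis=1)
        frac = np.where(total.to_numpy() > 0, act.to_numpy() / total.to_numpy(), 0.0)
        return pd.Series(frac, index=trajectory["time"], name=f"f{node}")
    raise NetworkError(f"unknown readout mode {mode!r}")


def total_abundance(state: Mapping[str, float], net: ReactionNetwork, node: str) -> float:
    """Total copies of a receptor/kinase group in a state map (free + complexed)."""
    if node not in net.groups:
        raise NetworkError(f"unknown node {node!r}")
    return float(sum(state[s] for s in net.groups[node]))


def calibrate_receptor_abundance(
    params: CloneParameters,
    targets: Mapping[str, float],
    drugs: Sequence[DrugAction] = (),
    max_iter: int = 8,
    rel_tol: float = 1.0e-6,
) -> tuple[CloneParameters, dict[str, float]]:
    """Set receptor synthesis rates so equilibrated totals hit measured abundances.

    Receptor copy numbers per cell are what is measured experimentally; the
    synthesis rate consistent with a target abundance depends (weakly, via
    basal auto-activation flux) on the rest of the network, so a fixed-point
    iteration rescales ``kt`` until the equilibrated total matches.
    """
    kt_of = {"MET": "kt_MET", "EGFR": "kt_EGFR", "ALK": "kt_ALK", "ROS1": "kt_ROS1"}
    p = params
    state: dict[str, float] = {}
    for _ in range(max_iter):
        net = build_network(p, drugs)
        state = equilibrate(net)
        worst = 0.0
        changes = {}
        for node, target in targets.items():
            tot = total_abundance(state, net, node)
            if tot <= 0:
                raise NetworkError(f"cannot calibrate {node}: zero equilibrated total")
            worst = max(worst, abs(tot - target) / target)
            changes[kt_of[node]] = getattr(p, kt_of[node]) * target / tot
        if worst < rel_tol:
            break
        p = replace(p, **changes)
    return p, state
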