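"""Reference cell parameterizations anchored to measured receptor abundances.

The reference (A549-like) NSCLC cell expresses normal MET and EGFR; its
quantified surface abundances — 13,590 MET and 158,834 EGFR receptors per
cell — anchor the synthesis/degradation balance of the receptor modules.
Aberrant clones derive from the same base: the exon-14-skipped clone swaps
in the slow-degrading MET pool, and the amplified clone adds the surplus
synthesis pool.
"""

from __future__ import annotations

from dataclasses import replace

from .network import CloneParameters, calibrate_receptor_abundance

__all__ = [
    "A549_MET_RECEPTORS_PER_CELL",
    "A549_EGFR_RECEPTORS_PER_CELL",
    "a549_reference",
    "reference_clone",
]

A549_MET_RECEPTORS_PER_CELL = 13_590.0
A549_EGFR_RECEPTORS_PER_CELL = 158_834.0


def a549_reference(**overrides) -> tuple[CloneParameters, dict[str, float]]:
    """Abundance-calibrated wild-type reference clone and its steady state.

    Receptor synthesis rates are set so the ligand-free, drug-free
    equilibrated totals equal the measured per-cell copy numbers (a
    fixed-point calibration, since basal auto-activation flux feeds back on
    the totals).  Returns (parameters, equilibrated state).
    """
    base = CloneParameters(clone_kind="wild_type", **overrides)
    return calibrate_receptor_abundance(
        base,
        {
            "MET": A549_MET_RECEPTORS_PER_CELL,
            "EGFR": A549_EGFR_RECEPTORS_PER_CELL,
        },
    )


def reference_clone(kind: str, amplification_factor: float = 5.0,
                    calibrated_base: CloneParameters | None = None) -> CloneParameters:
    """Reference parameter set for a clone kind sharing the calibrated base."""
    base = calibrated_base if calibrated_base is not None else a549_reference()[0]
    if kind == "wild_type":
        return base
    if kind == "ex14":
        return replace(base, clone_kind="ex14")
    if kind == "amplified":
        return replace(base, clone_kind="amplified",
                       amplification_factor=amplification_factor)
    raise ValueError(f"unknown clone kind {kind!r}")


def patient_normal_clone(calibrated_base: CloneParameters | None = None) -> CloneParameters:
    """The "normal cancer cell" clone co-resident in patient tumors.

    Its proliferation is largely MET-independent (higher basal growth
    ``k0_cell``), so it competes with the aberrant clone on comparable
    terms and clone ratios genuinely vary across virtual patients; it is
    also the reservoir of TKI-insensitive growth that limits response
    depth.
    """
    base = calibrated_base if calibrated_base is not None else a549_reference()[0]
    return replace(base, k0_cell=0.0075)
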