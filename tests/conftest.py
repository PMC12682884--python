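"""Shared fixtures: calibrated reference clones, drug library, small cohorts.

Session scope keeps the expensive pieces (abundance calibration, cohort
generation, per-patient treatment simulations) to one computation each.
"""

from __future__ import annotations

import numpy as np
import pytest

from metqsp import (
    TreatmentArm,
    a549_reference,
    generate_cohort,
    load_drug_library,
    reference_clone,
)
from metqsp.reference import patient_normal_clone
from metqsp.trials import simulate_patient_response


@pytest.fixture(scope="session")
def drug_library():
    return load_drug_library()


@pytest.fixture(scope="session")
def calibrated_reference():
    """(parameters, steady state) of the abundance-calibrated wild-type clone."""
    return a549_reference()


@pytest.fixture(scope="session")
def wild_type_clone(calibrated_reference):
    return calibrated_reference[0]


@pytest.fixture(scope="session")
def ex14_clone(calibrated_reference):
    return reference_clone("ex14", calibrated_base=calibrated_reference[0])


@pytest.fixture(scope="session")
def amplified_clone(calibrated_reference):
    return reference_clone("amplified", calibrated_base=calibrated_reference[0])


@pytest.fixture(scope="session")
def small_cohort(ex14_clone, calibrated_reference):
    """Eight METex14 virtual patients (fixed seed) for trial-level tests."""
    normal = patient_normal_clone(calibrated_reference[0])
    return generate_cohort(ex14_clone, normal, 8, "METex14", seed=11)


@pytest.fixture(scope="session")
def capmatinib_responses(small_cohort, drug_library):
    """Per-patient best changes for three arms sharing the small cohort.

    Arms: capmatinib standard (400 mg BID), capmatinib low (100 mg BID),
    and capmatinib standard + GDC0941 (PI3K inhibitor) combination.
    """
    from metqsp.pk import DoseRegimen

    capma = drug_library["capmatinib"]
    gdc = drug_library["GDC0941"]
    arms = {
        "standard": TreatmentArm("capmatinib", [(capma, capma.default_regimen)]),
        "low": TreatmentArm(
            "capmatinib_low", [(capma, DoseRegimen(100.0, "BID"))]
        ),
        "combo": TreatmentArm(
            "capmatinib+GDC0941",
            [(capma, capma.default_regimen), (gdc, gdc.default_regimen)],
        ),
    }
    duration = 24.0 * 126  # three assessment cycles
    out = {}
    for label, arm in arms.items():
        out[label] = np.array(
            [
                simulate_patient_response(p, arm, duration_h=duration)[0]
                for p in small_cohort.patients
            ]
        )
    return out
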