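"""Organoid-informed personalization: fits, projections, dose scans."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import curve_fit

from metqsp.network import CloneParameters, DrugAction, LigandStimulus
from metqsp.pdo import (
    PDODataset,
    PDOError,
    PatientModel,
    apply_potency,
    dose_reduction_scan,
    fit_pdo,
    project_clinical,
    simulate_pdo_viability,
)
from metqsp.pk import DoseRegimen

# the organoid assay's printed concentration grid (uM)
PDO_GRID_UM = np.array([0.0, 0.01, 0.1, 0.3163, 1.0, 3.163, 10.0])

BASE = CloneParameters(clone_kind="amplified", amplification_factor=3.0)


def chemo_action(name="cisplatin", emax=0.03, ec50=2000.0):
    return DrugAction(name, "chemo_cell_kill", emax=emax, ec50=ec50, hill=1.0)


class TestDataset:
    def test_validation(self):
        with pytest.raises(PDOError, match="increasing"):
            PDODataset("p1", {"x": (np.array([0.0, 1.0, 0.5]), np.ones(3))})
        with pytest.raises(PDOError, match="zero concentration"):
            PDODataset("p1", {"x": (np.array([0.0, 1.0]), np.array([0.2, 0.1]))})
        ds = PDODataset("p1", {"a+b": (PDO_GRID_UM, np.ones(7))})
        assert ds.components("a+b") == ["a", "b"]

    def test_to_frame_schema(self):
        ds = PDODataset("p1", {"cisplatin": (PDO_GRID_UM, np.ones(7))})
        df = ds.to_frame()
        assert set(df.columns) == {"patient", "drug", "concentration_uM", "viability"}
        assert len(df) == 7


class TestViabilitySimulation:
    def test_chemo_closed_form(self):
        act = chemo_action()
        v = simulate_pdo_viability(BASE, [act], PDO_GRID_UM)
        c_nM = PDO_GRID_UM * 1e3
        expected = np.exp(-act.emax * c_nM / (act.ec50 + c_nM) * 168.0)
        assert np.allclose(v, expected, rtol=1e-12)

    def test_viability_monotone_and_starts_at_one(self):
        v = simulate_pdo_viability(BASE, [chemo_action()], PDO_GRID_UM)
        assert v[0] == 1.0
        assert np.all(np.diff(v) <= 1e-12)

    def test_combination_wells_compound_both_kill_terms(self):
        a = chemo_action("a", emax=0.02, ec50=1000.0)
        b = chemo_action("b", emax=0.01, ec50=5000.0)
        va = simulate_pdo_viability(BASE, [a], PDO_GRID_UM)
        vb = simulate_pdo_viability(BASE, [b], PDO_GRID_UM)
        vab = simulate_pdo_viability(BASE, [a, b], PDO_GRID_UM)
        assert np.allclose(vab, va * vb, rtol=1e-12)  # independent-action product


class TestFit:
    def _library(self, drug_library):
        return drug_library

    def test_noiseless_recovery_within_two_percent(self, drug_library):
        truth = PatientModel("p1", 1.0, 3.0, {"cisplatin": 1.8}, BASE)
        acts = [apply_potency(a, 1.8) for a in drug_library["cisplatin"].actions]
        via = simulate_pdo_viability(truth.clone_parameters(), acts, PDO_GRID_UM)
        data = PDODataset("p1", {"cisplatin": (PDO_GRID_UM, via)})
        model = fit_pdo(data, drug_library, base_params=BASE)
        assert model.potency["cisplatin"] == pytest.approx(1.8, rel=0.02)

    def test_noisy_recovery_within_25_percent_over_20_seeds(self, drug_library):
        """Identifiable potency recovered within 25% from 10%-noise panels."""
        from metqsp.fixtures import gen_pdo

        truth = PatientModel("p1", 1.0, 3.0, {"cisplatin": 1.8}, BASE)
        actions = {"cisplatin": drug_library["cisplatin"].actions}
        errs = []
        for seed in range(20):
            data = gen_pdo(truth, actions, PDO_GRID_UM, cv=0.10, seed=seed)
            model = fit_pdo(data, drug_library, base_params=BASE,
                            max_evaluations=250)
            errs.append(abs(model.potency["cisplatin"] / 1.8 - 1.0))
        assert np.median(errs) < 0.25
        assert np.mean(np.array(errs) < 0.25) >= 0.75

    def test_flat_panel_pins_potency_with_warning(self, drug_library):
        data = PDODataset("p1", {"cisplatin": (PDO_GRID_UM, np.ones(7))})
        model = fit_pdo(data, drug_library, base_params=BASE,
                        max_evaluations=200)
        assert model.potency["cisplatin"] <= 0.0101
        assert any("flat" in w for w in model.warnings)

    def test_unknown_drug_fitted_generically_with_note(self, drug_library):
        act = chemo_action("sorafenib", emax=0.02, ec50=1000.0)
        via = simulate_pdo_viability(BASE, [act], PDO_GRID_UM)
        data = PDODataset("p1", {"sorafenib": (PDO_GRID_UM, via)})
        model = fit_pdo(data, drug_library, base_params=BASE,
                        max_evaluations=100, generic_chemo=act)
        assert any("not in drug library" in w for w in model.warnings)

    def test_too_few_concentrations_rejected(self, drug_library):
        data = PDODataset("p1", {"cisplatin": (np.array([0.0, 1.0, 10.0]),
                                               np.array([1.0, 0.8, 0.4]))})
        with pytest.raises(PDOError, match="4 concentrations"):
            fit_pdo(data, drug_library, base_params=BASE)

    def test_implied_ic50_within_twofold_of_4pl_fit(self, drug_library):
        """IC50 read off the mechanistic curve agrees with an independent
        four-parameter-logistic fit of the same table within 2-fold."""
        truth = PatientModel("p1", 1.0, 3.0, {"cisplatin": 2.0}, BASE)
        acts = [apply_potency(a, 2.0) for a in drug_library["cisplatin"].actions]
        grid = np.array([0.0, 0.01, 0.1, 0.3163, 1.0, 3.163, 10.0, 31.63, 100.0])
        via = simulate_pdo_viability(truth.clone_parameters(), acts, grid)

        def fourpl(x, bottom, top, ic50, h):
            return bottom + (top - bottom) / (1.0 + (x / ic50) ** h)

        popt, _ = curve_fit(fourpl, grid[1:], via[1:],
                            p0=[0.0, 1.0, 1.0, 1.0],
                            bounds=([0, 0.5, 1e-4, 0.3], [0.5, 1.5, 1e3, 4.0]),
                            maxfev=20000)
        ic50_4pl = popt[2]
        # mechanistic half-viability concentration by interpolation
        half = 0.5 * (via[1:].max() + via[1:].min())
        ic50_mech = np.interp(-half, -via[1:], grid[1:])
        assert 0.5 < ic50_mech / ic50_4pl < 2.0


@pytest.fixture(scope="module")
def egfr_patient():
    """A patient whose tumor growth is EGFR-ligand driven (for TKI tests)."""
    return PatientModel("p4", 1.0, 2.0, {"erlotinib": 1.0, "gefitinib": 1.0}, BASE)


@pytest.fixture(scope="module")
def chemo_patient():
    """Patient sensitive to pemetrexed more than cisplatin (organoid-fitted)."""
    return PatientModel("p1", 1.0, 3.0,
                        {"pemetrexed": 3.0, "cisplatin": 0.7}, BASE)


class TestClinicalProjection:
    def test_zero_dose_equals_untreated_growth(self, drug_library, chemo_patient):
        reg = DoseRegimen(0.0, "Q3W", per_m2=True)
        proj = project_clinical(
            chemo_patient, [("none", [("cisplatin", reg)])], drug_library,
            duration_h=24.0 * 7 * 13,
        )[0]
        assert proj.diameter_change_pct[-1] > 0  # tumor grows unchecked
        assert proj.recist_at_three_months == "PD"

    def test_unknown_drug_refused(self, drug_library, chemo_patient):
        with pytest.raises(PDOError, match="no PK entry"):
            project_clinical(
                chemo_patient,
                [("x", [("sorafenib", DoseRegimen(100.0, "QD"))])],
                drug_library, duration_h=24.0 * 7 * 13,
            )

    def test_erlotinib_dose_monotonicity_for_egfr_driven_patient(
        self, drug_library, egfr_patient
    ):
        stim = [LigandStimulus("EGF", 5.0)]
        regs = [
            ("full", [("erlotinib", DoseRegimen(150.0, "QD"))]),
            ("quarter", [("erlotinib", DoseRegimen(37.5, "QD"))]),
        ]
        projs = project_clinical(egfr_patient, regs, drug_library,
                                 duration_h=24.0 * 7 * 13, stimuli=stim)
        assert projs[0].three_month_change_pct < projs[1].three_month_change_pct

    def test_pemetrexed_halving_hurts_more_than_cisplatin_halving(
        self, drug_library, chemo_patient
    ):
        """For a pemetrexed-sensitive patient, halving pemetrexed loses more
        three-month response than halving cisplatin in the doublet."""
        pem = DoseRegimen(500.0, "Q3W", per_m2=True)
        cis = DoseRegimen(75.0, "Q3W", per_m2=True)
        regs = [
            ("full", [("pemetrexed", pem), ("cisplatin", cis)]),
            ("half_pem", [("pemetrexed", pem.scaled(0.5)), ("cisplatin", cis)]),
            ("half_cis", [("pemetrexed", pem), ("cisplatin", cis.scaled(0.5))]),
        ]
        projs = project_clinical(chemo_patient, regs, drug_library,
                                 duration_h=24.0 * 7 * 13)
        full, half_pem, half_cis = (p.three_month_change_pct for p in projs)
        loss_pem = half_pem - full
        loss_cis = half_cis - full
        assert loss_pem > loss_cis > -1e-9


class TestDoseReductionScan:
    def test_factorial_row_count_and_full_dose_consistency(
        self, drug_library, chemo_patient
    ):
        pem = DoseRegimen(500.0, "Q3W", per_m2=True)
        cis = DoseRegimen(75.0, "Q3W", per_m2=True)
        combo = [("pemetrexed", pem), ("cisplatin", cis)]
        table = dose_reduction_scan(chemo_patient, combo, [1.0, 0.5], drug_library)
        assert len(table) == 4
        full_row = table[(table["fraction_pemetrexed"] == 1.0)
                         & (table["fraction_cisplatin"] == 1.0)]
        proj = project_clinical(chemo_patient,
                                [("full", combo)], drug_library,
                                duration_h=24.0 * 7 * 14)[0]
        assert full_row["three_month_change_pct"].iloc[0] == pytest.approx(
            proj.three_month_change_pct, abs=1e-9
        )
        # response never improves when any component's dose drops
        assert table["three_month_change_pct"].min() == full_row[
            "three_month_change_pct"
        ].iloc[0]

    def test_symmetric_two_drug_fixture_gives_symmetric_table(self, drug_library):
        patient = PatientModel("sym", 1.0, 3.0,
                               {"cisplatin": 1.0, "carboplatin": 1.0}, BASE)
        # identical potency constants for both components
        import copy

        lib = dict(drug_library)
        rec = copy.deepcopy(lib["cisplatin"])
        combo_reg = DoseRegimen(100.0, "Q3W")
        recb = copy.deepcopy(rec)
        recb.name = "carboplatin"
        for a in recb.actions:
            a.drug = "carboplatin"
        lib["cisplatin"], lib["carboplatin"] = rec, recb
        table = dose_reduction_scan(
            patient, [("cisplatin", combo_reg), ("carboplatin", combo_reg)],
            [1.0, 0.5], lib,
        )
        asym = table.set_index(["fraction_cisplatin", "fraction_carboplatin"])
        a = asym.loc[(0.5, 1.0), "three_month_change_pct"]
        b = asym.loc[(1.0, 0.5), "three_month_change_pct"]
        assert a == pytest.approx(b, abs=0.1)
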