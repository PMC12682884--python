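"""Signaling-network construction, equilibration, and mechanistic properties."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from metqsp.network import (
    CloneParameters,
    DrugAction,
    LigandStimulus,
    NetworkError,
    build_network,
    equilibrate,
    ligand_ng_per_ml_to_nM,
    readout,
    simulate_timecourse,
    total_abundance,
)
from metqsp.pk import constant_exposure

CAPMA = DrugAction("capmatinib", "met_tki_binding", kon=2e-3, kon_oe=1.5e-3, koff=0.1)


class TestConstruction:
    def test_no_drugs_means_no_drug_complex_species(self):
        net = build_network(CloneParameters())
        assert not any("capmatinib" in s for s in net.species)

    def test_met_tki_adds_binding_reactions_per_pool(self):
        p = CloneParameters(clone_kind="amplified", amplification_factor=5.0)
        net = build_network(p, [CAPMA])
        names = [r.name for r in net.reactions]
        # wild-type pool and overexpressed surplus pool each bind the TKI
        assert "MET_capmatinib_on" in names and "METoe_capmatinib_on" in names
        on = {r.name: r.rate for r in net.reactions if r.name.endswith("capmatinib_on")}
        assert on["MET_capmatinib_on"] == pytest.approx(2e-3)
        assert on["METoe_capmatinib_on"] == pytest.approx(1.5e-3)

    def test_ex14_clone_uses_slow_degradation_without_cbl_route(self):
        p = CloneParameters(clone_kind="ex14")
        net = build_network(p)
        rates = {r.name: r.rate for r in net.reactions}
        assert rates["MET14_degradation"] == pytest.approx(p.kd_14_MET)
        # no enhanced degradation of the phosphorylated ex14 receptor
        assert rates["pMET14_degradation"] == pytest.approx(p.kd_14_MET)

    def test_wild_type_phospho_met_degrades_faster(self):
        p = CloneParameters()
        net = build_network(p)
        rates = {r.name: r.rate for r in net.reactions}
        assert rates["pMET_degradation"] == pytest.approx(
            p.cbl_degradation_factor * p.kd_MET
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(NetworkError):
            CloneParameters(kd_MET=-0.1)
        with pytest.raises(NetworkError):
            CloneParameters(kd_14_MET=0.2, kd_MET=0.1)  # ex14 must degrade slower
        with pytest.raises(NetworkError):
            DrugAction("x", "mystery_mechanism")
        with pytest.raises(NetworkError):
            DrugAction("x", "met_tki_binding", kon=-1.0, kon_oe=1.0, koff=1.0)
        with pytest.raises(NetworkError):
            DrugAction("x", "kinase_hill_inhibition", target="NOTAKINASE", ic50=1.0)

    def test_ligand_unit_conversion(self):
        assert ligand_ng_per_ml_to_nM("HGF", 100.0) == pytest.approx(
            100.0 * 1e3 / 83_000.0
        )
        assert ligand_ng_per_ml_to_nM("EGF", 6.2) == pytest.approx(1.0)

    def test_species_and_reaction_tables(self):
        sp, rx = build_network(CloneParameters(), [CAPMA]).to_tables()
        assert {"species", "group"} <= set(sp.columns)
        assert (rx["rate_constant"] >= 0).all()
        assert "MET_capmatinib_on" in set(rx["reaction"])


class TestEquilibrate:
    def test_reference_receptor_abundances(self, calibrated_reference):
        params, state = calibrated_reference
        net = build_network(params)
        assert total_abundance(state, net, "MET") == pytest.approx(13_590.0, rel=1e-4)
        assert total_abundance(state, net, "EGFR") == pytest.approx(158_834.0, rel=1e-4)

    def test_zero_synthesis_gives_zero_steady_state(self):
        p = CloneParameters(kt_MET=0.0, kt_EGFR=0.0, kt_ALK=0.0, kt_ROS1=0.0)
        net = build_network(p)
        state = equilibrate(net)
        for rec in ("MET", "EGFR", "ALK", "ROS1"):
            assert total_abundance(state, net, rec) == pytest.approx(0.0, abs=1e-6)

    def test_isolated_birth_death_equals_kt_over_kd(self):
        # EGFR with no ligand is a pure birth-death species at equilibrium
        p = CloneParameters(kt_EGFR=5000.0, kd_EGFR=0.25)
        state = equilibrate(build_network(p))
        assert state["EGFR"] == pytest.approx(5000.0 / 0.25, rel=1e-6)

    def test_steady_state_is_a_fixed_point_over_1000_h(self, wild_type_clone):
        net = build_network(wild_type_clone)
        state = equilibrate(net)
        traj = simulate_timecourse(net, state, horizon_h=1000.0,
                                   t_eval=np.array([0.0, 1000.0]))
        y0 = traj.iloc[0][net.species].to_numpy(dtype=float)
        y1 = traj.iloc[-1][net.species].to_numpy(dtype=float)
        assert np.allclose(y1, y0, rtol=1e-5, atol=1e-4)

    def test_arbitrary_positive_start_reaches_same_state(self, wild_type_clone):
        net = build_network(wild_type_clone)
        ref = equilibrate(net)
        rng = np.random.default_rng(3)
        start = {s: float(rng.uniform(1.0, 1e4)) for s in net.species}
        # conserved kinase totals must match the reference to land on the
        # same fixed point
        for kin in ("PI3K", "AKT", "RAS", "MEK", "ERK"):
            start[kin] = sum(ref[s] for s in net.groups[kin])
            start[f"a{kin}"] = 0.0
        other = equilibrate(net, initial=start)
        for rec in ("MET", "EGFR"):
            assert total_abundance(other, net, rec) == pytest.approx(
                total_abundance(ref, net, rec), rel=1e-5
            )


class TestConservation:
    def test_kinase_groups_conserved_during_stimulation(self, wild_type_clone):
        net = build_network(wild_type_clone)
        state = equilibrate(net)
        traj = simulate_timecourse(net, state,
                                   stimuli=[LigandStimulus("HGF", 100.0)],
                                   horizon_h=24.0)
        for kin in ("PI3K", "AKT", "RAS", "MEK", "ERK"):
            totals = traj[net.groups[kin]].sum(axis=1).to_numpy()
            assert np.allclose(totals, totals[0], rtol=1e-6)

    def test_receptor_total_constant_without_turnover(self):
        p = CloneParameters(kt_MET=0.0, kd_MET=1e-12, kd_14_MET=0.0,
                            cbl_degradation_factor=1.0)
        net = build_network(p)
        init = {s: 0.0 for s in net.species}
        init["MET"] = 1e4
        traj = simulate_timecourse(net, init,
                                   stimuli=[LigandStimulus("HGF", 100.0)],
                                   horizon_h=10.0)
        tot = traj[net.groups["MET"]].sum(axis=1).to_numpy()
        assert np.allclose(tot, 1e4, rtol=1e-6)


class TestDynamics:
    def test_hgf_step_transient_phospho_and_receptor_loss(self, wild_type_clone):
        net = build_network(wild_type_clone)
        state = equilibrate(net)
        traj = simulate_timecourse(net, state,
                                   stimuli=[LigandStimulus("HGF", 100.0)],
                                   horizon_h=24.0)
        pmet = readout(traj, net, "MET", "active_fraction")
        total = readout(traj, net, "MET", "total")
        assert pmet.max() > 10 * pmet.iloc[0]          # activation burst
        assert pmet.iloc[-1] < 0.9 * pmet.max()        # then decline
        assert total.iloc[-1] < 0.5 * total.iloc[0]    # internalization/degradation

    def test_ex14_phospho_met_decays_slower_than_wild_type(
        self, wild_type_clone, ex14_clone
    ):
        def post_stim_fraction(params):
            net = build_network(params)
            state = equilibrate(net)
            traj = simulate_timecourse(net, state,
                                       stimuli=[LigandStimulus("HGF", 100.0)],
                                       horizon_h=24.0)
            s = readout(traj, net, "MET", "active_fraction")
            return s.max(), s.iloc[-1]

        peak_wt, end_wt = post_stim_fraction(wild_type_clone)
        peak_14, end_14 = post_stim_fraction(ex14_clone)
        assert end_14 / peak_14 > end_wt / peak_wt  # prolonged phosphorylation

    def test_ex14_higher_steady_met_and_phospho_auc(self, wild_type_clone, ex14_clone):
        def run(params):
            net = build_network(params)
            state = equilibrate(net)
            total = total_abundance(state, net, "MET")
            traj = simulate_timecourse(net, state,
                                       stimuli=[LigandStimulus("HGF", 100.0)],
                                       horizon_h=24.0)
            pm = readout(traj, net, "MET", "active_fraction")
            auc = np.trapezoid(pm.to_numpy(), pm.index.to_numpy())
            return total, auc

        tot_wt, auc_wt = run(wild_type_clone)
        tot_14, auc_14 = run(ex14_clone)
        assert tot_14 > tot_wt
        assert auc_14 > auc_wt

    def test_amplification_raises_basal_phospho_superlinearly(self, wild_type_clone):
        def basal_pmet(amp):
            p = replace(wild_type_clone, clone_kind="amplified",
                        amplification_factor=amp)
            net = build_network(p)
            state = equilibrate(net)
            return sum(state[s] for s in net.active_species["MET"])

        p2, p4 = basal_pmet(2.0), basal_pmet(4.0)
        assert p4 > 2.0 * p2  # doubling synthesis more than doubles basal pMET

    def test_monotone_inhibition_downstream(self, ex14_clone):
        """Higher constant TKI exposure weakly lowers MET, AKT and ERK activity."""
        net = build_network(ex14_clone, [CAPMA])
        state = equilibrate(net)
        means = []
        for conc in (0.0, 50.0, 500.0, 5000.0):
            exp = {"capmatinib": constant_exposure("capmatinib", conc, 100.0)}
            traj = simulate_timecourse(net, state, exposures=exp, horizon_h=100.0)
            means.append(
                [readout(traj, net, node, "active_fraction").mean()
                 for node in ("MET", "AKT", "ERK")]
            )
        means = np.array(means)
        assert (np.diff(means, axis=0) <= 1e-9).all()

    def test_zero_receptor_clone_is_legal_and_silent(self):
        p = CloneParameters(kt_MET=0.0, kt_EGFR=0.0, kt_ALK=0.0, kt_ROS1=0.0)
        net = build_network(p)
        state = equilibrate(net)
        traj = simulate_timecourse(net, state,
                                   stimuli=[LigandStimulus("HGF", 100.0)],
                                   horizon_h=24.0)
        assert readout(traj, net, "AKT", "active_fraction").max() < 1e-9


class TestReadout:
    def test_active_fraction_limits(self, wild_type_clone):
        net = build_network(wild_type_clone)
        init = {s: 0.0 for s in net.species}
        init["AKT"] = 100.0  # all inactive
        traj = simulate_timecourse(net, init, horizon_h=0.01,
                                   t_eval=np.array([0.0, 0.01]))
        assert readout(traj, net, "AKT", "active_fraction").iloc[0] == 0.0
        init["aAKT"] = 100.0  # equal split
        traj = simulate_timecourse(net, init, horizon_h=0.01,
                                   t_eval=np.array([0.0, 0.01]))
        assert readout(traj, net, "AKT", "active_fraction").iloc[0] == pytest.approx(0.5)

    def test_unknown_node_rejected(self, wild_type_clone):
        net = build_network(wild_type_clone)
        state = equilibrate(net)
        traj = simulate_timecourse(net, state, horizon_h=1.0)
        with pytest.raises(NetworkError, match="unknown node"):
            readout(traj, net, "NOTANODE")

    def test_max_normalized_series_preserves_shape(self, wild_type_clone):
        from metqsp.calibration import normalize

        net = build_network(wild_type_clone)
        state = equilibrate(net)
        traj = simulate_timecourse(net, state,
                                   stimuli=[LigandStimulus("HGF", 100.0)],
                                   horizon_h=24.0)
        perk = readout(traj, net, "ERK", "active_fraction").to_numpy()
        normed = normalize(perk, "to_max")
        assert np.allclose(normed * perk.max(), perk)
        assert normed.max() == pytest.approx(1.0)
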