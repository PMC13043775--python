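"""Synthetic-data generators: fixtures, seeding contracts, calibration."""

import numpy as np
import pandas as pd
import pytest

from gemscout import (
    EffectSpec,
    PhaseConfig,
    SyntheticDesign,
    check_goal,
    curves_from_frame,
    estimate_growth_params,
    make_chain3,
    make_random_network,
    make_toy_network,
    simulate_activation,
    simulate_growth_curves,
    simulate_metabolomics,
    simulate_transcriptomics,
    solve_fba,
)


class TestNetworks:
    def test_chain3_shape(self):
        net = make_chain3()
        assert len(net.reactions) == 3
        assert len(net.metabolites) == 4
        assert net.goal_compounds == {"biomass"}

    def test_toy9_glucose_growth(self, toy9):
        assert solve_fba(toy9, PhaseConfig.glucose()).objective_value > 0

    def test_toy9_ethanol_logic(self, toy9):
        state = simulate_activation(toy9, PhaseConfig.ethanol())
        catabolism = toy9.pathway_reactions("ethanol_catabolism")
        assert catabolism <= state.active_reactions
        assert "PDC" not in state.active_reactions  # fermentation needs glucose
        assert check_goal(state, toy9)

    def test_toy9_pathway_labels(self, toy9):
        labels = {p for r in toy9.reactions for p in r.pathways}
        assert labels == {"glycolysis", "fermentation", "TCA", "ethanol_catabolism"}

    def test_random_network_valid_and_deterministic(self):
        a = make_random_network(7)
        b = make_random_network(7)
        assert a == b
        assert a.reaction_ids and a.metabolite_ids


class TestGrowthCurves:
    def test_noise_free_od24_calibration(self):
        frame = simulate_growth_curves(noise_sd=0.0, replicates=2)
        at24 = frame[frame["time_h"] == 24.0].groupby("strain")["od560"].first()
        assert at24["reference"] == pytest.approx(0.265, abs=1e-9)
        assert at24["mutant"] == pytest.approx(0.338, abs=1e-9)

    def test_noise_free_mu_recovery(self):
        frame = simulate_growth_curves(noise_sd=0.0, replicates=2)
        curves = {c.strain: c for c in curves_from_frame(frame)}
        mu_ref = estimate_growth_params(curves["reference"]).mu
        mu_mut = estimate_growth_params(curves["mutant"]).mu
        assert mu_ref == pytest.approx(0.402, rel=0.02)
        assert mu_mut == pytest.approx(0.450, rel=0.02)

    def test_sampling_grid(self):
        frame = simulate_growth_curves(replicates=1, noise_sd=0.0)
        times = np.sort(frame[frame["strain"] == "reference"]["time_h"].unique())
        assert times[0] == 0.0 and times[-1] == 24.0
        assert np.allclose(np.diff(times), 1 / 3)  # every 20 minutes
        assert frame["od560"].iloc[0] == pytest.approx(0.05)  # initial OD

    def test_seeding_contract(self):
        a = simulate_growth_curves(seed=1, replicates=2)
        b = simulate_growth_curves(seed=1, replicates=2)
        c = simulate_growth_curves(seed=2, replicates=2)
        pd.testing.assert_frame_equal(a, b)
        assert not np.allclose(a["od560"], c["od560"])
        # identical noise-free skeletons under different seeds
        sa = simulate_growth_curves(seed=1, replicates=1, noise_sd=0.0)
        sb = simulate_growth_curves(seed=2, replicates=1, noise_sd=0.0)
        pd.testing.assert_frame_equal(sa, sb)

    def test_diauxic_curve_keeps_24h_calibration(self):
        frame = simulate_growth_curves(noise_sd=0.0, replicates=1, diauxic=True)
        at24 = frame[frame["time_h"] == 24.0].groupby("strain")["od560"].first()
        assert at24["reference"] == pytest.approx(0.265, abs=1e-6)
        ref = frame[frame["strain"] == "reference"].sort_values("time_h")["od560"]
        assert (np.diff(ref) > -1e-12).all()  # monotone through the shift


class TestTranscriptomics:
    def test_same_seed_identical(self):
        design = SyntheticDesign(replicates=3, seed=0)
        a, ta = simulate_transcriptomics(design, n_features=50, seed=3)
        b, tb = simulate_transcriptomics(design, n_features=50, seed=3)
        pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_frame_equal(ta, tb)

    def test_truth_table_records_effects(self):
        design = SyntheticDesign(replicates=2, seed=0)
        eff = EffectSpec(transcript_log2fc={"t0001": {"glucose": -1.5}})
        _, truth = simulate_transcriptomics(design, eff, n_features=10, seed=1)
        row = truth.set_index("feature").loc["t0001"]
        assert row["log2fc_glucose"] == -1.5
        assert row["log2fc_ethanol"] == 0.0

    def test_feature_ids_embedded(self, toy9):
        design = SyntheticDesign(replicates=2, seed=0)
        mat, _ = simulate_transcriptomics(
            design, feature_ids=sorted(toy9.genes), n_features=100, seed=2
        )
        assert set(toy9.genes) <= set(mat.features)
        assert len(mat.features) == 100

    def test_design_shape(self):
        design = SyntheticDesign(replicates=4, seed=0)
        mat, _ = simulate_transcriptomics(design, n_features=20, seed=5)
        assert len(mat.samples) == 16  # 2 strains x 2 phases x 4 replicates
        assert (mat.values.values >= 0).all()


class TestMetabolomics:
    def test_no_dropout_keeps_all(self):
        design = SyntheticDesign(replicates=2, seed=0)
        mat, truth = simulate_metabolomics(
            design, detection_dropout=0.0, qc_dropout=0.0, seed=4
        )
        assert len(mat.features) == 85
        assert truth["detected"].all() and truth["qc_pass"].all()

    def test_default_attrition_range(self):
        design = SyntheticDesign(replicates=2, seed=0)
        survivors = []
        for seed in range(10):
            mat, truth = simulate_metabolomics(design, seed=seed)
            survivors.append(len(mat.features))
            assert truth["qc_pass"].sum() == len(mat.features)
            assert (truth["qc_pass"] <= truth["detected"]).all()
        # calibrated to ~9/85 surviving QC of ~14/85 identified
        assert all(3 <= s <= 20 for s in survivors)
        assert 6 <= np.mean(survivors) <= 13

    def test_same_seed_identical(self):
        design = SyntheticDesign(replicates=2, seed=0)
        a, _ = simulate_metabolomics(design, seed=8)
        b, _ = simulate_metabolomics(design, seed=8)
        pd.testing.assert_frame_equal(a.values, b.values)


def test_design_validation():
    with pytest.raises(ValueError):
        SyntheticDesign(replicates=1)
    with pytest.raises(ValueError):
        EffectSpec(detection_dropout=1.0)
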