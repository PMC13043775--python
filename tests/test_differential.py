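"""Differential stand-ins: normalisation, NB Wald test, metabolite linear model, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gemscout import (
    EffectSpec,
    OmicsMatrix,
    SyntheticDesign,
    bh_adjust,
    normalize_counts,
    simulate_metabolomics,
    simulate_transcriptomics,
)
from gemscout import test_metabolites as metabolite_lm
from gemscout import test_transcripts as transcript_nb


def _matrix(values, strains, phase="glucose"):
    values = pd.DataFrame(values)
    values.index = [f"f{i}" for i in range(values.shape[0])]
    values.columns = [f"s{i}" for i in range(values.shape[1])]
    meta = pd.DataFrame(
        {
            "strain": strains,
            "phase": phase,
            "replicate": list(range(1, len(strains) + 1)),
        },
        index=values.columns,
    )
    return OmicsMatrix(values, meta)


class TestNormalizeCounts:
    def test_identical_samples_unchanged(self):
        m = _matrix(np.tile([[10], [20], [30]], (1, 4)), ["reference"] * 4)
        out = normalize_counts(m)
        assert np.allclose(out.size_factors, 1.0)
        pd.testing.assert_frame_equal(out.values, m.values.astype(float))

    def test_proportional_sample_ratio(self):
        a = np.array([10, 20, 40, 80])
        m = _matrix(np.column_stack([a, 2 * a]), ["reference", "mutant"])
        out = normalize_counts(m)
        # factors (1, 2) up to a common normalisation
        assert out.size_factors.iloc[1] / out.size_factors.iloc[0] == pytest.approx(2.0)
        assert np.allclose(out.values.iloc[:, 0], out.values.iloc[:, 1])

    def test_all_zero_feature_flagged_and_kept(self):
        m = _matrix([[10, 12], [0, 0], [30, 28]], ["reference", "mutant"])
        out = normalize_counts(m)
        assert out.all_zero_features == ("f1",)
        assert (out.values.loc["f1"] == 0).all()

    def test_all_zero_sample_rejected(self):
        m = _matrix([[10, 0], [20, 0]], ["reference", "mutant"])
        with pytest.raises(ValueError, match="all-zero"):
            normalize_counts(m)


class TestBhAdjust:
    def test_known_stepup(self):
        # p(i) * m / i then cumulative min from the largest rank
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_empty(self):
        assert bh_adjust([]).size == 0

    @given(st.lists(st.floats(1e-10, 1.0), min_size=1, max_size=30))
    def test_bounds_and_order(self, ps):
        out = bh_adjust(ps)
        assert np.all(out >= np.asarray(ps) - 1e-12)
        assert np.all(out <= 1.0 + 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(out[order]) >= -1e-12)


class TestTranscripts:
    def test_identical_group_means_zero_log2fc(self):
        m = _matrix(
            [[50, 50, 50, 50], [10, 30, 10, 30]],
            ["reference", "reference", "mutant", "mutant"],
        )
        res = {r.feature: r for r in transcript_nb(m)}
        assert res["f0"].log2fc == pytest.approx(0.0)
        assert res["f1"].log2fc == pytest.approx(0.0)

    def test_spiked_log2fc_recovery(self):
        design = SyntheticDesign(replicates=4, seed=21)
        spiked = [f"t{i:04d}" for i in range(50)]
        eff = EffectSpec.for_features(spiked, -1.0, "glucose")
        mat, _ = simulate_transcriptomics(design, eff, n_features=2000, seed=21)
        res = transcript_nb(mat, "glucose")
        est = [r.log2fc for r in res if r.feature in set(spiked)]
        assert np.median(est) == pytest.approx(-1.0, abs=0.2)

    def test_requires_two_replicates(self):
        m = _matrix([[1, 2, 3]], ["reference", "reference", "mutant"])
        with pytest.raises(ValueError, match="replicates"):
            transcript_nb(m)

    def test_contrast_symmetry_and_column_order(self):
        design = SyntheticDesign(replicates=3, seed=4)
        mat, _ = simulate_transcriptomics(design, n_features=100, seed=4)
        res = transcript_nb(mat, "glucose")
        shuffled = OmicsMatrix(
            mat.values[list(reversed(mat.values.columns))], mat.metadata
        )
        res2 = transcript_nb(shuffled, "glucose")
        assert np.allclose(
            [r.log2fc for r in res], [r.log2fc for r in res2], rtol=1e-12
        )
        # swapping strain labels flips the fold-change sign
        meta_swapped = mat.metadata.copy()
        meta_swapped["strain"] = meta_swapped["strain"].map(
            {"mutant": "reference", "reference": "mutant"}
        )
        res3 = transcript_nb(OmicsMatrix(mat.values, meta_swapped), "glucose")
        assert np.allclose(
            [r.log2fc for r in res3], [-r.log2fc for r in res], atol=1e-9
        )


class TestMetabolites:
    def test_identical_groups_flagged(self):
        m = _matrix(
            [[8.0, 8.0, 8.0, 8.0]],
            ["reference", "reference", "mutant", "mutant"],
        )
        r = metabolite_lm(m)[0]
        assert r.log2fc == pytest.approx(0.0)
        assert r.p == 1.0
        assert r.flag == "zero_variance"

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        vals = np.array([[1, 1, 1, 2, 2, 2]]) + rng.normal(0, 1e-4, (1, 6))
        m = _matrix(vals, ["reference"] * 3 + ["mutant"] * 3)
        assert metabolite_lm(m)[0].p < 1e-6

    def test_nadh_scale_effect_recovery(self):
        # single-replicate-set estimates have SE ~ sd*sqrt(2/n) ~ 0.35, so the
        # +/-0.3 recovery tolerance is asserted on the median over seeds
        design = SyntheticDesign(replicates=4, seed=5)
        eff = EffectSpec(
            metabolite_log2fc={"m000": {"ethanol": 2.82}},
            detection_dropout=0.0,
            qc_dropout=0.0,
        )
        ests, ps = [], []
        for seed in range(8):
            mat, _ = simulate_metabolomics(design, eff, seed=seed)
            r = {x.feature: x for x in metabolite_lm(mat, "ethanol")}["m000"]
            ests.append(r.log2fc)
            ps.append(r.p)
        assert np.median(ests) == pytest.approx(2.82, abs=0.3)
        assert np.median(ps) < 0.1


def test_metadata_validation():
    values = pd.DataFrame([[1, 2]], index=["f0"], columns=["a", "b"])
    meta = pd.DataFrame({"strain": ["reference", "mutant"]}, index=["a", "b"])
    with pytest.raises(ValueError, match="phase"):
        OmicsMatrix(values, meta)
    with pytest.raises(ValueError, match="duplicate"):
        OmicsMatrix(
            pd.DataFrame([[1, 2], [1, 2]], index=["f0", "f0"], columns=["a", "b"]),
            pd.DataFrame(
                {"strain": ["reference", "mutant"], "phase": "glucose", "replicate": [1, 1]},
                index=["a", "b"],
            ),
        )
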