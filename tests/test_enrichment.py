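"""Exact tests, GSEA and the consensus enrichment report."""

import numpy as np
import pytest
from scipy import stats as sps

from gemscout import (
    ContingencyTable,
    EffectSpec,
    PathwaySet,
    SyntheticDesign,
    boschloo,
    consensus_enrichment,
    fisher_two_tailed,
    gsea_preranked,
    simulate_transcriptomics,
)
from gemscout import test_transcripts as transcript_nb


def fisher_enumeration_oracle(t: ContingencyTable) -> float:
    """Brute-force two-sided Fisher p: enumerate all tables with the margins."""
    m, n = t.in_sig + t.in_not, t.out_sig + t.out_not
    s = t.in_sig + t.out_sig
    lo, hi = max(0, s - n), min(m, s)
    probs = {k: sps.hypergeom.pmf(k, m + n, m, s) for k in range(lo, hi + 1)}
    obs = probs[t.in_sig]
    return float(sum(p for p in probs.values() if p <= obs * (1 + 1e-7)))


class TestFisher:
    def test_perfect_split(self):
        assert fisher_two_tailed(ContingencyTable(5, 0, 0, 5)) == pytest.approx(2 / 252)

    def test_balanced_table(self):
        assert fisher_two_tailed(ContingencyTable(3, 3, 3, 3)) == 1.0

    def test_degenerate_margin(self):
        assert fisher_two_tailed(ContingencyTable(0, 0, 3, 4)) == 1.0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        t = ContingencyTable(*rng.integers(0, 9, size=4).tolist())
        if t.degenerate:
            return
        assert fisher_two_tailed(t) == pytest.approx(fisher_enumeration_oracle(t), rel=1e-9)


class TestBoschloo:
    def test_balanced_table(self):
        assert boschloo(ContingencyTable(3, 3, 3, 3)) == 1.0

    def test_never_exceeds_fisher(self):
        t = ContingencyTable(5, 0, 0, 5)
        assert boschloo(t) <= fisher_two_tailed(t)

    def test_degenerate(self):
        assert boschloo(ContingencyTable(0, 4, 0, 4)) == 1.0


class TestGsea:
    def test_unweighted_top_set(self):
        stats_map = {"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0}
        res = gsea_preranked(stats_map, {"a", "b"}, n_perm=50, seed=0, weight=0.0)
        assert res.es == pytest.approx(1.0)
        assert res.p_up is not None and res.p_down is None

    def test_empty_intersection_not_applicable(self):
        res = gsea_preranked({"a": 1.0, "b": -1.0}, {"zzz"}, n_perm=10, seed=0)
        assert res.flag == "no_overlap"
        assert res.es is None

    def test_set_equal_to_universe_flagged(self):
        res = gsea_preranked({"a": 1.0, "b": -1.0}, {"a", "b"}, n_perm=10, seed=0)
        assert res.flag == "set_is_universe"

    def test_p_range_and_reproducibility(self):
        rng = np.random.default_rng(3)
        stats_map = {f"f{i}": float(rng.normal()) for i in range(60)}
        members = {f"f{i}" for i in range(10)}
        a = gsea_preranked(stats_map, members, n_perm=199, seed=7)
        b = gsea_preranked(stats_map, members, n_perm=199, seed=7)
        assert (a.p_up, a.p_down, a.es) == (b.p_up, b.p_down, b.es)
        p = a.p_up if a.p_up is not None else a.p_down
        assert 1 / 200 <= p <= 1.0

    def test_shifted_set_detected_down(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            stats_map = {f"f{i}": float(rng.normal()) for i in range(200)}
            for i in range(20):
                stats_map[f"f{i}"] -= 2.0
            res = gsea_preranked(stats_map, {f"f{i}" for i in range(20)}, n_perm=199, seed=seed)
            if res.p_down is not None and res.p_down < 0.05:
                hits += 1
        assert hits >= 27  # >= 90% power at this effect size


class TestConsensus:
    def test_no_significant_features(self):
        from gemscout.differential import DifferentialResult

        de = [
            DifferentialResult(f"f{i}", 0.0, 0.9, 0.95, 0.1, "transcript_nb")
            for i in range(40)
        ]
        sets = [PathwaySet("pw", gene_ids=frozenset({"f0", "f1", "f2"}))]
        res = consensus_enrichment(sets, de, n_perm=49, seed=0)[0]
        assert res.fisher_p == 1.0
        assert res.boschloo_p == 1.0

    def test_disjoint_pathway_not_applicable(self):
        from gemscout.differential import DifferentialResult

        de = [DifferentialResult("f0", 0.0, 0.5, 0.5, 0.0, "transcript_nb")]
        sets = [PathwaySet("pw", gene_ids=frozenset({"x1"}))]
        res = consensus_enrichment(sets, de, n_perm=9, seed=0)[0]
        assert res.flag == "not_measured"
        assert res.fisher_p is None

    def test_spiked_pathway_flagged_down(self):
        design = SyntheticDesign(replicates=4, seed=13)
        spiked = [f"t{i:04d}" for i in range(40)]
        eff = EffectSpec.for_features(spiked, -1.5, "glucose")
        mat, _ = simulate_transcriptomics(design, eff, n_features=600, seed=13)
        de = transcript_nb(mat, "glucose")
        sets = [
            PathwaySet("target", gene_ids=frozenset(spiked)),
            PathwaySet("decoy", gene_ids=frozenset(f"t{i:04d}" for i in range(300, 340))),
        ]
        res = {r.pathway: r for r in consensus_enrichment(sets, de, n_perm=199, seed=1)}
        assert res["target"].significant
        assert res["target"].fgsea_down_p is not None  # direction split: down column
        assert res["target"].fgsea_up_p is None
        assert res["target"].boschloo_p <= res["target"].fisher_p
        # the conservative exact tests stay quiet on the decoy (the rank-based
        # test is the one prone to false positives, hence the consensus)
        assert res["decoy"].fisher_p > 0.05
        assert res["decoy"].boschloo_p > 0.05


def test_contingency_validation():
    with pytest.raises(ValueError):
        ContingencyTable(-1, 0, 0, 0)
    with pytest.raises(ValueError):
        PathwaySet("empty")
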