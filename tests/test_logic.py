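"""Deductive (logic) simulator: fixpoint examples, goal checks, oracle properties."""

import pytest

from gemscout import (
    GeneState,
    PhaseConfig,
    check_goal,
    medium_compounds,
    remove_reactions,
    simulate_activation,
)
from gemscout.network import MetabolicNetwork, Metabolite, Reaction
from gemscout.synth import make_random_network


def reachability_oracle(network, deleted=frozenset()):
    """Naive deductive-closure oracle, independent of the worklist engine.

    Recomputes directed rules from scratch each pass and scans every rule
    every time until nothing changes.
    """
    from gemscout.gpr import eval_gpr

    present = set(medium_compounds(network))
    active = set()
    while True:
        new_present = set(present)
        new_active = set(active)
        for r in network.reactions:
            if not eval_gpr(r.gpr, deleted):
                continue
            lb, ub = network.effective_bounds(r)
            if ub > 0 and r.substrates() <= present:
                new_active.add(r.id)
                new_present |= r.products()
            if lb < 0 and r.products() <= present:
                new_active.add(r.id)
                new_present |= r.substrates()
        if new_present == present and new_active == active:
            return frozenset(active), frozenset(present)
        present, active = new_present, new_active


class TestChain3Fixpoint:
    def test_intact_genes_reach_biomass(self, chain3):
        state = simulate_activation(chain3)
        assert state.active_reactions == {"R1", "R2", "R3"}
        assert {"B", "biomass"} <= state.present_metabolites
        assert check_goal(state, chain3)

    def test_gene_deletion_blocks_chain(self, chain3):
        state = simulate_activation(chain3, state=GeneState({"g2"}))
        assert state.active_reactions == {"R1"}
        assert "B" not in state.present_metabolites
        assert not check_goal(state, chain3)

    def test_reaction_removal_blocks_goal(self, chain3):
        state = simulate_activation(remove_reactions(chain3, {"R2"}))
        assert not check_goal(state, chain3)

    def test_empty_medium_vacuous_fixpoint(self, chain3):
        closed = MetabolicNetwork(
            metabolites=chain3.metabolites,
            reactions=chain3.reactions,
            genes=chain3.genes,
            objective_reaction=chain3.objective_reaction,
            medium={"R1": 0.0},
            goal_compounds=chain3.goal_compounds,
        )
        state = simulate_activation(closed)
        assert state.active_reactions == frozenset()
        assert state.present_metabolites == frozenset()

    def test_empty_goal_is_vacuously_met(self, chain3):
        empty_goal = MetabolicNetwork(
            metabolites=chain3.metabolites,
            reactions=chain3.reactions,
            genes=chain3.genes,
            objective_reaction="R3",
            medium=chain3.medium,
            goal_compounds=frozenset(),
        )
        state = simulate_activation(remove_reactions(empty_goal, {"R1"}))
        assert check_goal(state, empty_goal)


def test_toy9_phase_contrast(toy9):
    glc = simulate_activation(toy9, PhaseConfig.glucose())
    eth = simulate_activation(toy9, PhaseConfig.ethanol())
    # fermentative branch runs only on glucose; ethanol catabolism on both
    assert "PDC" in glc.active_reactions
    assert "PDC" not in eth.active_reactions
    assert {"ETHt", "ADH", "ALD", "GLX"} <= eth.active_reactions
    assert check_goal(glc, toy9) and check_goal(eth, toy9)


def test_expressed_genes_rules(toy9):
    all_rule = simulate_activation(toy9, gene_expression_rule="all_gpr_genes")
    # deleting one isozyme: the other still carries the reaction
    deleted = simulate_activation(toy9, state=GeneState({"g_adh1"}))
    assert "ADH" in deleted.active_reactions
    assert "g_adh1" not in deleted.expressed_genes
    assert "g_adh2" in deleted.expressed_genes
    sat = simulate_activation(toy9, gene_expression_rule="satisfied_leaves")
    assert sat.expressed_genes <= all_rule.expressed_genes


def test_deleted_gene_must_exist(toy9):
    with pytest.raises(ValueError, match="ghost"):
        simulate_activation(toy9, state=GeneState({"ghost"}))


def test_presence_state_invariant(toy9):
    state = simulate_activation(toy9)
    gpr_union = frozenset().union(
        *(toy9.reaction(r).genes for r in state.active_reactions)
    )
    assert state.expressed_genes <= gpr_union
    for rid in state.active_reactions:
        r = toy9.reaction(rid)
        lb, ub = toy9.effective_bounds(r)
        ok_fwd = ub > 0 and r.substrates() <= state.present_metabolites
        ok_bwd = lb < 0 and r.products() <= state.present_metabolites
        assert ok_fwd or ok_bwd


@pytest.mark.parametrize("seed", range(200))
def test_matches_reachability_oracle(seed):
    net = make_random_network(seed)
    deleted = frozenset(f"g{i}" for i in range(seed % 4))
    state = simulate_activation(net, state=GeneState(deleted & net.genes))
    oracle_active, oracle_present = reachability_oracle(net, deleted & net.genes)
    assert state.active_reactions == oracle_active
    assert state.present_metabolites == oracle_present


@pytest.mark.parametrize("seed", range(40))
def test_monotonicity_under_deletion_and_medium(seed):
    net = make_random_network(seed, n_reactions=12)
    base = simulate_activation(net)
    # deleting genes never enlarges presence
    smaller = simulate_activation(net, state=GeneState(frozenset(["g0", "g1"])))
    assert smaller.active_reactions <= base.active_reactions
    assert smaller.present_metabolites <= base.present_metabolites
    assert smaller.expressed_genes <= base.expressed_genes
    # removing reactions never enlarges presence
    victim = sorted(net.reaction_ids - {"UP0"})[seed % (len(net.reactions) - 1)]
    cut = simulate_activation(remove_reactions(net, {victim}))
    assert cut.active_reactions <= base.active_reactions
    assert cut.present_metabolites <= base.present_metabolites
    # enlarging the medium never shrinks presence
    richer_net = MetabolicNetwork(
        metabolites=net.metabolites
        + (Metabolite("mseed", compartment="e", boundary=True),),
        reactions=net.reactions + (Reaction("UPx", {"mseed": -1, "m2": 1}, 0, 1000),),
        genes=net.genes,
        medium={**net.medium, "UPx": 5.0},
    )
    richer = simulate_activation(richer_net)
    assert base.active_reactions <= richer.active_reactions
    assert base.present_metabolites <= richer.present_metabolites
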