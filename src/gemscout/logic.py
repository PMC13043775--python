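"""Qualitative metabolic simulation by logical deduction.

A genome-scale model can be read as a set of definite Horn clauses: a
reaction direction *fires* when all of its consumed metabolites are
available and its GPR is satisfied, making its products available.  The
least fixpoint of these rules — computed here by forward chaining rather
than a theorem prover, which yields the identical deductive closure for
Horn clauses — is the set of activated reactions, present metabolites and
expressed genes.  Output is binary/qualitative: presence, not quantity;
stoichiometric coefficients are ignored.

Reversible reactions are split into two directed rules, both gated by the
same GPR; a direction exists only if its flux bound allows it (forward if
the effective upper bound is positive, backward if the lower bound is
negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .gpr import eval_gpr, gpr_genes, satisfied_leaves
from .network import MetabolicNetwork, PhaseConfig, apply_phase

__all__ = [
    "GeneState",
    "PresenceState",
    "evaluate_gpr",
    "medium_compounds",
    "simulate_activation",
    "check_goal",
]


@dataclass(frozen=True)
class GeneState:
    """Which genes are deleted in the simulated strain."""

    deleted_genes: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "deleted_genes", frozenset(self.deleted_genes))


@dataclass(frozen=True)
class PresenceState:
    """Binary activation of reactions, metabolites and genes from one simulation."""

    active_reactions: frozenset
    present_metabolites: frozenset
    expressed_genes: frozenset
    phase: str = "glucose"
    source: str = "logic"


def evaluate_gpr(expr, deleted=frozenset()) -> bool:
    """True iff the GPR is satisfied with ``deleted`` genes false, others true."""
    return eval_gpr(expr, deleted)


def medium_compounds(network: MetabolicNetwork) -> frozenset:
    """Boundary metabolites available from the medium.

    A boundary metabolite counts as available when some reaction direction
    with positive capacity consumes it — i.e. an uptake route exists.
    """
    boundary = {m.id for m in network.metabolites if m.boundary}
    present = set()
    for r in network.reactions:
        lb, ub = network.effective_bounds(r)
        if ub > 0:
            present |= r.substrates() & boundary
        if lb < 0:
            present |= r.products() & boundary
    return frozenset(present)


def simulate_activation(
    network: MetabolicNetwork,
    cfg: PhaseConfig | None = None,
    state: GeneState | None = None,
    gene_expression_rule: str = "all_gpr_genes",
) -> PresenceState:
    """Least-fixpoint deduction of activated reactions/metabolites/genes.

    Present metabolites start from the medium; a reaction direction becomes
    active when all its substrates are present and its GPR evaluates true
    given the deleted genes.  Iteration order does not affect the result
    (monotone rules).  ``gene_expression_rule`` selects which GPR genes of
    an active reaction count as expressed: all non-deleted genes of the
    rule (default) or only leaves on satisfied branches.
    """
    if cfg is not None:
        network = apply_phase(network, cfg)
    state = state or GeneState()
    deleted = state.deleted_genes
    unknown = sorted(deleted - network.genes)
    if unknown:
        raise ValueError(f"deleted genes not in network: {unknown}")
    if gene_expression_rule not in ("all_gpr_genes", "satisfied_leaves"):
        raise ValueError(f"unknown gene_expression_rule {gene_expression_rule!r}")

    # directed rules: (reaction, substrates, products)
    rules = []
    for r in network.reactions:
        if not eval_gpr(r.gpr, deleted):
            continue
        lb, ub = network.effective_bounds(r)
        if ub > 0:
            rules.append((r, r.substrates(), r.products()))
        if lb < 0:
            rules.append((r, r.products(), r.substrates()))

    present = set(medium_compounds(network))
    active: set = set()
    pending = list(rules)
    while pending:  # each sweep fires >=1 rule, so <= |rules|+1 sweeps total
        still = []
        fired = False
        for rule in pending:
            r, subs, prods = rule
            if subs <= present:
                active.add(r.id)
                present |= prods
                fired = True
            else:
                still.append(rule)
        if not fired:
            break
        pending = still

    expressed: set = set()
    for rid in active:
        r = network.reaction(rid)
        if gene_expression_rule == "all_gpr_genes":
            expressed |= gpr_genes(r.gpr) - deleted
        else:
            expressed |= satisfied_leaves(r.gpr, deleted)

    return PresenceState(
        active_reactions=frozenset(active),
        present_metabolites=frozenset(present),
        expressed_genes=frozenset(expressed),
        phase=cfg.phase if cfg is not None else "glucose",
        source="logic",
    )


def check_goal(state: PresenceState, network: MetabolicNetwork) -> bool:
    """True iff every goal compound (essential for growth) was deduced present."""
    return network.goal_compounds <= state.present_metabolites
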