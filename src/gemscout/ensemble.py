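"""Stochastic pathway-disruption ensemble.

A regulatory hypothesis about a gene that is absent from the metabolic
model (e.g. a putative transcription factor) cannot be simulated as a
gene knockout.  Instead the hypothesis is instantiated by repeatedly
removing a random subset of reactions from the pathways it is presumed to
regulate, simulating growth, and aggregating presence over the ensemble:

* each of ``n_sim`` draws removes ``k`` reactions, ``k`` uniform on
  ``[r_min, r_max]``, chosen uniformly without replacement from the
  target set (defaults 500 draws, 5..12 reactions);
* per entity (gene or metabolite), ``freq`` is the fraction of disrupted
  simulations in which it was present, ``delta = freq - baseline`` with
  baseline the undisrupted presence (0/1), and the predicted direction is
  the sign of ``delta`` outside a dead-zone ``tau`` (default 0).

Note the framing assumes disruption (a negative effect) of the targeted
pathways; a positively regulated hypothesis needs a different target set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .fba import FbaConfig, extract_presence, solve_fba
from .logic import GeneState, PresenceState, check_goal, simulate_activation
from .network import MetabolicNetwork, PhaseConfig, apply_phase, remove_reactions

__all__ = [
    "DisruptionConfig",
    "EnsemblePrediction",
    "run_ensemble",
    "classify_direction",
    "predicted_differential_count",
]


@dataclass(frozen=True)
class DisruptionConfig:
    target_reactions: frozenset
    n_sim: int = 500
    r_min: int = 5
    r_max: int = 12
    simulator: str = "logic"  # "logic" | "fba"
    seed: int = 0
    nongrowth_policy: str = "keep"  # "keep" | "reject_resample" | "flag"
    direction_tolerance: float = 0.0  # dead-zone tau for classify_direction
    fba: FbaConfig = field(default_factory=FbaConfig)

    def __post_init__(self):
        object.__setattr__(self, "target_reactions", frozenset(self.target_reactions))
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if not (1 <= self.r_min <= self.r_max):
            raise ValueError("need 1 <= r_min <= r_max")
        if self.r_max > len(self.target_reactions):
            raise ValueError(
                f"r_max {self.r_max} exceeds target set size {len(self.target_reactions)}"
            )
        if self.simulator not in ("logic", "fba"):
            raise ValueError(f"unknown simulator {self.simulator!r}")
        if self.nongrowth_policy not in ("keep", "reject_resample", "flag"):
            raise ValueError(f"unknown nongrowth_policy {self.nongrowth_policy!r}")
        if self.direction_tolerance < 0:
            raise ValueError("direction_tolerance must be >= 0")


@dataclass
class EnsemblePrediction:
    """Per-entity aggregate of the ensemble plus run metadata.

    ``entities`` columns: entity_id, kind ("gene"/"metabolite"), baseline,
    freq, delta, direction.
    """

    entities: pd.DataFrame
    phase: str
    simulator: str
    n_sim: int
    growth_fraction: float
    baseline_growth: bool
    config: DisruptionConfig
    nongrowth_draws: Optional[list] = None  # filled under the "flag" policy

    def frame(self, kind: Optional[str] = None) -> pd.DataFrame:
        if kind is None:
            return self.entities
        return self.entities[self.entities["kind"] == kind]

    def to_tsv(self, path) -> None:
        self.entities.to_csv(path, sep="\t", index=False)


def classify_direction(delta: float, tau: float = 0.0) -> str:
    """Sign classification of a presence-frequency difference with dead-zone tau."""
    if not -1.0 - 1e-12 <= delta <= 1.0 + 1e-12:
        raise ValueError(f"|delta| must be <= 1, got {delta}")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if delta > tau:
        return "up"
    if delta < -tau:
        return "down"
    return "none"


def _simulate(network: MetabolicNetwork, simulator: str, fba_cfg: FbaConfig):
    """One growth simulation -> (PresenceState, grew)."""
    if simulator == "logic":
        state = simulate_activation(network)
        return state, check_goal(state, network)
    sol = solve_fba(network)
    if sol.status != "optimal" or sol.objective_value <= fba_cfg.presence_threshold:
        # an infeasible/zero-growth model supports no flux: empty presence
        empty = PresenceState(frozenset(), frozenset(), frozenset(), sol.phase, "fba")
        if sol.status != "optimal":
            return empty, False
        return extract_presence(sol, network, fba_cfg), False
    return extract_presence(sol, network, fba_cfg), True


def run_ensemble(
    network: MetabolicNetwork,
    cfg: Optional[PhaseConfig],
    dcfg: DisruptionConfig,
) -> EnsemblePrediction:
    """Run the disruption ensemble and aggregate per-entity predictions."""
    if cfg is not None:
        network = apply_phase(network, cfg)
    unknown = sorted(dcfg.target_reactions - network.reaction_ids)
    if unknown:
        raise ValueError(f"target reactions not in network: {unknown}")

    genes = sorted(network.genes)
    mets = sorted(network.metabolite_ids)
    baseline_state, baseline_growth = _simulate(network, dcfg.simulator, dcfg.fba)

    rng = np.random.default_rng(dcfg.seed)
    target = sorted(dcfg.target_reactions)
    gene_counts = dict.fromkeys(genes, 0)
    met_counts = dict.fromkeys(mets, 0)
    growth_count = 0
    nongrowth_draws: list = []

    def draw():
        # subset size first, then members: documented draw order
        k = int(rng.integers(dcfg.r_min, dcfg.r_max + 1))
        members = rng.choice(target, size=k, replace=False)
        return frozenset(members.tolist())

    max_attempts = 1000 * dcfg.n_sim
    attempts = 0
    done = 0
    while done < dcfg.n_sim:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "reject_resample exhausted: target disruption almost always kills growth"
            )
        removed = draw()
        state, grew = _simulate(remove_reactions(network, removed), dcfg.simulator, dcfg.fba)
        if not grew and dcfg.nongrowth_policy == "reject_resample":
            continue
        done += 1
        if grew:
            growth_count += 1
        elif dcfg.nongrowth_policy == "flag":
            nongrowth_draws.append(sorted(removed))
        for g in state.expressed_genes:
            gene_counts[g] += 1
        for m in state.present_metabolites:
            met_counts[m] += 1

    rows = []
    for eid, kind, counts, base_set in (
        *((g, "gene", gene_counts, baseline_state.expressed_genes) for g in genes),
        *((m, "metabolite", met_counts, baseline_state.present_metabolites) for m in mets),
    ):
        baseline = 1.0 if eid in base_set else 0.0
        freq = counts[eid] / dcfg.n_sim
        delta = freq - baseline
        rows.append(
            {
                "entity_id": eid,
                "kind": kind,
                "baseline": baseline,
                "freq": freq,
                "delta": delta,
                "direction": classify_direction(delta, dcfg.direction_tolerance),
            }
        )
    entities = pd.DataFrame(rows, columns=["entity_id", "kind", "baseline", "freq", "delta", "direction"])
    return EnsemblePrediction(
        entities=entities,
        phase=cfg.phase if cfg is not None else "glucose",
        simulator=dcfg.simulator,
        n_sim=dcfg.n_sim,
        growth_fraction=growth_count / dcfg.n_sim,
        baseline_growth=baseline_growth,
        config=dcfg,
        nongrowth_draws=nongrowth_draws if dcfg.nongrowth_policy == "flag" else None,
    )


def predicted_differential_count(pred: EnsemblePrediction) -> dict:
    """Number of entities predicted differential (direction != none), per class."""
    diff = pred.entities[pred.entities["direction"] != "none"]
    return {
        "gene": int((diff["kind"] == "gene").sum()),
        "metabolite": int((diff["kind"] == "metabolite").sum()),
    }
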