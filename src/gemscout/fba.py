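"""Flux balance analysis with threshold-based presence extraction.

FBA maximises the flux through a growth objective subject to steady-state
mass balance (Sv = 0 over non-boundary metabolites) and flux bounds.  The
LP is solved with HiGHS via :func:`scipy.optimize.linprog`, with a fixed
variable order (the network's reaction order) so repeated runs agree
bit-wise.  Presence is binary: a reaction is active when its absolute
flux exceeds the presence threshold (default 1e-9 mmol/(gDW*h), strict
inequality); the metabolites and GPR genes of active reactions are
present/expressed.

FBA optima are typically degenerate; the default extraction reads one
deterministic solution.  An optional flux-variability mode counts an
entity as present if it is active in *any* optimal solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import linprog

from .gpr import gpr_genes
from .logic import PresenceState
from .network import MetabolicNetwork, PhaseConfig, apply_phase

__all__ = ["FbaConfig", "FluxSolution", "FbaError", "solve_fba", "extract_presence"]


class FbaError(RuntimeError):
    """Solver-level failure (unbounded objective, missing objective, ...)."""


@dataclass(frozen=True)
class FbaConfig:
    presence_threshold: float = 1e-9  # mmol/(gDW*h)
    solver_tolerance: float = 1e-9
    fva_presence: bool = False  # presence = active in any optimal solution

    def __post_init__(self):
        if self.presence_threshold <= 0:
            raise ValueError("presence_threshold must be positive")


@dataclass(frozen=True)
class FluxSolution:
    fluxes: Mapping[str, float]
    objective_value: float
    status: str  # "optimal" | "infeasible"
    phase: str = "glucose"

    def __post_init__(self):
        object.__setattr__(self, "fluxes", dict(self.fluxes))


def _lp(network: MetabolicNetwork, c: np.ndarray, min_objective=None):
    S, _rows, cols = network.stoichiometric_matrix()
    bounds = [network.effective_bounds(r) for r in network.reactions]
    A_ub = b_ub = None
    if min_objective is not None:
        row, rhs = min_objective  # require row . v >= rhs
        A_ub = -row[None, :]
        b_ub = np.array([-rhs])
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=S, b_eq=np.zeros(S.shape[0]),
        bounds=bounds, method="highs",
    )
    return res, cols


def solve_fba(network: MetabolicNetwork, cfg: Optional[PhaseConfig] = None) -> FluxSolution:
    """Maximise the growth objective; return fluxes or an infeasible status."""
    if cfg is not None:
        network = apply_phase(network, cfg)
    if network.objective_reaction is None or network.objective_reaction not in network.reaction_ids:
        raise FbaError(f"objective reaction {network.objective_reaction!r} not in network")
    cols = [r.id for r in network.reactions]
    c = np.zeros(len(cols))
    c[cols.index(network.objective_reaction)] = -1.0  # linprog minimises
    res, cols = _lp(network, c)
    phase = cfg.phase if cfg is not None else "glucose"
    if res.status == 3:
        raise FbaError("objective is unbounded; an exchange bound is missing")
    if res.status != 0:
        return FluxSolution(fluxes={}, objective_value=float("nan"), status="infeasible", phase=phase)
    return FluxSolution(
        fluxes=dict(zip(cols, res.x)),
        objective_value=float(-res.fun),
        status="optimal",
        phase=phase,
    )


def _fva_active(network: MetabolicNetwork, objective_value: float, threshold: float) -> frozenset:
    """Reactions able to carry |flux| > threshold in some optimal solution."""
    cols = [r.id for r in network.reactions]
    obj_row = np.zeros(len(cols))
    obj_row[cols.index(network.objective_reaction)] = 1.0
    active = set()
    for j, rid in enumerate(cols):
        c = np.zeros(len(cols))
        c[j] = 1.0
        hit = False
        floor = objective_value - 1e-9
        for sign in (1.0, -1.0):
            res, _ = _lp(network, sign * c, min_objective=(obj_row, floor))
            if res.status == 0 and abs(res.x[j]) > threshold:
                hit = True
                break
        if hit:
            active.add(rid)
    return frozenset(active)


def extract_presence(
    sol: FluxSolution,
    network: MetabolicNetwork,
    cfg: FbaConfig = FbaConfig(),
) -> PresenceState:
    """Binary presence from a flux solution: |v| strictly above the threshold."""
    if sol.status != "optimal":
        raise FbaError("cannot extract presence from a non-optimal solution")
    if cfg.fva_presence:
        active = _fva_active(network, sol.objective_value, cfg.presence_threshold)
    else:
        active = frozenset(
            rid for rid, v in sol.fluxes.items() if abs(v) > cfg.presence_threshold
        )
    mets: set = set()
    genes: set = set()
    for rid in active:
        r = network.reaction(rid)
        mets |= set(r.stoichiometry)
        genes |= gpr_genes(r.gpr)
    return PresenceState(
        active_reactions=active,
        present_metabolites=frozenset(mets),
        expressed_genes=frozenset(genes),
        phase=sol.phase,
        source="fba",
    )
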