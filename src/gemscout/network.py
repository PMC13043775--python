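"""Metabolic-network data model and JSON I/O.

The network is a small, validated stand-in for a consensus genome-scale
metabolic model (GEM): metabolites with compartments, reactions with
stoichiometry, flux bounds and GPR rules, a growth objective, a growth
medium, and a set of goal compounds for the qualitative simulator.

JSON dialect (``format_version`` ``"1.0"``)::

    {
      "format_version": "1.0",
      "id": "toy9",
      "metabolites": [
        {"id": "glc_e", "name": "glucose", "compartment": "e",
         "kegg_id": "C00031", "boundary": true}, ...
      ],
      "reactions": [
        {"id": "GLY", "stoichiometry": {"glc_c": -1, "pyr_c": 2},
         "lower_bound": 0, "upper_bound": 1000,
         "gpr": "g_glk and g_pfk", "pathways": ["glycolysis"]}, ...
      ],
      "genes": ["g_glk", ...],
      "objective": "BIOMASS",
      "medium": {"GLCt": 10.0},
      "goal_compounds": ["biomass_c"]
    }

Conventions
-----------
* Metabolites flagged ``boundary`` sit outside the mass balance (the SBML
  ``boundaryCondition`` analogue); they represent the extracellular pool.
* Uptake reactions are written *import-forward*: the forward direction
  consumes the boundary metabolite.  ``medium`` caps the forward capacity
  of the listed reactions, so a medium value of 0 forbids uptake while
  leaving secretion (negative flux) to the reaction's lower bound.
* Bounds default to (-1000, 1000) for reversible and (0, 1000) for
  irreversible reactions, mirroring GEM conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np

from .gpr import GprNode, gpr_genes, gpr_to_string, parse_gpr

FORMAT_VERSION = "1.0"

DEFAULT_BOUND = 1000.0

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "PhaseConfig",
    "NetworkFormatError",
    "NetworkValidationError",
    "load_network",
    "write_network",
    "network_from_dict",
    "network_to_dict",
    "apply_phase",
    "remove_reactions",
]


class NetworkFormatError(ValueError):
    """A network file does not conform to the JSON dialect."""


class NetworkValidationError(ValueError):
    """A structurally parsed network violates an invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    kegg_id: Optional[str] = None
    boundary: bool = False

    def __post_init__(self):
        if not self.id:
            raise NetworkValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise NetworkValidationError(f"metabolite {self.id}: compartment must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """One reaction: stoichiometry (negative = consumed), bounds, GPR, pathway labels."""

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: GprNode = None
    pathways: frozenset = frozenset()

    def __post_init__(self):
        if not self.stoichiometry:
            raise NetworkValidationError(f"reaction {self.id}: stoichiometry must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise NetworkValidationError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > upper_bound {self.upper_bound}"
            )
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))
        object.__setattr__(self, "pathways", frozenset(self.pathways))

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def genes(self) -> frozenset:
        return gpr_genes(self.gpr)

    def substrates(self) -> frozenset:
        return frozenset(m for m, c in self.stoichiometry.items() if c < 0)

    def products(self) -> frozenset:
        return frozenset(m for m, c in self.stoichiometry.items() if c > 0)


@dataclass(frozen=True)
class MetabolicNetwork:
    metabolites: tuple
    reactions: tuple
    genes: frozenset = frozenset()
    objective_reaction: Optional[str] = None
    medium: Mapping[str, float] = field(default_factory=dict)
    goal_compounds: frozenset = frozenset()
    id: str = "network"

    def __post_init__(self):
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        object.__setattr__(self, "genes", frozenset(self.genes))
        object.__setattr__(self, "medium", dict(self.medium))
        object.__setattr__(self, "goal_compounds", frozenset(self.goal_compounds))
        met_ids = [m.id for m in self.metabolites]
        if len(met_ids) != len(set(met_ids)):
            dupes = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise NetworkValidationError(f"duplicate metabolite ids: {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(rxn_ids) != len(set(rxn_ids)):
            dupes = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise NetworkValidationError(f"duplicate reaction ids: {dupes}")
        met_set = set(met_ids)
        for r in self.reactions:
            missing = sorted(set(r.stoichiometry) - met_set)
            if missing:
                raise NetworkValidationError(
                    f"reaction {r.id} references undeclared metabolites: {missing}"
                )
            undeclared = sorted(r.genes - self.genes)
            if undeclared:
                raise NetworkValidationError(
                    f"reaction {r.id} GPR references undeclared genes: {undeclared}"
                )
        rxn_set = set(rxn_ids)
        bad_medium = sorted(set(self.medium) - rxn_set)
        if bad_medium:
            raise NetworkValidationError(f"medium references unknown reactions: {bad_medium}")
        bad_goal = sorted(self.goal_compounds - met_set)
        if bad_goal:
            raise NetworkValidationError(f"goal_compounds reference unknown metabolites: {bad_goal}")

    # -- lookups -----------------------------------------------------------
    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def metabolite_ids(self) -> frozenset:
        return frozenset(m.id for m in self.metabolites)

    @property
    def reaction_ids(self) -> frozenset:
        return frozenset(r.id for r in self.reactions)

    def effective_bounds(self, rxn: Reaction) -> tuple[float, float]:
        """Flux bounds with the medium's uptake cap applied (import-forward)."""
        ub = rxn.upper_bound
        if rxn.id in self.medium:
            ub = min(ub, float(self.medium[rxn.id]))
        return (rxn.lower_bound, ub)

    def pathway_reactions(self, pathway: str) -> frozenset:
        return frozenset(r.id for r in self.reactions if pathway in r.pathways)

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list, list]:
        """Dense S over non-boundary metabolites (rows) x reactions (cols)."""
        rows = [m.id for m in self.metabolites if not m.boundary]
        cols = [r.id for r in self.reactions]
        idx = {m: i for i, m in enumerate(rows)}
        S = np.zeros((len(rows), len(cols)))
        for j, r in enumerate(self.reactions):
            for m, coef in r.stoichiometry.items():
                if m in idx:
                    S[idx[m], j] = coef
        return S, rows, cols


@dataclass(frozen=True)
class PhaseConfig:
    """Growth phase of the diauxic experiment, as exchange-bound overrides.

    Overrides map reaction id -> (lower_bound, upper_bound).  The glucose
    phase is the network default (glucose-rich medium); the ethanol phase
    closes the glucose exchange entirely and allows ethanol uptake of 1.0.
    """

    phase: str = "glucose"
    exchange_overrides: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        if self.phase not in ("glucose", "ethanol"):
            raise NetworkValidationError(f"unknown phase {self.phase!r}")
        object.__setattr__(
            self,
            "exchange_overrides",
            {k: (float(v[0]), float(v[1])) for k, v in dict(self.exchange_overrides).items()},
        )

    @classmethod
    def glucose(cls) -> "PhaseConfig":
        return cls(phase="glucose")

    @classmethod
    def ethanol(
        cls,
        glucose_exchange: str = "GLCt",
        ethanol_exchange: str = "ETHt",
        ethanol_uptake: float = 1.0,
        ethanol_lower: float = -DEFAULT_BOUND,
    ) -> "PhaseConfig":
        return cls(
            phase="ethanol",
            exchange_overrides={
                glucose_exchange: (0.0, 0.0),
                ethanol_exchange: (ethanol_lower, ethanol_uptake),
            },
        )


# -- operations ------------------------------------------------------------

def apply_phase(network: MetabolicNetwork, cfg: PhaseConfig) -> MetabolicNetwork:
    """Return a copy of the network with the phase's exchange bounds applied.

    The overridden reactions' bounds are replaced outright and the medium
    entry (if any) is updated to the new forward capacity, so the effective
    bounds equal the override.  Idempotent for a fixed config.
    """
    missing = sorted(set(cfg.exchange_overrides) - network.reaction_ids)
    if missing:
        raise NetworkValidationError(f"phase overrides name unknown reactions: {missing}")
    new_reactions = []
    for r in network.reactions:
        if r.id in cfg.exchange_overrides:
            lb, ub = cfg.exchange_overrides[r.id]
            r = replace(r, lower_bound=lb, upper_bound=ub)
        new_reactions.append(r)
    medium = dict(network.medium)
    for rid, (_lb, ub) in cfg.exchange_overrides.items():
        if rid in medium:
            medium[rid] = ub
    return replace(network, reactions=tuple(new_reactions), medium=medium)


def remove_reactions(network: MetabolicNetwork, ids: Iterable[str]) -> MetabolicNetwork:
    """Copy of the network without the named reactions (knockout by removal)."""
    ids = frozenset(ids)
    unknown = sorted(ids - network.reaction_ids)
    if unknown:
        raise NetworkValidationError(f"cannot remove unknown reactions: {unknown}")
    reactions = tuple(r for r in network.reactions if r.id not in ids)
    medium = {k: v for k, v in network.medium.items() if k not in ids}
    return replace(network, reactions=reactions, medium=medium)


# -- JSON I/O --------------------------------------------------------------

def network_from_dict(data: dict) -> MetabolicNetwork:
    if not isinstance(data, dict):
        raise NetworkFormatError("network document must be a JSON object")
    version = data.get("format_version")
    if version != FORMAT_VERSION:
        raise NetworkFormatError(
            f"unsupported format_version {version!r} (expected {FORMAT_VERSION!r})"
        )
    for key in ("metabolites", "reactions"):
        if key not in data or not isinstance(data[key], list):
            raise NetworkFormatError(f"missing or non-list field {key!r}")
    try:
        metabolites = tuple(
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                kegg_id=m.get("kegg_id"),
                boundary=bool(m.get("boundary", False)),
            )
            for m in data["metabolites"]
        )
    except KeyError as e:
        raise NetworkFormatError(f"metabolite entry missing field {e}") from e
    reactions = []
    for rd in data["reactions"]:
        try:
            stoich = {str(k): float(v) for k, v in rd["stoichiometry"].items()}
            reversible_default = -DEFAULT_BOUND if rd.get("reversible") else 0.0
            reactions.append(
                Reaction(
                    id=rd["id"],
                    stoichiometry=stoich,
                    lower_bound=float(rd.get("lower_bound", reversible_default)),
                    upper_bound=float(rd.get("upper_bound", DEFAULT_BOUND)),
                    gpr=parse_gpr(rd.get("gpr", "")),
                    pathways=frozenset(rd.get("pathways", ())),
                )
            )
        except KeyError as e:
            raise NetworkFormatError(f"reaction entry missing field {e}") from e
        except (TypeError, ValueError) as e:
            raise NetworkFormatError(f"bad reaction entry {rd.get('id', '?')!r}: {e}") from e
    genes = frozenset(data.get("genes", ()))
    declared = frozenset().union(*(r.genes for r in reactions)) if reactions else frozenset()
    genes = genes | declared  # genes used in GPRs are implicitly declared
    net = MetabolicNetwork(
        metabolites=metabolites,
        reactions=tuple(reactions),
        genes=genes,
        objective_reaction=data.get("objective"),
        medium={str(k): float(v) for k, v in data.get("medium", {}).items()},
        goal_compounds=frozenset(data.get("goal_compounds", ())),
        id=data.get("id", "network"),
    )
    if net.objective_reaction is not None and net.objective_reaction not in net.reaction_ids:
        raise NetworkValidationError(
            f"objective reaction {net.objective_reaction!r} not in network"
        )
    return net


def network_to_dict(network: MetabolicNetwork) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "id": network.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"kegg_id": m.kegg_id} if m.kegg_id else {}),
                **({"boundary": True} if m.boundary else {}),
            }
            for m in network.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": gpr_to_string(r.gpr),
                "pathways": sorted(r.pathways),
            }
            for r in network.reactions
        ],
        "genes": sorted(network.genes),
        "objective": network.objective_reaction,
        "medium": dict(network.medium),
        "goal_compounds": sorted(network.goal_compounds),
    }


def load_network(path) -> MetabolicNetwork:
    """Load and validate a network from the JSON dialect."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as e:
            raise NetworkFormatError(f"{path}: not valid JSON ({e})") from e
    return network_from_dict(data)


def write_network(network: MetabolicNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(network), fh, indent=1, sort_keys=False)
        fh.write("\n")
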