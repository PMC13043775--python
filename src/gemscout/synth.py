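"""Synthetic inputs for every pipeline stage.

Nothing here requires a download: a toy genome-scale network stands in
for a consensus yeast model, and the omics/growth generators emit data
with the statistical structure the analysis stages assume, plus ground
truth, so recovery, calibration and power are all measurable.

Defaults encode the physiology the pipeline targets: two strains
(reference and deletion mutant) in a diauxic low-glucose batch culture,
OD560 sampled every 20 minutes for 24 h from an initial OD of 0.05,
reference mu 0.402 h^-1 vs mutant 0.450 h^-1, 24-h ODs 0.265 vs 0.338;
negative-binomial transcript counts (2000 features); log-normal
metabolite intensities with heavy detection dropout (85 predicted -> ~14
identified -> ~9 passing QC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .differential import OmicsMatrix
from .gpr import parse_gpr
from .network import MetabolicNetwork, Metabolite, Reaction

__all__ = [
    "SyntheticDesign",
    "EffectSpec",
    "make_toy_network",
    "make_chain3",
    "make_random_network",
    "simulate_growth_curves",
    "simulate_transcriptomics",
    "simulate_metabolomics",
]

# metabolite identification/QC attrition observed in untargeted LC-MS of
# short-chain organic acids: 85 predicted -> 14 identified -> 9 pass QC
DEFAULT_DETECTION_DROPOUT = 1.0 - 14.0 / 85.0
DEFAULT_QC_DROPOUT = 1.0 - 9.0 / 14.0


@dataclass(frozen=True)
class SyntheticDesign:
    replicates: int = 4
    strains: tuple = ("reference", "mutant")
    phases: tuple = ("glucose", "ethanol")
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per group")


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effects: feature -> phase -> log2FC(mutant/reference)."""

    transcript_log2fc: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    metabolite_log2fc: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    transcript_dispersion: float = 0.05
    metabolite_sd: float = 0.5  # log2-scale replicate noise
    detection_dropout: float = DEFAULT_DETECTION_DROPOUT
    qc_dropout: float = DEFAULT_QC_DROPOUT

    def __post_init__(self):
        for name in ("detection_dropout", "qc_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        object.__setattr__(self, "transcript_log2fc", dict(self.transcript_log2fc))
        object.__setattr__(self, "metabolite_log2fc", dict(self.metabolite_log2fc))

    @staticmethod
    def for_features(
        features: Sequence[str],
        log2fc: float,
        phase: str = "glucose",
        **kwargs,
    ) -> "EffectSpec":
        """Spike the same log2FC on a set of transcript features in one phase."""
        return EffectSpec(
            transcript_log2fc={f: {phase: log2fc} for f in features}, **kwargs
        )


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def make_chain3() -> MetabolicNetwork:
    """Micro-fixture: linear chain A_ext -> A -> B -> biomass, one gene per step."""
    return MetabolicNetwork(
        id="chain3",
        metabolites=(
            Metabolite("A_ext", "A (extracellular)", "e", boundary=True),
            Metabolite("A", "A", "c"),
            Metabolite("B", "B", "c"),
            Metabolite("biomass", "biomass", "e", boundary=True),
        ),
        reactions=(
            Reaction("R1", {"A_ext": -1, "A": 1}, 0, 1000, parse_gpr("g1")),
            Reaction("R2", {"A": -1, "B": 1}, 0, 1000, parse_gpr("g2")),
            Reaction("R3", {"B": -1, "biomass": 1}, 0, 1000, parse_gpr("g3")),
        ),
        genes=frozenset({"g1", "g2", "g3"}),
        objective_reaction="R3",
        medium={"R1": 10.0},
        goal_compounds=frozenset({"biomass"}),
    )


def make_toy_network(seed: int = 0) -> MetabolicNetwork:
    """Deterministic toy yeast-like network ("toy9").

    Glucose and ethanol enter through import-forward transports; a
    glycolysis-like chain feeds pyruvate, a fermentation branch produces
    ethanol, an AND-gated entry guards a TCA-like cycle, and an ethanol
    catabolism route (with a glyoxylate-shunt-like anaplerosis) enables
    respiratory growth.  Biomass needs acetyl-CoA and oxaloacetate.
    ``seed`` is accepted for interface symmetry; the fixture is fixed.
    """
    del seed
    mets = (
        Metabolite("glc_e", "glucose (extracellular)", "e", kegg_id="C00031", boundary=True),
        Metabolite("glc_c", "glucose", "c", kegg_id="C00031"),
        Metabolite("pyr_c", "pyruvate", "c", kegg_id="C00022"),
        Metabolite("acald_c", "acetaldehyde", "c", kegg_id="C00084"),
        Metabolite("eth_c", "ethanol", "c", kegg_id="C00469"),
        Metabolite("eth_e", "ethanol (extracellular)", "e", kegg_id="C00469", boundary=True),
        Metabolite("accoa_c", "acetyl-CoA", "c", kegg_id="C00024"),
        Metabolite("oaa_c", "oxaloacetate", "c", kegg_id="C00036"),
        Metabolite("akg_c", "2-oxoglutarate", "c", kegg_id="C00026"),
        Metabolite("biomass_c", "biomass", "c", boundary=True),
    )
    R = Reaction
    rxns = (
        # import-forward exchanges; medium caps forward capacity
        R("GLCt", {"glc_e": -1, "glc_c": 1}, 0, 1000, parse_gpr("g_hxt"), {"glycolysis"}),
        R("ETHt", {"eth_e": -1, "eth_c": 1}, -1000, 1000, None,
          {"fermentation", "ethanol_catabolism"}),
        R("GLY", {"glc_c": -1, "pyr_c": 2}, 0, 1000, parse_gpr("g_glk and g_pfk"),
          {"glycolysis"}),
        R("PDC", {"pyr_c": -1, "acald_c": 1}, 0, 1000, parse_gpr("g_pdc"), {"fermentation"}),
        R("ADH", {"acald_c": -1, "eth_c": 1}, -1000, 1000, parse_gpr("g_adh1 or g_adh2"),
          {"fermentation", "ethanol_catabolism"}),
        R("ALD", {"acald_c": -1, "accoa_c": 1}, 0, 1000, parse_gpr("g_ald4 or g_ald6"),
          {"ethanol_catabolism"}),
        R("PYC", {"pyr_c": -1, "oaa_c": 1}, 0, 1000, parse_gpr("g_pyc1"), {"TCA"}),
        R("GLX", {"accoa_c": -2, "oaa_c": 1}, 0, 1000, parse_gpr("g_icl1"),
          {"ethanol_catabolism"}),
        R("TCA1", {"accoa_c": -1, "oaa_c": -1, "akg_c": 1}, 0, 1000,
          parse_gpr("g_cit1 and g_aco1"), {"TCA"}),
        R("TCA2", {"akg_c": -1, "oaa_c": 1}, 0, 1000, parse_gpr("g_kgd1"), {"TCA"}),
        R("BIOMASS", {"accoa_c": -1, "oaa_c": -1, "biomass_c": 1}, 0, 1000, None, frozenset()),
    )
    genes = frozenset(
        {"g_hxt", "g_glk", "g_pfk", "g_pdc", "g_adh1", "g_adh2", "g_ald4",
         "g_ald6", "g_pyc1", "g_icl1", "g_cit1", "g_aco1", "g_kgd1"}
    )
    return MetabolicNetwork(
        id="toy9",
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        objective_reaction="BIOMASS",
        medium={"GLCt": 10.0, "ETHt": 0.0},
        goal_compounds=frozenset({"biomass_c"}),
    )


def make_random_network(
    seed: int,
    n_reactions: int = 10,
    n_metabolites: int = 8,
    n_genes: int = 5,
    p_reversible: float = 0.2,
) -> MetabolicNetwork:
    """Random small network for property tests (logic-simulator oracle).

    Metabolite m0 is an external boundary seed with an uptake transport;
    remaining reactions connect random substrate/product pairs with
    random single-gene or two-gene GPRs.
    """
    rng = np.random.default_rng(seed)
    met_ids = [f"m{i}" for i in range(n_metabolites)]
    mets = [Metabolite("m0", compartment="e", boundary=True)] + [
        Metabolite(m, compartment="c") for m in met_ids[1:]
    ]
    genes = [f"g{i}" for i in range(n_genes)]
    rxns = [Reaction("UP0", {"m0": -1, "m1": 1}, 0, 1000, None)]
    for i in range(1, n_reactions):
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        subs = rng.choice(met_ids, size=n_sub, replace=False)
        prods = rng.choice([m for m in met_ids if m not in subs], size=n_prod, replace=False)
        stoich = {m: -1.0 for m in subs}
        stoich.update({m: 1.0 for m in prods})
        form = rng.choice(["none", "leaf", "and", "or"])
        if form == "none":
            gpr = None
        elif form == "leaf":
            gpr = str(rng.choice(genes))
        else:
            g1, g2 = rng.choice(genes, size=2, replace=False)
            gpr = parse_gpr(f"{g1} {form} {g2}")
        lb = -1000.0 if rng.random() < p_reversible else 0.0
        rxns.append(Reaction(f"R{i}", stoich, lb, 1000, gpr))
    return MetabolicNetwork(
        id=f"random{seed}",
        metabolites=tuple(mets),
        reactions=tuple(rxns),
        genes=frozenset(genes),
        objective_reaction=None,
        medium={"UP0": 10.0},
        goal_compounds=frozenset(),
    )


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

def _calibrate_logistic(mu: float, od_end: float, od0: float, horizon: float):
    """Solve (r, K) so the logistic curve has max d/dt ln(OD) = mu at t=0
    and reaches od_end at the horizon."""

    def od_at_end(K: float) -> float:
        r = mu / (1.0 - od0 / K)
        e = np.exp(r * horizon)
        return K * od0 * e / (K - od0 + od0 * e)

    K = brentq(lambda K: od_at_end(K) - od_end, od_end * (1 + 1e-9), 1e3, xtol=1e-14)
    r = mu / (1.0 - od0 / K)
    return r, K


def _logistic(times: np.ndarray, r: float, K: float, od0: float) -> np.ndarray:
    e = np.exp(r * times)
    return K * od0 * e / (K - od0 + od0 * e)


def _diauxic(times, r1, K1, od0, shift, r2, od_end, horizon):
    """Two logistic segments joined at the shift time (qualitative diauxie)."""
    seg1 = _logistic(times, r1, K1, od0)
    od_shift = _logistic(np.array([shift]), r1, K1, od0)[0]
    K2 = brentq(
        lambda K: _logistic(np.array([horizon - shift]), r2, K, od_shift)[0] - od_end,
        od_end * (1 + 1e-9),
        1e3,
    )
    seg2 = _logistic(np.clip(times - shift, 0, None), r2, K2, od_shift)
    return np.where(times < shift, seg1, seg2)


def simulate_growth_curves(
    mu_ref: float = 0.402,
    mu_mut: float = 0.450,
    od0: float = 0.05,
    od24_ref: float = 0.265,
    od24_mut: float = 0.338,
    noise_sd: float = 0.02,
    replicates: int = 16,
    interval_h: float = 1.0 / 3.0,
    duration_h: float = 24.0,
    diauxic: bool = False,
    shift_time_h: float = 12.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format growth table (well, strain, replicate, time_h, od560).

    The noise-free skeleton per strain is a logistic curve calibrated so
    its maximum specific growth rate equals ``mu`` and its OD at
    ``duration_h`` equals the stated 24-h OD; the diauxic option joins a
    second, slower logistic segment at the shift time with the same 24-h
    calibration.  Noise is multiplicative log-normal per measurement.
    """
    if mu_ref <= 0 or mu_mut <= 0:
        raise ValueError("growth rates must be positive")
    times = np.arange(0.0, duration_h + interval_h / 2, interval_h)
    rng = np.random.default_rng(seed)
    rows = []
    well = 0
    for strain, mu, od_end in (
        ("reference", mu_ref, od24_ref),
        ("mutant", mu_mut, od24_mut),
    ):
        if diauxic:
            r1, K1 = _calibrate_logistic(mu, od_end * 0.7, od0, shift_time_h)
            skeleton = _diauxic(times, r1, K1, od0, shift_time_h, 0.25 * r1, od_end, duration_h)
        else:
            r, K = _calibrate_logistic(mu, od_end, od0, duration_h)
            skeleton = _logistic(times, r, K, od0)
        for rep in range(1, replicates + 1):
            noise = rng.normal(0.0, noise_sd, size=times.size) if noise_sd > 0 else 0.0
            od = skeleton * np.exp(noise)
            well += 1
            for t, v in zip(times, od):
                rows.append((f"W{well:03d}", strain, rep, float(t), float(v)))
    return pd.DataFrame(rows, columns=["well", "strain", "replicate", "time_h", "od560"])


# ---------------------------------------------------------------------------
# omics matrices
# ---------------------------------------------------------------------------

def _sample_table(design: SyntheticDesign) -> pd.DataFrame:
    rows = []
    for phase in design.phases:
        for strain in design.strains:
            for rep in range(1, design.replicates + 1):
                sid = f"{phase[:3]}_{strain[:3]}_{rep}"
                rows.append({"sample_id": sid, "strain": strain, "phase": phase, "replicate": rep})
    return pd.DataFrame(rows).set_index("sample_id")


def _effect(effects: Mapping[str, Mapping[str, float]], feature: str, phase: str) -> float:
    return float(effects.get(feature, {}).get(phase, 0.0))


def simulate_transcriptomics(
    design: SyntheticDesign,
    effects: EffectSpec = EffectSpec(),
    n_features: int = 2000,
    feature_ids: Optional[Sequence[str]] = None,
    seed: Optional[int] = None,
) -> tuple:
    """Negative-binomial transcript counts; returns (OmicsMatrix, truth table).

    Baseline means are log-normal across features, per-sample library-size
    factors are log-normal, and group means are scaled by 2^log2FC for
    features with a spiked effect in that phase.
    """
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    feats = list(feature_ids or [])[:n_features]
    feats += [f"t{i:04d}" for i in range(len(feats), n_features)]
    meta = _sample_table(design)
    base_mean = np.exp(rng.normal(np.log(100.0), 1.2, size=n_features))
    lib = np.exp(rng.normal(0.0, 0.1, size=len(meta)))
    alpha = effects.transcript_dispersion
    counts = np.zeros((n_features, len(meta)), dtype=int)
    for j, (sid, row) in enumerate(meta.iterrows()):
        fold = np.array(
            [
                2.0 ** _effect(effects.transcript_log2fc, f, row["phase"])
                if row["strain"] == "mutant"
                else 1.0
                for f in feats
            ]
        )
        mu = base_mean * fold * lib[j]
        if alpha > 0:
            counts[:, j] = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
        else:
            counts[:, j] = rng.poisson(mu)
    values = pd.DataFrame(counts, index=feats, columns=meta.index)
    truth = pd.DataFrame(
        {
            "feature": feats,
            "base_mean": base_mean,
            **{
                f"log2fc_{ph}": [_effect(effects.transcript_log2fc, f, ph) for f in feats]
                for ph in design.phases
            },
        }
    )
    return OmicsMatrix(values, meta), truth


def simulate_metabolomics(
    design: SyntheticDesign,
    effects: EffectSpec = EffectSpec(),
    n_features: int = 85,
    feature_ids: Optional[Sequence[str]] = None,
    detection_dropout: Optional[float] = None,
    qc_dropout: Optional[float] = None,
    seed: Optional[int] = None,
) -> tuple:
    """Log-normal metabolite intensities with detection and QC dropout.

    Dropout emulates untargeted LC-MS attrition: of ``n_features``
    predicted metabolites only a fraction is identified at all, and a
    further fraction of those fails preprocessing QC.  Returns the
    surviving OmicsMatrix and a truth table for all features (columns
    ``detected`` and ``qc_pass`` record the attrition).
    """
    seed = design.seed if seed is None else seed
    detection_dropout = (
        effects.detection_dropout if detection_dropout is None else detection_dropout
    )
    qc_dropout = effects.qc_dropout if qc_dropout is None else qc_dropout
    rng = np.random.default_rng(seed)
    feats = list(feature_ids or [])[:n_features]
    feats += [f"m{i:03d}" for i in range(len(feats), n_features)]
    meta = _sample_table(design)
    base_log2 = rng.uniform(12.0, 22.0, size=n_features)
    detected = rng.random(n_features) >= detection_dropout
    qc_pass = detected & (rng.random(n_features) >= qc_dropout)
    log2vals = np.zeros((n_features, len(meta)))
    for j, (sid, row) in enumerate(meta.iterrows()):
        shift = np.array(
            [
                _effect(effects.metabolite_log2fc, f, row["phase"])
                if row["strain"] == "mutant"
                else 0.0
                for f in feats
            ]
        )
        log2vals[:, j] = base_log2 + shift + rng.normal(0.0, effects.metabolite_sd, n_features)
    values = pd.DataFrame(2.0 ** log2vals, index=feats, columns=meta.index)
    truth = pd.DataFrame(
        {
            "feature": feats,
            "base_log2": base_log2,
            "detected": detected,
            "qc_pass": qc_pass,
            **{
                f"log2fc_{ph}": [_effect(effects.metabolite_log2fc, f, ph) for f in feats]
                for ph in design.phases
            },
        }
    )
    surviving = [f for f, ok in zip(feats, qc_pass) if ok]
    return OmicsMatrix(values.loc[surviving], meta), truth
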