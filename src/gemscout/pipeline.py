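"""End-to-end orchestration: synth -> simulate/disrupt -> test -> enrich -> evaluate.

One :class:`RunConfig` (constructible from YAML) drives the whole
workflow on synthetic data; every random stage takes a seed derived from
the run seed, all intermediates are written as TSV/JSON with sha256
checksums, and a manifest records seeds, timings and a config hash so a
rerun with the same config reproduces every output bit-wise.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .differential import results_frame, test_metabolites, test_transcripts
from .enrichment import PathwaySet, consensus_enrichment
from .ensemble import DisruptionConfig, run_ensemble
from .evaluation import EvaluationReport, build_report
from .network import MetabolicNetwork, PhaseConfig, load_network, write_network
from .phenomics import curves_from_frame, strain_comparison
from .synth import (
    EffectSpec,
    SyntheticDesign,
    make_toy_network,
    simulate_growth_curves,
    simulate_metabolomics,
    simulate_transcriptomics,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    outdir: str = "gemscout_run"
    seed: int = 42
    network_path: Optional[str] = None  # default: built-in toy network
    phases: tuple = ("glucose", "ethanol")
    target_pathway: str = "TCA"
    simulators: tuple = ("logic", "fba")
    n_sim: int = 500
    r_min: int = 1
    r_max: int = 3  # toy-network scale; a genome-scale run would use 5..12
    replicates: int = 4
    spike_log2fc: float = -1.0  # ground-truth effect on the target pathway's genes
    alpha_feature: float = 0.05
    alpha_set: float = 0.05
    metabolite_alpha: float = 0.1
    n_perm: int = 1000
    growth_replicates: int = 16
    growth_n_perm: int = 10_000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("phases", "simulators"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class PipelineResult:
    report: EvaluationReport
    manifest: dict
    outdir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full synthetic workflow; see module docstring."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}, "files": {}}
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()

    def stage(name):
        t0 = time.perf_counter()

        def done():
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}

        return done

    # 1. network
    done = stage("network")
    if cfg.network_path:
        if not Path(cfg.network_path).exists():
            raise FileNotFoundError(f"network path does not exist: {cfg.network_path}")
        network = load_network(cfg.network_path)
    else:
        network = make_toy_network()
    net_path = out / "network.json"
    write_network(network, net_path)
    done()

    target = network.pathway_reactions(cfg.target_pathway)
    if not target:
        raise ValueError(f"no reactions labelled with pathway {cfg.target_pathway!r}")
    target_genes = sorted(
        frozenset().union(*(network.reaction(r).genes for r in target)) or frozenset()
    )

    # 2. synthetic data (growth + omics, spiked on the target pathway's genes)
    done = stage("synthetic_data")
    design = SyntheticDesign(replicates=cfg.replicates, seed=cfg.seed)
    growth = simulate_growth_curves(replicates=cfg.growth_replicates, seed=cfg.seed + 1)
    growth.to_csv(out / "growth.tsv", sep="\t", index=False)
    effects = EffectSpec(
        transcript_log2fc={
            g: {ph: cfg.spike_log2fc for ph in cfg.phases} for g in target_genes
        },
        metabolite_log2fc={},
    )
    tmat, t_truth = simulate_transcriptomics(
        design, effects, feature_ids=sorted(network.genes), seed=cfg.seed + 2
    )
    tmat.to_tsv(out / "transcripts.tsv", out / "samples.tsv")
    t_truth.to_csv(out / "transcripts_truth.tsv", sep="\t", index=False)
    mmat, m_truth = simulate_metabolomics(
        design,
        effects,
        n_features=85,
        feature_ids=sorted(network.metabolite_ids),
        seed=cfg.seed + 3,
    )
    mmat.to_tsv(out / "metabolites.tsv", out / "metabolite_samples.tsv")
    m_truth.to_csv(out / "metabolites_truth.tsv", sep="\t", index=False)
    done()

    # 3. disruption ensembles
    done = stage("disruption_ensemble")
    preds = {}
    for sim in cfg.simulators:
        for phase in cfg.phases:
            pcfg = PhaseConfig.glucose() if phase == "glucose" else PhaseConfig.ethanol()
            dcfg = DisruptionConfig(
                target_reactions=target,
                n_sim=cfg.n_sim,
                r_min=cfg.r_min,
                r_max=cfg.r_max,
                simulator=sim,
                seed=cfg.seed + 10,
            )
            pred = run_ensemble(network, pcfg, dcfg)
            pred.to_tsv(out / f"pred_{sim}_{phase}.tsv")
            preds[(sim, phase)] = pred
    done()

    # 4. differential analysis
    done = stage("differential")
    transcripts = {ph: test_transcripts(tmat, ph) for ph in cfg.phases}
    metabolites = {ph: test_metabolites(mmat, ph) for ph in cfg.phases}
    for ph in cfg.phases:
        results_frame(transcripts[ph]).to_csv(out / f"de_transcripts_{ph}.tsv", sep="\t", index=False)
        results_frame(metabolites[ph]).to_csv(out / f"de_metabolites_{ph}.tsv", sep="\t", index=False)
    done()

    # 5. enrichment on the pathway sets defined by the network labels
    done = stage("enrichment")
    all_pathways = sorted({p for r in network.reactions for p in r.pathways})
    sets = []
    for p in all_pathways:
        rids = network.pathway_reactions(p)
        genes = frozenset().union(*(network.reaction(r).genes for r in rids))
        mets = frozenset().union(*(set(network.reaction(r).stoichiometry) for r in rids))
        if genes or mets:
            sets.append(PathwaySet(p, gene_ids=genes, metabolite_ids=mets))
    enrich = {
        ph: consensus_enrichment(
            sets,
            transcripts[ph],
            alpha_feature=cfg.alpha_feature,
            alpha_set=cfg.alpha_set,
            n_perm=cfg.n_perm,
            seed=cfg.seed + 20,
        )
        for ph in cfg.phases
    }
    for ph in cfg.phases:
        rows = [asdict(r) for r in enrich[ph]]
        with open(out / f"enrichment_{ph}.json", "w") as fh:
            json.dump(rows, fh, indent=1)
    done()

    # 6. phenomics
    done = stage("phenomics")
    comparison = strain_comparison(
        curves_from_frame(growth), n=cfg.growth_n_perm, seed=cfg.seed + 30
    )
    pheno = {
        "median_diff": comparison["median_diff"],
        "mean_diff": comparison["mean_diff"],
        "p": {k: v.p for k, v in comparison["tests"].items()},
    }
    with open(out / "phenomics.json", "w") as fh:
        json.dump(pheno, fh, indent=1)
    done()

    # 7. evaluation
    done = stage("evaluation")
    report = build_report(preds, transcripts, metabolites, alpha=cfg.alpha_feature)
    report.to_tsv(out / "report.tsv")
    done()

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return PipelineResult(report=report, manifest=manifest, outdir=out)
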