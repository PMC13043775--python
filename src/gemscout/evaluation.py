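"""Evaluating ensemble predictions against differential omics results.

The join is by entity id: an entity predicted differential (direction up
or down) that is also measured contributes to the direction-prediction
accuracy — the fraction of such entities whose predicted sign matches
the sign of the empirical log2 fold-change.  When no predicted entity is
measured the accuracy is not applicable (None), mirroring the situation
where a qualitative simulator's predictions and the detected metabolites
do not overlap at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .differential import DifferentialResult
from .ensemble import EnsemblePrediction, predicted_differential_count

__all__ = ["EvaluationReport", "direction_accuracy", "join_table", "build_report"]


def _de_frame(de: Sequence[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.feature for r in de],
            "log2fc": [r.log2fc for r in de],
            "p": [r.p for r in de],
            "fdr": [r.fdr for r in de],
        }
    )


def join_table(
    pred: EnsemblePrediction,
    de: Sequence[DifferentialResult],
    kind: Optional[str] = None,
) -> pd.DataFrame:
    """Per-entity join of predicted direction and empirical differential stats."""
    entities = pred.frame(kind)
    joined = entities.merge(_de_frame(de), left_on="entity_id", right_on="feature", how="inner")
    emp_sign = np.sign(joined["log2fc"])
    pred_sign = joined["direction"].map({"up": 1, "down": -1, "none": 0})
    joined["match"] = (pred_sign != 0) & (emp_sign == pred_sign)
    return joined.drop(columns=["feature"])


def direction_accuracy(
    pred: EnsemblePrediction,
    de: Sequence[DifferentialResult],
    significance_filter: str = "all_measured",
    alpha: float = 0.05,
    kind: Optional[str] = None,
) -> Optional[float]:
    """Fraction of predicted-differential, measured entities with matching sign.

    ``significance_filter="significant_only"`` restricts the evaluable set
    to features with empirical FDR < alpha.  Returns None when the
    evaluable set is empty (not applicable).
    """
    if significance_filter not in ("all_measured", "significant_only"):
        raise ValueError(f"unknown significance_filter {significance_filter!r}")
    joined = join_table(pred, de, kind)
    evaluable = joined[joined["direction"] != "none"]
    if significance_filter == "significant_only":
        evaluable = evaluable[evaluable["fdr"] < alpha]
    if evaluable.empty:
        return None
    return float(evaluable["match"].mean())


@dataclass
class EvaluationReport:
    """Per simulator x phase counts and accuracies, plus the full join tables."""

    summary: pd.DataFrame
    joins: Mapping[tuple, pd.DataFrame]

    def to_tsv(self, path) -> None:
        self.summary.to_csv(path, sep="\t", index=False)

    def to_dict(self) -> dict:
        return self.summary.to_dict(orient="records")


def build_report(
    preds: Mapping[tuple, EnsemblePrediction],
    transcripts: Mapping[str, Sequence[DifferentialResult]],
    metabolites: Optional[Mapping[str, Sequence[DifferentialResult]]] = None,
    significance_filter: str = "all_measured",
    alpha: float = 0.05,
) -> EvaluationReport:
    """Table-style evaluation across simulators and phases.

    ``preds`` is keyed by (simulator, phase); ``transcripts`` and
    ``metabolites`` map phase -> differential results.  Phases present in
    predictions must have transcript results.
    """
    metabolites = metabolites or {}
    rows = []
    joins = {}
    for (simulator, phase), pred in sorted(preds.items()):
        if phase not in transcripts:
            raise ValueError(f"no transcript results for phase {phase!r}")
        if pred.phase != phase:
            raise ValueError(
                f"prediction phase {pred.phase!r} does not match key phase {phase!r}"
            )
        counts = predicted_differential_count(pred)
        de_t = transcripts[phase]
        de_m = metabolites.get(phase, [])
        acc_g = direction_accuracy(pred, de_t, significance_filter, alpha, kind="gene")
        acc_m = (
            direction_accuracy(pred, de_m, significance_filter, alpha, kind="metabolite")
            if de_m
            else None
        )
        joins[(simulator, phase, "gene")] = join_table(pred, de_t, kind="gene")
        if de_m:
            joins[(simulator, phase, "metabolite")] = join_table(pred, de_m, kind="metabolite")
        rows.append(
            {
                "simulator": simulator,
                "phase": phase,
                "n_predicted_genes": counts["gene"],
                "n_predicted_metabolites": counts["metabolite"],
                "direction_accuracy_genes": acc_g,
                "direction_accuracy_metabolites": acc_m,
                "growth_fraction": pred.growth_fraction,
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=[
            "simulator",
            "phase",
            "n_predicted_genes",
            "n_predicted_metabolites",
            "direction_accuracy_genes",
            "direction_accuracy_metabolites",
            "growth_fraction",
        ],
    )
    return EvaluationReport(summary=summary, joins=joins)
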