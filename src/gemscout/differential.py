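"""Simplified differential analysis of omics matrices.

This module is an explicit, self-contained stand-in for the DESeq2 /
notame stages of a multiomics workflow — it is *not* a reimplementation
of either.  Transcript counts get median-of-ratios normalisation and a
Wald-type test on a negative-binomial model with a pooled
method-of-moments dispersion (no across-feature dispersion shrinkage, no
fold-change shrinkage).  Metabolite intensities are log2-transformed and
tested with a two-group linear model (equivalent to an equal-variance
two-sample t-test); the conventional significance cut-off there is
p < 0.1, reflecting the noise and low coverage of untargeted
metabolomics.  Multiple testing uses Benjamini-Hochberg FDR.

Fold changes are log2(mutant/reference) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OmicsMatrix",
    "DifferentialResult",
    "normalize_counts",
    "test_transcripts",
    "test_metabolites",
    "bh_adjust",
    "results_frame",
]

REQUIRED_METADATA = ("strain", "phase", "replicate")


@dataclass
class OmicsMatrix:
    """Feature x sample table with per-sample metadata.

    ``values``: DataFrame, rows = feature ids, columns = sample ids.
    ``metadata``: DataFrame indexed by sample id with columns ``strain``
    (reference/mutant), ``phase`` (glucose/ethanol) and ``replicate``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    size_factors: Optional[pd.Series] = None
    all_zero_features: tuple = ()

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in REQUIRED_METADATA:
            if col not in self.metadata.columns:
                raise ValueError(f"metadata missing column {col!r}")
            if self.metadata.loc[list(self.values.columns), col].isna().any():
                raise ValueError(f"incomplete metadata column {col!r}")
        if (self.values.values < 0).any():
            raise ValueError("omics values must be non-negative")

    @property
    def features(self) -> list:
        return self.values.index.tolist()

    @property
    def samples(self) -> list:
        return self.values.columns.tolist()

    def subset(self, phase: Optional[str] = None) -> "OmicsMatrix":
        meta = self.metadata.loc[list(self.values.columns)]
        keep = meta.index if phase is None else meta.index[meta["phase"] == phase]
        return OmicsMatrix(self.values[list(keep)], self.metadata.loc[list(keep)])

    def to_tsv(self, values_path, metadata_path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="feature_id")
        self.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, values_path, metadata_path) -> "OmicsMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="feature_id")
        metadata = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
        return cls(values, metadata)


@dataclass(frozen=True)
class DifferentialResult:
    feature: str
    log2fc: float
    p: float
    fdr: float
    stat: float  # signed Wald/t statistic, used as the GSEA ranking metric
    test: str  # "transcript_nb" | "metabolite_lm"
    flag: Optional[str] = None


def results_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "log2fc": r.log2fc,
                "p": r.p,
                "fdr": r.fdr,
                "stat": r.stat,
                "test": r.test,
                "flag": r.flag or "",
            }
            for r in results
        ]
    )


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(list(pvals), dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def normalize_counts(matrix: OmicsMatrix) -> OmicsMatrix:
    """Median-of-ratios (DESeq-style) size-factor normalisation.

    The geometric reference is computed over features with all-positive
    counts; all-zero features are flagged and passed through untouched
    (they stay all-zero after scaling).
    """
    counts = matrix.values
    if ((counts == 0).all(axis=0)).any():
        bad = counts.columns[(counts == 0).all(axis=0)].tolist()
        raise ValueError(f"samples with all-zero counts: {bad}")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature with all-positive counts; cannot estimate size factors")
    log_counts = np.log(counts[positive])
    log_geomean = log_counts.mean(axis=1)
    log_ratios = log_counts.sub(log_geomean, axis=0)
    size_factors = np.exp(log_ratios.median(axis=0))
    normalized = counts.div(size_factors, axis=1)
    all_zero = counts.index[(counts == 0).all(axis=1)].tolist()
    return OmicsMatrix(
        values=normalized,
        metadata=matrix.metadata,
        size_factors=size_factors,
        all_zero_features=tuple(all_zero),
    )


def _groups(matrix: OmicsMatrix, phase: str):
    meta = matrix.metadata.loc[list(matrix.values.columns)]
    in_phase = meta["phase"] == phase
    mut = meta.index[in_phase & (meta["strain"] == "mutant")].tolist()
    ref = meta.index[in_phase & (meta["strain"] == "reference")].tolist()
    if len(mut) < 2 or len(ref) < 2:
        raise ValueError(
            f"need >=2 replicates per strain in phase {phase!r} "
            f"(got mutant={len(mut)}, reference={len(ref)})"
        )
    return mut, ref


def test_transcripts(matrix: OmicsMatrix, phase: str = "glucose") -> list:
    """Wald-type NB test of mutant vs reference transcript counts in one phase.

    Counts are normalised (median-of-ratios), the NB dispersion is a pooled
    method-of-moments estimate per feature, and the Wald statistic on the
    ln-scale mean difference is referred to a t distribution with
    n1+n2-2 degrees of freedom.  Significance convention: FDR < 0.05.
    """
    mut, ref = _groups(matrix, phase)
    sub = OmicsMatrix(matrix.values[mut + ref], matrix.metadata)
    norm = normalize_counts(sub)
    X = norm.values
    pseudo = 0.5

    mu_m = X[mut].mean(axis=1)
    mu_r = X[ref].mean(axis=1)
    var_m = X[mut].var(axis=1, ddof=1)
    var_r = X[ref].var(axis=1, ddof=1)
    n_m, n_r = len(mut), len(ref)

    # pooled method-of-moments NB dispersion: var = mu + alpha mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_m = (var_m - mu_m) / mu_m**2
        alpha_r = (var_r - mu_r) / mu_r**2
    alpha = pd.concat([alpha_m, alpha_r], axis=1).mean(axis=1).clip(lower=0.0, upper=100.0)
    alpha = alpha.fillna(0.0)

    log2fc = np.log2((mu_m + pseudo) / (mu_r + pseudo))
    # delta-method variance of ln(mean) under NB
    se2 = (1.0 / (mu_m + pseudo) + alpha) / n_m + (1.0 / (mu_r + pseudo) + alpha) / n_r
    z = np.log((mu_m + pseudo) / (mu_r + pseudo)) / np.sqrt(se2)
    df = n_m + n_r - 2
    p = 2.0 * stats.t.sf(np.abs(z), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    fdr = bh_adjust(p)

    results = []
    for i, feat in enumerate(X.index):
        flag = "all_zero" if feat in norm.all_zero_features else None
        results.append(
            DifferentialResult(
                feature=feat,
                log2fc=float(log2fc.iloc[i]),
                p=float(p[i]),
                fdr=float(fdr[i]),
                stat=float(z.iloc[i]),
                test="transcript_nb",
                flag=flag,
            )
        )
    return results


def test_metabolites(matrix: OmicsMatrix, phase: str = "glucose") -> list:
    """Two-group linear model on log2 intensities (mutant vs reference).

    Equivalent to an equal-variance two-sample t-test per feature.
    Features with zero variance in both groups get p = 1 with a flag.
    Significance convention: p < 0.1.
    """
    mut, ref = _groups(matrix, phase)
    log2v = np.log2(matrix.values[mut + ref] + 1e-12)
    results = []
    pvals = []
    rows = []
    for feat in log2v.index:
        a = log2v.loc[feat, mut].to_numpy(float)
        b = log2v.loc[feat, ref].to_numpy(float)
        l2fc = float(a.mean() - b.mean())
        # zero variance in both groups: p undefined, reported as 1 with a flag
        if a.var(ddof=0) == 0.0 and b.var(ddof=0) == 0.0:
            rows.append((feat, l2fc, 1.0, 0.0, "zero_variance"))
            pvals.append(1.0)
            continue
        t, p = stats.ttest_ind(a, b, equal_var=True)
        p = float(np.clip(p, np.finfo(float).tiny, 1.0))
        rows.append((feat, l2fc, p, float(t), None))
        pvals.append(p)
    fdr = bh_adjust(pvals)
    for (feat, l2fc, p, t, flag), q in zip(rows, fdr):
        results.append(
            DifferentialResult(
                feature=feat,
                log2fc=l2fc,
                p=p,
                fdr=float(q),
                stat=t,
                test="metabolite_lm",
                flag=flag,
            )
        )
    return results
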