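"""Consensus pathway-set enrichment.

Three complementary tests are combined into one report, mirroring the
practice of balancing a conservative exact test against a more powerful
one and a rank-based one:

* **Fisher's exact test**, two-sided: sum of hypergeometric probabilities
  of all 2x2 tables with the observed margins whose probability does not
  exceed the observed table's.
* **Boschloo's test**: the unconditional exact test that uses Fisher's
  two-sided p as its statistic and takes the supremum of
  P(statistic <= observed) over a grid of nuisance success probabilities.
  By construction it is uniformly at least as powerful as Fisher
  (p_boschloo <= p_fisher).
* **Preranked GSEA**: classic weighted running-sum enrichment score
  (weight exponent 1 on |stat|) with a gene-label permutation null.  The
  report is direction-split: a pathway with a positive enrichment score
  gets an "up" p-value and a not-applicable "down" entry, and vice versa.

A pathway is flagged significant when any of the three p-values falls
below the set-level alpha (default 0.05); feature-level significance for
the 2x2 tables is FDR < 0.05 by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .differential import DifferentialResult, bh_adjust

__all__ = [
    "PathwaySet",
    "ContingencyTable",
    "EnrichmentResult",
    "GseaResult",
    "fisher_two_tailed",
    "boschloo",
    "gsea_preranked",
    "consensus_enrichment",
]


@dataclass(frozen=True)
class PathwaySet:
    name: str
    gene_ids: frozenset = frozenset()
    metabolite_ids: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))
        object.__setattr__(self, "metabolite_ids", frozenset(self.metabolite_ids))
        if not self.gene_ids and not self.metabolite_ids:
            raise ValueError(f"pathway {self.name!r}: both member sets empty")

    @property
    def members(self) -> frozenset:
        return self.gene_ids | self.metabolite_ids


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows = in-set / out-of-set, columns = significant / not."""

    in_sig: int
    in_not: int
    out_sig: int
    out_not: int

    def __post_init__(self):
        for v in (self.in_sig, self.in_not, self.out_sig, self.out_not):
            if v < 0 or int(v) != v:
                raise ValueError("contingency counts must be non-negative integers")

    def as_array(self) -> np.ndarray:
        return np.array([[self.in_sig, self.in_not], [self.out_sig, self.out_not]], int)

    @property
    def degenerate(self) -> bool:
        t = self.as_array()
        return (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any()


def fisher_two_tailed(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p; degenerate margins give p = 1."""
    if t.degenerate:
        return 1.0
    return float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])


def _fisher_p_grid(m: int, n: int) -> np.ndarray:
    """Two-sided Fisher p for every table [[x, m-x], [y, n-y]], vectorised by x+y."""
    p = np.ones((m + 1, n + 1))
    for s in range(0, m + n + 1):
        lo, hi = max(0, s - n), min(m, s)
        ks = np.arange(lo, hi + 1)
        pmf = stats.hypergeom.pmf(ks, m + n, m, s)
        # sum of probabilities <= observed (with scipy's relative tolerance)
        for k, pk in zip(ks, pmf):
            p[k, s - k] = pmf[pmf <= pk * (1 + 1e-7)].sum()
    return np.clip(p, 0.0, 1.0)


def boschloo(t: ContingencyTable, grid_size: int = 99) -> float:
    """Unconditional exact test with Fisher's two-sided p as statistic.

    p = sup over a grid of nuisance probabilities pi of
    P_pi(fisher_p(X, Y) <= fisher_p(observed)) with X ~ Bin(m, pi),
    Y ~ Bin(n, pi) for the two row totals m, n.
    """
    if t.degenerate:
        return 1.0
    m, n = t.in_sig + t.in_not, t.out_sig + t.out_not
    fisher_grid = _fisher_p_grid(m, n)
    observed = fisher_grid[t.in_sig, t.out_sig]
    mask = fisher_grid <= observed * (1 + 1e-10)
    xs, ys = np.arange(m + 1), np.arange(n + 1)
    best = 0.0
    for pi in np.linspace(0, 1, grid_size + 2)[1:-1]:
        px = stats.binom.pmf(xs, m, pi)
        py = stats.binom.pmf(ys, n, pi)
        prob = float((np.outer(px, py) * mask).sum())
        best = max(best, prob)
    return min(best, 1.0)


@dataclass(frozen=True)
class GseaResult:
    es: Optional[float]  # signed enrichment score, None when not applicable
    es_up: Optional[float]
    es_down: Optional[float]
    p_up: Optional[float]
    p_down: Optional[float]
    n_hits: int
    flag: Optional[str] = None


def _running_es(order_is_hit: np.ndarray, weights: np.ndarray) -> float:
    """Signed ES: the running-sum deviation of largest magnitude."""
    n = order_is_hit.size
    n_hits = int(order_is_hit.sum())
    hit_w = weights * order_is_hit
    denom = hit_w.sum()
    if denom == 0:  # all hit weights zero: fall back to unweighted hits
        hit_w = order_is_hit.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~order_is_hit.astype(bool)).astype(float) / (n - n_hits)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea_preranked(
    stats_map: Mapping[str, float],
    feature_set,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> GseaResult:
    """Classic preranked GSEA with a gene-label permutation null.

    Features are ranked by the signed statistic (descending; ties broken
    by feature id).  The permutation p has resolution 1/(n_perm+1) and is
    reported only for the direction of the observed enrichment score.
    """
    feature_set = frozenset(feature_set)
    features = sorted(stats_map, key=lambda f: (-stats_map[f], f))
    n = len(features)
    hits = np.array([f in feature_set for f in features])
    n_hits = int(hits.sum())
    if n_hits == 0:
        return GseaResult(None, None, None, None, None, 0, flag="no_overlap")
    if n_hits == n:
        return GseaResult(None, None, None, None, None, n_hits, flag="set_is_universe")

    values = np.abs(np.array([stats_map[f] for f in features], float)) ** weight
    # both-direction extremes of the observed running sum (for reporting)
    hit_w = values * hits
    denom = hit_w.sum()
    if denom == 0:
        hit_w = hits.astype(float)
        denom = hit_w.sum()
    running = np.cumsum(hit_w / denom - (~hits).astype(float) / (n - n_hits))
    es_up = float(max(running.max(), 0.0))
    es_down = float(min(running.min(), 0.0))
    es = _running_es(hits, values)

    rng = np.random.default_rng(seed)
    perm_es = np.empty(n_perm)
    for i in range(n_perm):
        perm_hits = np.zeros(n, dtype=bool)
        perm_hits[rng.choice(n, size=n_hits, replace=False)] = True
        perm_es[i] = _running_es(perm_hits, values)
    if es > 0:
        p_up = (1 + int((perm_es >= es).sum())) / (n_perm + 1)
        return GseaResult(es, es_up, es_down, float(p_up), None, n_hits)
    p_down = (1 + int((perm_es <= es).sum())) / (n_perm + 1)
    return GseaResult(es, es_up, es_down, None, float(p_down), n_hits)


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    fisher_p: Optional[float]
    boschloo_p: Optional[float]
    fgsea_up_p: Optional[float]
    fgsea_down_p: Optional[float]
    es_up: Optional[float]
    es_down: Optional[float]
    significant: bool
    n_in_universe: int
    n_in_significant: int
    flag: Optional[str] = None


def consensus_enrichment(
    pathways: Sequence[PathwaySet],
    de: Sequence[DifferentialResult],
    alpha_feature: float = 0.05,
    alpha_set: float = 0.05,
    significance_field: str = "fdr",
    n_perm: int = 1000,
    seed: int = 0,
) -> list:
    """Fisher + Boschloo + direction-split GSEA per pathway, Table-style report.

    The feature universe is everything in ``de``; feature significance is
    ``fdr < alpha_feature`` by default (use ``significance_field="p"`` for
    the metabolite convention).  A pathway with no measured member yields
    a not-applicable row.
    """
    if significance_field not in ("fdr", "p"):
        raise ValueError("significance_field must be 'fdr' or 'p'")
    universe = {r.feature for r in de}
    sig = {r.feature for r in de if getattr(r, significance_field) < alpha_feature}
    stats_map = {r.feature: r.stat for r in de}

    results = []
    for i, pw in enumerate(pathways):
        members = pw.members & universe
        if not members:
            results.append(
                EnrichmentResult(pw.name, None, None, None, None, None, None,
                                 False, 0, 0, flag="not_measured")
            )
            continue
        in_sig = len(members & sig)
        table = ContingencyTable(
            in_sig=in_sig,
            in_not=len(members) - in_sig,
            out_sig=len(sig - members),
            out_not=len(universe - members - sig),
        )
        fp = fisher_two_tailed(table)
        bp = boschloo(table)
        g = gsea_preranked(stats_map, members, n_perm=n_perm, seed=seed + i)
        ps = [p for p in (fp, bp, g.p_up, g.p_down) if p is not None]
        results.append(
            EnrichmentResult(
                pathway=pw.name,
                fisher_p=fp,
                boschloo_p=bp,
                fgsea_up_p=g.p_up,
                fgsea_down_p=g.p_down,
                es_up=g.es_up,
                es_down=g.es_down,
                significant=any(p < alpha_set for p in ps),
                n_in_universe=len(members),
                n_in_significant=in_sig,
                flag=g.flag,
            )
        )
    return results
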