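"""Pre-ranked gene-set enrichment on burden-test results.

Genes are ranked by their burden permutation p-values (score
-log10(p), ties broken by odds ratio then symbol); each gene set is scored
with the classical weighted Kolmogorov-Smirnov running sum, significance is
assessed by drawing random gene sets of equal size from the ranked list
(gene-label permutation, the pre-ranked convention) and multiplicity is
handled with Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .burden_segregation import BurdenResult


@dataclass
class RankedList:
    """Genes ordered by decreasing rank score; scores finite and non-increasing."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("ranked list contains duplicate genes")
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("rank scores must be finite")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("rank scores must be non-increasing")
        self._pos = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def positions(self, gene_set: Sequence[str]) -> np.ndarray:
        return np.asarray(sorted(self._pos[g] for g in gene_set if g in self._pos), dtype=int)


@dataclass(slots=True)
class GeneSetResult:
    set_name: str
    n_genes_in_list: int
    enrichment_score: float
    p_perm: float
    q_value: float = math.nan
    rank: int = 0
    testable: bool = True


def build_ranked_list(burden_results: Sequence[BurdenResult]) -> RankedList:
    """Rank genes by burden significance: score -log10(p_perm), ties by OR then symbol."""
    ordered = sorted(burden_results, key=lambda r: (r.p_perm, -r.or_freq_ratio, r.gene))
    genes = [r.gene for r in ordered]
    scores = np.array([-math.log10(r.p_perm) for r in ordered])
    return RankedList(genes=genes, scores=scores)


def enrichment_score(
    ranked_list: RankedList,
    gene_set: Sequence[str],
    weight: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted Kolmogorov-Smirnov running-sum enrichment score.

    Walking the ranked list top to bottom, a hit increments the running sum
    by |score|^weight normalised by the sum over set members, a miss
    decrements by 1/(N - |S|); the enrichment score is the signed maximum
    deviation from zero (weight 0 reduces to the unweighted KS statistic).
    Returns (ES, running-sum profile).
    """
    positions = ranked_list.positions(gene_set)
    n = len(ranked_list)
    if positions.size == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if positions.size == n:
        raise ValueError("gene set covers the entire ranked list: no misses to score")
    return _es_from_positions(ranked_list.scores, positions, n, weight)


def _es_from_positions(
    scores: np.ndarray, positions: np.ndarray, n: int, weight: float
) -> tuple[float, np.ndarray]:
    hit_w = np.abs(scores[positions]) ** weight
    denom = hit_w.sum()
    if denom == 0:  # all-zero scores in the set: fall back to equal weights
        hit_w = np.ones_like(hit_w)
        denom = hit_w.sum()
    steps = np.full(n, -1.0 / (n - positions.size))
    steps[positions] = hit_w / denom
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def gsea_permutation_p(
    ranked_list: RankedList,
    gene_set: Sequence[str],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    weight: float = 1.0,
    exhaustive: bool = False,
) -> float:
    """Gene-label permutation p-value for a set's enrichment score.

    The null draws random gene sets of the same size from the ranked list; a
    null draw counts when its |ES| reaches |ES_obs| with matching sign.
    Monte-Carlo mode uses the add-one estimator; ``exhaustive=True``
    enumerates every subset (small lists only) and returns the exact
    fraction.
    """
    positions = ranked_list.positions(gene_set)
    n = len(ranked_list)
    k = positions.size
    es_obs, _ = enrichment_score(ranked_list, gene_set, weight)
    sign = 1.0 if es_obs >= 0 else -1.0
    scores = ranked_list.scores

    def counts(null_positions: np.ndarray) -> bool:
        es, _ = _es_from_positions(scores, null_positions, n, weight)
        return abs(es) >= abs(es_obs) - 1e-15 and (es >= 0) == (sign > 0)

    if exhaustive:
        hits = total = 0
        for combo in itertools.combinations(range(n), k):
            total += 1
            if counts(np.asarray(combo, dtype=int)):
                hits += 1
        return hits / total
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    hits = 0
    for _ in range(n_perm):
        null_pos = rng.choice(n, size=k, replace=False)
        null_pos.sort()
        if counts(null_pos):
            hits += 1
    return (1 + hits) / (n_perm + 1)


def q_values(p_list: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (monotone after sorting)."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def run_gsea(
    burden_results: Sequence[BurdenResult],
    gmt_collection: Sequence[tuple[str, str, list[str]]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 0.0,
) -> list[GeneSetResult]:
    """Score every gene set against the burden ranking; rank by p then ES.

    The pipeline default is the unweighted KS statistic (weight 0): the
    burden-derived rank score (-log10 permutation p) is exactly zero for
    every gene without case carriers, and score-weighted hits would then let
    degenerate null sets (a single top gene padded with zero-score genes)
    tie the maximal enrichment score while scoring zero-evidence sets by
    their arbitrary tie order.  The weighted running sum remains available
    through ``weight``.

    Sets with no gene in the ranking are flagged untestable (p and q are NaN)
    and excluded from multiplicity adjustment.
    """
    if not gmt_collection:
        raise ValueError("empty gene-set collection")
    ranked = build_ranked_list(burden_results)
    rng = np.random.default_rng(seed)
    results: list[GeneSetResult] = []
    for name, _desc, genes in gmt_collection:
        overlap = ranked.positions(genes)
        if overlap.size == 0:
            results.append(
                GeneSetResult(name, 0, math.nan, math.nan, testable=False)
            )
            continue
        es, _ = enrichment_score(ranked, genes, weight)
        p = gsea_permutation_p(ranked, genes, n_perm=n_perm, seed=rng, weight=weight)
        results.append(GeneSetResult(name, int(overlap.size), es, p))
    testable = [r for r in results if r.testable]
    qs = q_values([r.p_perm for r in testable])
    for r, q in zip(testable, qs):
        r.q_value = float(q)
    testable.sort(key=lambda r: (r.p_perm, -r.enrichment_score, r.set_name))
    for i, r in enumerate(testable, 1):
        r.rank = i
    return testable + [r for r in results if not r.testable]
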