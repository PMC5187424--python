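"""Collapsing T1 burden testing, segregation filtering and replication Fisher tests.

To keep pedigree members statistically independent, one sequenced affected
member per pedigree is drawn uniformly at random as the proband; the burden
test then compares, per gene, the number of probands carrying at least one
qualifying variant with the corresponding count in controls.  Significance
comes from permuting case/control labels (the case-carrier count is the test
statistic, with a one-sided enrichment tail), effect size from the ratio of
proband to control carrier frequency, and candidate genes are additionally
required to segregate — all sequenced affected members carrying the same
variant — in at least two pedigrees.  Sporadic cases are held out of the
familial test and used for replication against external control carrier
counts via Fisher's exact test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .io_formats import CohortTable, Pedigree
from .variant_qc import QualifyingVariant

logger = logging.getLogger("famburden")


@dataclass(slots=True)
class BurdenResult:
    gene: str
    n_case_carriers: int
    n_cases: int
    n_ctrl_carriers: int
    n_ctrls: int
    or_freq_ratio: float  # inf when b=0 and a>0
    p_perm: float
    n_affected_familial_carriers: int = 0
    rank: int = 0

    @property
    def or_is_infinite(self) -> bool:
        return math.isinf(self.or_freq_ratio)


@dataclass(slots=True)
class SegregationRecord:
    gene: str
    pedigree_id: str
    variant_key: str
    n_sequenced_affected: int
    n_affected_carriers: int
    segregates: bool


def assign_probands(
    pedigrees: Sequence[Pedigree], seed: int | np.random.Generator
) -> dict[str, str]:
    """Pick one sequenced affected member per pedigree, uniformly at random.

    Deterministic under a fixed seed.  A pedigree without a sequenced
    affected member is an error — it cannot contribute a proband.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out: dict[str, str] = {}
    for ped in pedigrees:
        candidates = ped.sequenced_affected()
        if not candidates:
            raise ValueError(f"pedigree {ped.pedigree_id} has no sequenced affected member")
        out[ped.pedigree_id] = candidates[int(rng.integers(len(candidates)))]
    return out


def carrier_flags(gene_variants: Sequence[QualifyingVariant], sample_indices: np.ndarray) -> np.ndarray:
    """Boolean flag per sample: carries >=1 non-missing het/hom-alt genotype in the gene.

    Counted once regardless of how many of the gene's variants a sample
    carries; invariant to variant order and duplication.
    """
    flags = np.zeros(len(sample_indices), dtype=bool)
    for qv in gene_variants:
        calls = qv.variant.calls
        for j, i in enumerate(sample_indices):
            if calls[i].is_carrier:
                flags[j] = True
    return flags


def t1_carrier_counts(
    gene_variants: Sequence[QualifyingVariant],
    proband_indices: np.ndarray,
    control_indices: np.ndarray,
) -> tuple[int, int, int, int]:
    """Collapsed carrier counts (a, n1, b, n2) for probands and controls."""
    a = int(carrier_flags(gene_variants, proband_indices).sum())
    b = int(carrier_flags(gene_variants, control_indices).sum())
    return a, len(proband_indices), b, len(control_indices)


def frequency_ratio_or(a: int, n1: int, b: int, n2: int) -> float:
    """Ratio of carrier frequencies, (a/n1)/(b/n2).

    Zero when no case carriers; infinite when only case carriers — use
    :func:`continuity_corrected_or` for a finite estimate in that case.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if a == 0:
        return 0.0
    if b == 0:
        return math.inf
    return (a / n1) / (b / n2)


def continuity_corrected_or(a: int, n1: int, b: int, n2: int) -> float:
    """Half-count-corrected frequency ratio, finite even at zero control carriers."""
    return ((a + 0.5) / (n1 + 0.5)) / ((b + 0.5) / (n2 + 0.5))


def permutation_burden_p(
    carrier: np.ndarray,
    is_case: np.ndarray,
    n_perm: int = 100_000,
    seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
) -> float:
    """Permutation p-value for case enrichment of carriers.

    The statistic is the number of case carriers; case/control labels are
    permuted preserving group sizes.  Monte-Carlo mode returns the add-one
    estimator ``(1 + #{permuted >= observed}) / (n_perm + 1)``, which is
    never zero.  With ``exhaustive=True`` every assignment of the case
    labels is enumerated and the exact tail fraction is returned (only
    feasible for small inputs).  Degenerate inputs — no carriers or all
    carriers — give p = 1.
    """
    carrier = np.asarray(carrier, dtype=bool)
    is_case = np.asarray(is_case, dtype=bool)
    if carrier.shape != is_case.shape:
        raise ValueError("carrier and label vectors must have equal length")
    n = carrier.size
    k = int(carrier.sum())
    n1 = int(is_case.sum())
    observed = int((carrier & is_case).sum())
    if k == 0 or k == n:
        return 1.0
    if exhaustive:
        total = 0
        hits = 0
        for case_set in itertools.combinations(range(n), n1):
            total += 1
            stat = sum(carrier[i] for i in case_set)
            if stat >= observed:
                hits += 1
        return hits / total
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    hits = 0
    chunk = max(1, min(n_perm, 4_000_000 // max(n, 1)))
    remaining = n_perm
    base = np.tile(carrier, (chunk, 1))
    while remaining > 0:
        m = min(chunk, remaining)
        perm = rng.permuted(base[:m], axis=1)
        # after a uniform permutation of the flags, any fixed n1 positions act as cases
        stats_ = perm[:, :n1].sum(axis=1)
        hits += int((stats_ >= observed).sum())
        remaining -= m
    return (1 + hits) / (n_perm + 1)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities at most that of the observed table;
    a table with a zero margin gives p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def segregation_scan(
    gene_map: Mapping[str, Sequence[QualifyingVariant]],
    pedigrees: Sequence[Pedigree],
    cohort: CohortTable,
    min_families: int = 2,
) -> tuple[list[SegregationRecord], dict[str, int]]:
    """Per-gene, per-pedigree segregation of qualifying variants.

    A variant segregates in a pedigree when the pedigree has at least two
    sequenced affected members and every one of them carries the variant.  A
    gene segregates in a pedigree when any of its qualifying variants does.
    Returns all records plus, per gene, the number of segregating pedigrees;
    a gene passes the filter when that count reaches ``min_families``.
    """
    records: list[SegregationRecord] = []
    gene_fams: dict[str, set[str]] = {}
    ped_samples = {
        ped.pedigree_id: [cohort.index_of(s) for s in ped.sequenced_affected() if s in cohort._index]
        for ped in pedigrees
    }
    for gene, qvs in gene_map.items():
        for ped in pedigrees:
            idx = ped_samples[ped.pedigree_id]
            n_seq = len(idx)
            for qv in qvs:
                calls = qv.variant.calls
                n_carry = sum(1 for i in idx if calls[i].is_carrier)
                seg = n_seq >= 2 and n_carry == n_seq
                if n_carry > 0 or seg:
                    records.append(
                        SegregationRecord(
                            gene=gene,
                            pedigree_id=ped.pedigree_id,
                            variant_key=qv.variant.key,
                            n_sequenced_affected=n_seq,
                            n_affected_carriers=n_carry,
                            segregates=seg,
                        )
                    )
                if seg:
                    gene_fams.setdefault(gene, set()).add(ped.pedigree_id)
    counts = {gene: len(fams) for gene, fams in gene_fams.items()}
    return records, counts


def segregating_genes(
    gene_map: Mapping[str, Sequence[QualifyingVariant]],
    pedigrees: Sequence[Pedigree],
    cohort: CohortTable,
    min_families: int = 2,
) -> list[str]:
    """Genes whose qualifying variants segregate in >= ``min_families`` pedigrees."""
    _, counts = segregation_scan(gene_map, pedigrees, cohort, min_families)
    return sorted(g for g, c in counts.items() if c >= min_families)


def rank_genes(results: Iterable[BurdenResult]) -> list[BurdenResult]:
    """Order by ascending permutation p, ties broken by descending OR then gene symbol."""
    ordered = sorted(
        results,
        key=lambda r: (r.p_perm, -r.or_freq_ratio, r.gene),
    )
    for i, r in enumerate(ordered, 1):
        r.rank = i
    return ordered


def burden_test(
    gene_map: Mapping[str, Sequence[QualifyingVariant]],
    cohort: CohortTable,
    pedigrees: Sequence[Pedigree],
    n_perm: int = 100_000,
    seed: int = 0,
    probands: Optional[Mapping[str, str]] = None,
) -> list[BurdenResult]:
    """Run the full per-gene collapsing burden test over probands vs controls.

    One random proband represents each pedigree (drawn here unless supplied);
    sporadic cases are excluded.  Results are ranked in place.
    """
    rng = np.random.default_rng(seed)
    if probands is None:
        probands = assign_probands(pedigrees, rng)
    proband_idx = np.asarray([cohort.index_of(s) for s in probands.values()], dtype=int)
    control_idx = cohort.control_indices()
    familial_idx = cohort.indices(role="familial_case")
    test_idx = np.concatenate([proband_idx, control_idx])
    is_case = np.zeros(test_idx.size, dtype=bool)
    is_case[: proband_idx.size] = True
    results = []
    for gene in sorted(gene_map):
        qvs = gene_map[gene]
        flags = carrier_flags(qvs, test_idx)
        a = int(flags[is_case].sum())
        b = int(flags[~is_case].sum())
        p = permutation_burden_p(flags, is_case, n_perm=n_perm, seed=rng)
        n_fam = int(carrier_flags(qvs, familial_idx).sum())
        results.append(
            BurdenResult(
                gene=gene,
                n_case_carriers=a,
                n_cases=proband_idx.size,
                n_ctrl_carriers=b,
                n_ctrls=control_idx.size,
                or_freq_ratio=frequency_ratio_or(a, proband_idx.size, b, control_idx.size),
                p_perm=p,
                n_affected_familial_carriers=n_fam,
            )
        )
    return rank_genes(results)


def replication_counts_test(
    case_carriers: int,
    n_cases: int,
    external_counts: Mapping[str, tuple[int, int]],
    gene: str,
) -> Optional[tuple[float, float]]:
    """Fisher two-sided p and frequency-ratio OR against an external control table.

    ``external_counts`` maps gene -> (carriers, total).  Returns None (with a
    warning) when the gene is absent from the table.
    """
    if gene not in external_counts:
        logger.warning("gene %s absent from external control table; skipped", gene)
        return None
    ext_carriers, ext_total = external_counts[gene]
    p = fisher_exact_two_sided(
        case_carriers, n_cases - case_carriers, ext_carriers, ext_total - ext_carriers
    )
    orr = frequency_ratio_or(case_carriers, n_cases, ext_carriers, ext_total)
    return p, orr


def read_external_counts(path) -> dict[str, tuple[int, int]]:
    """Read a TSV of per-gene external control carrier counts (gene, carriers, total)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:3])
    return {
        str(row[cols[0]]): (int(row[cols[1]]), int(row[cols[2]]))
        for _, row in df.iterrows()
    }
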