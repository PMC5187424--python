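"""Genotype- and site-level QC cascade and selection of qualifying rare disruptive variants.

The cascade masks individual genotype calls first (genotype quality, het
alternate depth, het allele balance), then evaluates site-level rules on the
post-mask data (upstream tranche flag, alignability, simple repeats, call
rate and Hardy-Weinberg equilibrium in cases and controls separately), and
finally restricts to the qualifying variant set: protein-truncating
(nonsense, splice acceptor/donor, frameshift) variants with minor allele
frequency below 1% both in the cohort and in any reference-panel annotation.
Genes whose qualifying variants are exclusively indels are removed, guarding
against indel-calling artefacts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .io_formats import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CohortTable,
    GenotypeCall,
    VariantRecord,
)

logger = logging.getLogger("famburden")

NONSENSE = "nonsense"
SPLICE = "splice_acceptor_donor"
FRAMESHIFT = "frameshift"
MISSENSE = "missense"
OTHER = "other"

DISRUPTIVE_CLASSES = frozenset({NONSENSE, SPLICE, FRAMESHIFT})

# Sequence Ontology terms as emitted by common annotators; extendable via the
# synonyms argument of classify_consequence.
_CONSEQUENCE_MAP = {
    "stop_gained": NONSENSE,
    "stop_gain": NONSENSE,
    "nonsense": NONSENSE,
    "splice_acceptor_variant": SPLICE,
    "splice_donor_variant": SPLICE,
    "splice_acceptor": SPLICE,
    "splice_donor": SPLICE,
    "frameshift_variant": FRAMESHIFT,
    "frameshift": FRAMESHIFT,
    "missense_variant": MISSENSE,
    "missense": MISSENSE,
}

# site-level drop reasons
R_TRANCHE = "tranche_fail"
R_ALIGNABILITY = "low_alignability"
R_SIMPLE_REPEAT = "simple_repeat"
R_CALL_RATE_CASES = "call_rate_cases"
R_CALL_RATE_CONTROLS = "call_rate_controls"
R_HWE_CASES = "hwe_cases"
R_HWE_CONTROLS = "hwe_controls"

# genotype-level masking reasons
R_LOW_GQ = "low_gq"
R_LOW_ALT_DEPTH = "low_alt_depth"
R_ALLELE_BALANCE = "allele_balance"


@dataclass(frozen=True)
class QCThresholds:
    """Filter cut-offs; the defaults are the study's published values."""

    gq_min: int = 30
    het_alt_depth_min: int = 3
    het_chi2_max: float = 10.83
    alignability_required: float = 1.0
    hwe_p_min: float = 1.0e-8
    call_rate_min: float = 0.75
    maf_max: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.maf_max <= 0.5):
            raise ValueError("maf_max must lie in (0, 0.5]")


@dataclass(slots=True)
class QualifyingVariant:
    """A rare protein-truncating variant that enters the burden test for its gene."""

    variant: VariantRecord
    variant_class: str
    cohort_maf: float


def classify_consequence(
    term: Optional[str], synonyms: Optional[Mapping[str, str]] = None
) -> str:
    """Map an annotation term to {nonsense, splice_acceptor_donor, frameshift, missense, other}.

    Missense is deliberately not part of the disruptive set: in-silico
    pathogenicity prediction for missense variants is not reliable enough to
    define qualifying variants.  Unrecognised terms fall through to ``other``
    with a warning.
    """
    if term is None:
        return OTHER
    t = term.strip().lower()
    if synonyms and t in synonyms:
        t = synonyms[t].strip().lower()
    cls = _CONSEQUENCE_MAP.get(t)
    if cls is not None:
        return cls
    if t not in ("synonymous_variant", "synonymous", "intron_variant", "other"):
        logger.warning("unrecognised consequence term %r -> other", term)
    return OTHER


def het_allele_balance_chi2(ad_ref: int, ad_alt: int) -> float:
    """1-df goodness-of-fit statistic of a heterozygote's read counts against 50:50.

    (ad_ref - ad_alt)^2 / (ad_ref + ad_alt).  Undefined at zero total depth;
    the caller masks such genotypes.
    """
    total = ad_ref + ad_alt
    if total <= 0:
        raise ValueError("allele-balance statistic undefined at zero depth")
    return (ad_ref - ad_alt) ** 2 / total


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums, over all possible
    heterozygote counts with the same parity, the probabilities of tables at
    most as probable as the observed one.  Monomorphic (or empty) tables give
    p = 1.  Stable for rare variants where the asymptotic chi-square breaks
    down.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    n_minor = min(n_alt, 2 * n - n_alt)
    if n == 0 or n_minor == 0:
        return 1.0
    # P(n_het | n, n_minor) ∝ n! / (nAA! nAa! naa!) * 2^n_het, computed in logs
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (
        hets * math.log(2.0)
        - _lgamma_arr(hom_major + 1)
        - _lgamma_arr(hets + 1)
        - _lgamma_arr(hom_minor + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = n_het
    p_obs = probs[np.nonzero(hets == observed)[0][0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(x)


def genotype_filter(call: GenotypeCall, thresholds: QCThresholds) -> tuple[GenotypeCall, Optional[str]]:
    """Mask a single genotype call, returning (possibly-masked call, masking reason).

    A call is set missing if its genotype quality falls below ``gq_min``, or —
    for heterozygotes — if the alternate depth falls below
    ``het_alt_depth_min`` or the allele-balance statistic reaches
    ``het_chi2_max``.  Already-missing calls pass through untouched.
    """
    if call.is_missing:
        return call, None
    if call.gq < thresholds.gq_min:
        return GenotypeCall(), R_LOW_GQ
    if call.gt == HET:
        if call.ad_alt < thresholds.het_alt_depth_min:
            return GenotypeCall(), R_LOW_ALT_DEPTH
        total = call.ad_ref + call.ad_alt
        if total <= 0:
            return GenotypeCall(), R_ALLELE_BALANCE
        if het_allele_balance_chi2(call.ad_ref, call.ad_alt) >= thresholds.het_chi2_max:
            return GenotypeCall(), R_ALLELE_BALANCE
    return call, None


def _group_stats(calls: list[GenotypeCall], idx: np.ndarray) -> tuple[float, tuple[int, int, int]]:
    n_ref = n_het = n_alt = n_missing = 0
    for i in idx:
        gt = calls[i].gt
        if gt == MISSING:
            n_missing += 1
        elif gt == HOM_REF:
            n_ref += 1
        elif gt == HET:
            n_het += 1
        else:
            n_alt += 1
    total = len(idx)
    call_rate = 1.0 if total == 0 else (total - n_missing) / total
    return call_rate, (n_ref, n_het, n_alt)


def site_filter(
    variant: VariantRecord, cohort: CohortTable, thresholds: QCThresholds
) -> tuple[bool, list[str]]:
    """Evaluate site-level rules on post-mask genotypes; returns (keep, failed reasons)."""
    reasons: list[str] = []
    if not variant.tranche_pass:
        reasons.append(R_TRANCHE)
    if variant.alignability < thresholds.alignability_required:
        reasons.append(R_ALIGNABILITY)
    if variant.in_simple_repeat:
        reasons.append(R_SIMPLE_REPEAT)
    case_idx = cohort.case_indices()
    ctrl_idx = cohort.control_indices()
    cr_case, counts_case = _group_stats(variant.calls, case_idx)
    cr_ctrl, counts_ctrl = _group_stats(variant.calls, ctrl_idx)
    if cr_case < thresholds.call_rate_min:
        reasons.append(R_CALL_RATE_CASES)
    if cr_ctrl < thresholds.call_rate_min:
        reasons.append(R_CALL_RATE_CONTROLS)
    if hwe_exact_p(*counts_case) <= thresholds.hwe_p_min:
        reasons.append(R_HWE_CASES)
    if hwe_exact_p(*counts_ctrl) <= thresholds.hwe_p_min:
        reasons.append(R_HWE_CONTROLS)
    return (not reasons), reasons


def cohort_maf(variant: VariantRecord) -> float:
    """Folded minor allele frequency over non-missing calls of the whole cohort."""
    n_called = 0
    n_alt = 0
    for c in variant.calls:
        if c.gt == MISSING:
            continue
        n_called += 1
        if c.gt == HET:
            n_alt += 1
        elif c.gt == HOM_ALT:
            n_alt += 2
    if n_called == 0:
        return 0.0
    p = n_alt / (2 * n_called)
    return min(p, 1.0 - p)


@dataclass
class QCResult:
    """Outcome of the full cascade: masked records, drops, and bookkeeping."""

    kept: list[VariantRecord]
    dropped: list[tuple[VariantRecord, list[str]]]
    genotype_mask_counts: dict[str, int] = field(default_factory=dict)

    @property
    def site_drop_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, reasons in self.dropped:
            for r in reasons:
                counts[r] = counts.get(r, 0) + 1
        return counts


def apply_qc(
    variants: Iterable[VariantRecord],
    cohort: CohortTable,
    thresholds: QCThresholds = QCThresholds(),
) -> QCResult:
    """Run the full cascade: genotype masking, then site filtering.

    Masking is applied in place of the call list (a new list per record), so
    site statistics — call rate and Hardy-Weinberg — see post-mask data.
    Applying the cascade to its own kept output is a no-op (idempotence).
    """
    mask_counts = {R_LOW_GQ: 0, R_LOW_ALT_DEPTH: 0, R_ALLELE_BALANCE: 0}
    kept: list[VariantRecord] = []
    dropped: list[tuple[VariantRecord, list[str]]] = []
    for rec in variants:
        new_calls = []
        for call in rec.calls:
            masked, reason = genotype_filter(call, thresholds)
            if reason is not None:
                mask_counts[reason] += 1
            new_calls.append(masked)
        rec = VariantRecord(
            chrom=rec.chrom,
            pos=rec.pos,
            ref=rec.ref,
            alt=rec.alt,
            gene=rec.gene,
            consequence=rec.consequence,
            tranche_pass=rec.tranche_pass,
            alignability=rec.alignability,
            in_simple_repeat=rec.in_simple_repeat,
            annotation_maf=rec.annotation_maf,
            calls=new_calls,
        )
        keep, reasons = site_filter(rec, cohort, thresholds)
        if keep:
            kept.append(rec)
        else:
            dropped.append((rec, reasons))
    return QCResult(kept=kept, dropped=dropped, genotype_mask_counts=mask_counts)


def qualifying_variants(
    variants: Iterable[VariantRecord],
    cohort: CohortTable,
    thresholds: QCThresholds = QCThresholds(),
    synonyms: Optional[Mapping[str, str]] = None,
) -> dict[str, list[QualifyingVariant]]:
    """Select rare disruptive variants per gene from QC-passed records.

    A variant qualifies if its consequence class is protein-truncating and
    the larger of its cohort frequency and any reference-panel frequency is
    below ``maf_max``.  Variants without a gene symbol are skipped with a
    warning.
    """
    gene_map: dict[str, list[QualifyingVariant]] = {}
    for rec in variants:
        cls = classify_consequence(rec.consequence, synonyms)
        if cls not in DISRUPTIVE_CLASSES:
            continue
        if rec.gene is None:
            logger.warning("variant %s lacks a gene symbol; skipped", rec.key)
            continue
        maf = cohort_maf(rec)
        worst = maf if rec.annotation_maf is None else max(maf, rec.annotation_maf)
        if worst >= thresholds.maf_max:
            continue
        gene_map.setdefault(rec.gene, []).append(
            QualifyingVariant(variant=rec, variant_class=cls, cohort_maf=maf)
        )
    return gene_map


def exclude_indel_only_genes(
    gene_map: Mapping[str, list[QualifyingVariant]],
) -> dict[str, list[QualifyingVariant]]:
    """Remove genes whose qualifying variants are all indels (indel-artefact guard)."""
    return {
        gene: qvs
        for gene, qvs in gene_map.items()
        if not all(qv.variant.is_indel for qv in qvs)
    }
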