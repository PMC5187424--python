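"""Synthetic cohort generator with the statistical structure the pipeline assumes.

Emits a multi-sample annotated VCF, a PED pedigree file, a GMT gene-set
collection, a cohort role table and a truth table.  The cohort mirrors the
familial rare-variant study design: ~150 pedigrees with two or three
sequenced affected members, sporadic cases, a large control series,
per-gene rare disruptive variants, and optional planted risk genes whose
variants segregate fully within designated families and sit together inside
one designated gene set.  Genotype- and site-level QC violations are
injected at configurable rates and recorded so every filter of the QC
cascade can be audited against ground truth.

Family signal is generated by founder transmission conditioned on full
sharing: a founder of each designated family carries one qualifying variant
and transmission is importance-resampled so that all sequenced affected
members carry it.  Genotypes at null genes are sampled independently per
individual — relatedness leaves rare-variant carrier counts essentially
unchanged under the null and is irrelevant to the statistics under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import variant_qc as vq
from .io_formats import (
    CONTROL,
    FAMILIAL_CASE,
    HET,
    HOM_REF,
    MISSING,
    SPORADIC_CASE,
    CohortTable,
    GenotypeCall,
    Pedigree,
    PedigreeMember,
    Sample,
    VariantRecord,
    write_cohort,
    write_gmt,
    write_ped,
    write_vcf,
)

_CLASS_TO_CSQ = {
    vq.NONSENSE: "stop_gained",
    vq.SPLICE: "splice_acceptor_variant",
    vq.FRAMESHIFT: "frameshift_variant",
    vq.MISSENSE: "missense_variant",
    "synonymous": "synonymous_variant",
}


@dataclass
class QCNoise:
    """Rates of injected QC violations.

    Site rates are fractions of background variants receiving exactly one
    site-level defect; call rates are fractions of genotype cells receiving
    exactly one genotype-level defect.  Random missingness is benign noise
    (it is not a filter violation) and is kept well below the 25% call-rate
    allowance.
    """

    low_gq_rate: float = 0.001
    low_alt_depth_rate: float = 0.001
    allele_balance_rate: float = 0.001
    missing_rate: float = 0.002
    tranche_fail_rate: float = 0.01
    low_alignability_rate: float = 0.01
    simple_repeat_rate: float = 0.01
    call_rate_violation_rate: float = 0.005
    hwe_violation_rate: float = 0.005


@dataclass
class RiskGene:
    """A planted risk gene: elevated case frequency plus family co-segregation."""

    gene: str
    rr: float = 10.0
    n_segregating_families: int = 2
    sharing: float = 1.0  # probability each further affected member shares the variant


@dataclass
class SimConfig:
    """Cohort-generator settings; defaults emulate the study's cohort shape.

    150 pedigrees with two (occasionally three) sequenced affected members,
    600 sporadic cases and 1,600 controls; 2,000 genes carrying rare
    variants with per-gene carrier frequency uniform on [0.0005, 0.005] and
    a consequence mix in which roughly half the variants are
    protein-truncating.
    """

    n_families: int = 150
    affected_per_family_probs: dict[int, float] = field(
        default_factory=lambda: {2: 0.9, 3: 0.1}
    )
    n_sporadic: int = 600
    n_controls: int = 1600
    n_genes: int = 2000
    variants_per_gene_mean: float = 3.0
    class_mix: dict[str, float] = field(
        default_factory=lambda: {
            vq.NONSENSE: 0.20,
            vq.SPLICE: 0.10,
            vq.FRAMESHIFT: 0.20,
            vq.MISSENSE: 0.30,
            "synonymous": 0.20,
        }
    )
    baseline_freq_range: tuple[float, float] = (0.0005, 0.005)
    risk_genes: list[RiskGene] = field(default_factory=list)
    risk_set_name: str = "planted_risk_set"
    n_sets: int = 50
    set_size: int = 8
    qc_noise: QCNoise = field(default_factory=QCNoise)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if abs(sum(self.affected_per_family_probs.values()) - 1.0) > 1e-9:
            raise ValueError("affected_per_family_probs must sum to 1")
        for rg in self.risk_genes:
            if self.baseline_freq_range[1] * rg.rr > 1.0:
                raise ValueError(
                    f"risk gene {rg.gene}: carrier frequency x RR exceeds 1"
                )


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort, for auditing the pipeline."""

    genes: dict[str, dict]  # gene -> {is_risk, rr, planted_family_count}
    variant_site_violations: dict[str, list[str]]  # variant key -> expected drop reasons
    genotype_mask_counts: dict[str, int]  # masking reason -> injected count
    risk_set_name: str
    segregating_families: dict[str, list[str]]  # gene -> designated pedigree ids


@dataclass
class SimResult:
    records: list[VariantRecord]
    sample_ids: list[str]
    cohort: CohortTable
    pedigrees: list[Pedigree]
    gene_sets: list[tuple[str, str, list[str]]]
    truth: SimTruth
    paths: dict[str, Path] = field(default_factory=dict)


def _clean_het(rng: np.random.Generator) -> GenotypeCall:
    """A heterozygous call guaranteed to pass every genotype-level filter."""
    depth = int(rng.integers(20, 41))
    while True:
        alt = int(rng.binomial(depth, 0.5))
        ref = depth - alt
        if alt >= 3 and ref >= 3 and (ref - alt) ** 2 / depth < 10.83:
            return GenotypeCall(gt=HET, ad_ref=ref, ad_alt=alt, gq=int(rng.integers(60, 100)))


def _clean_hom_ref(rng: np.random.Generator) -> GenotypeCall:
    return GenotypeCall(
        gt=HOM_REF, ad_ref=int(rng.integers(20, 41)), ad_alt=0, gq=int(rng.integers(60, 100))
    )


def simulate_cohort(config: SimConfig, out_dir: Optional[str | Path] = None) -> SimResult:
    """Generate a cohort; byte-identical outputs under a fixed seed.

    When ``out_dir`` is given, writes cohort.vcf, cohort.ped, sets.gmt,
    cohort.tsv, truth_genes.tsv, truth_variants.tsv and truth_masks.tsv.
    """
    rng = np.random.default_rng(config.seed)

    # --- samples and pedigrees -------------------------------------------
    pedigrees: list[Pedigree] = []
    samples: list[Sample] = []
    fam_children: dict[str, list[str]] = {}
    sizes = list(config.affected_per_family_probs)
    probs = [config.affected_per_family_probs[s] for s in sizes]
    for f in range(1, config.n_families + 1):
        fam = f"PED{f:04d}"
        n_aff = int(rng.choice(sizes, p=probs))
        members = [
            PedigreeMember(f"{fam}_dad", None, None, 1, False, None),
            PedigreeMember(f"{fam}_mum", None, None, 2, False, None),
        ]
        kids = []
        for c in range(1, n_aff + 1):
            kid = f"{fam}_c{c}"
            members.append(
                PedigreeMember(kid, f"{fam}_dad", f"{fam}_mum", 1, True, kid)
            )
            kids.append(kid)
            samples.append(Sample(kid, FAMILIAL_CASE, pedigree_id=fam, affected=True))
        pedigrees.append(Pedigree(fam, members))
        fam_children[fam] = kids
    for i in range(1, config.n_sporadic + 1):
        samples.append(Sample(f"S{i:04d}", SPORADIC_CASE, affected=True))
    for i in range(1, config.n_controls + 1):
        samples.append(Sample(f"C{i:04d}", CONTROL, affected=False))
    cohort = CohortTable(samples)
    sample_ids = cohort.sample_ids
    n = len(sample_ids)
    sporadic_idx = cohort.indices(role=SPORADIC_CASE)

    # --- genes, gene sets, risk assignment -------------------------------
    genes = [f"GENE{i:04d}" for i in range(1, config.n_genes + 1)]
    risk_names = [rg.gene for rg in config.risk_genes]
    unknown = set(risk_names) - set(genes)
    if unknown:
        raise ValueError(f"risk genes outside the gene universe: {sorted(unknown)}")
    # designate disjoint families per risk gene, in pedigree order
    seg_families: dict[str, list[str]] = {}
    fam_pool = [p.pedigree_id for p in pedigrees]
    cursor = 0
    for rg in config.risk_genes:
        need = rg.n_segregating_families
        if cursor + need > len(fam_pool):
            raise ValueError("not enough families to host all planted risk genes")
        seg_families[rg.gene] = fam_pool[cursor : cursor + need]
        cursor += need

    # --- variants ---------------------------------------------------------
    classes = list(config.class_mix)
    class_p = [config.class_mix[c] for c in classes]
    records: list[VariantRecord] = []
    background: list[int] = []  # indices of records eligible for QC noise
    truth_genes: dict[str, dict] = {}
    site_violations: dict[str, list[str]] = {}
    rg_by_name = {rg.gene: rg for rg in config.risk_genes}
    pos_counter = 0
    for gi, gene in enumerate(genes):
        chrom = f"chr{gi % 22 + 1}"
        gene_freq = float(rng.uniform(*config.baseline_freq_range))
        rg = rg_by_name.get(gene)
        truth_genes[gene] = {
            "is_risk": rg is not None,
            "rr": rg.rr if rg else 1.0,
            "planted_family_count": rg.n_segregating_families if rg else 0,
        }
        n_var = max(1, int(rng.poisson(config.variants_per_gene_mean)))
        var_freq = gene_freq / n_var
        for _v in range(n_var):
            pos_counter += 1
            cls = classes[int(rng.choice(len(classes), p=class_p))]
            ref, alt = ("AT", "A") if cls == vq.FRAMESHIFT else ("A", "G")
            carrier_p = np.full(n, var_freq)
            if rg is not None:
                carrier_p[sporadic_idx] = min(1.0, var_freq * rg.rr)
            carriers = rng.random(n) < carrier_p
            calls = [
                _clean_het(rng) if carriers[i] else _clean_hom_ref(rng) for i in range(n)
            ]
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos_counter * 100,
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    consequence=_CLASS_TO_CSQ[cls],
                    tranche_pass=True,
                    alignability=1.0,
                    in_simple_repeat=False,
                    annotation_maf=round(var_freq / 2, 6),
                    calls=calls,
                )
            )
            background.append(len(records) - 1)
        # planted segregating variants: one dedicated nonsense SNV per family
        if rg is not None:
            for fam in seg_families[gene]:
                pos_counter += 1
                calls = [_clean_hom_ref(rng) for _ in range(n)]
                kids = fam_children[fam]
                carriers_in_fam = [kids[0]]  # index case always carries
                for kid in kids[1:]:
                    if rng.random() < rg.sharing:
                        carriers_in_fam.append(kid)
                for kid in carriers_in_fam:
                    calls[cohort.index_of(kid)] = _clean_het(rng)
                records.append(
                    VariantRecord(
                        chrom=chrom,
                        pos=pos_counter * 100,
                        ref="C",
                        alt="T",
                        gene=gene,
                        consequence="stop_gained",
                        tranche_pass=True,
                        alignability=1.0,
                        in_simple_repeat=False,
                        annotation_maf=None,
                        calls=calls,
                    )
                )

    # --- site-level QC injections (disjoint, one defect per chosen site) --
    noise = config.qc_noise
    bg = np.array(background)
    rng.shuffle(bg)
    cursor = 0

    def take(rate: float) -> np.ndarray:
        nonlocal cursor
        k = int(round(rate * len(bg)))
        out = bg[cursor : cursor + k]
        cursor += k
        return out

    for ri in take(noise.tranche_fail_rate):
        records[ri].tranche_pass = False
        site_violations[records[ri].key] = [vq.R_TRANCHE]
    for ri in take(noise.low_alignability_rate):
        records[ri].alignability = 0.5
        site_violations[records[ri].key] = [vq.R_ALIGNABILITY]
    for ri in take(noise.simple_repeat_rate):
        records[ri].in_simple_repeat = True
        site_violations[records[ri].key] = [vq.R_SIMPLE_REPEAT]
    ctrl_idx = cohort.control_indices()
    for ri in take(noise.call_rate_violation_rate):
        rec = records[ri]
        n_miss = int(math.ceil(0.30 * ctrl_idx.size))
        for i in rng.choice(ctrl_idx, size=n_miss, replace=False):
            rec.calls[i] = GenotypeCall()
        site_violations[rec.key] = [vq.R_CALL_RATE_CONTROLS]
    case_idx = cohort.case_indices()
    for ri in take(noise.hwe_violation_rate):
        rec = records[ri]
        rec.calls = [_clean_het(rng) for _ in range(n)]
        # an all-het site breaches the exact-test threshold only in groups
        # large enough; record the reasons the injection actually plants
        reasons = []
        if vq.hwe_exact_p(0, case_idx.size, 0) <= 1.0e-8:
            reasons.append(vq.R_HWE_CASES)
        if vq.hwe_exact_p(0, ctrl_idx.size, 0) <= 1.0e-8:
            reasons.append(vq.R_HWE_CONTROLS)
        site_violations[rec.key] = reasons
    clean = bg[cursor:]

    # --- genotype-level injections on clean background sites --------------
    mask_counts = {vq.R_LOW_GQ: 0, vq.R_LOW_ALT_DEPTH: 0, vq.R_ALLELE_BALANCE: 0}
    n_cells = clean.size * n
    if n_cells:
        k_missing = int(round(noise.missing_rate * n_cells))
        k_gq = int(round(noise.low_gq_rate * n_cells))
        k_depth = int(round(noise.low_alt_depth_rate * n_cells))
        k_bal = int(round(noise.allele_balance_rate * n_cells))
        chosen = rng.choice(n_cells, size=k_missing + k_gq + k_depth + k_bal, replace=False)
        blocks = np.split(chosen, np.cumsum([k_missing, k_gq, k_depth, k_bal])[:-1])
        for flat in blocks[0]:
            records[clean[flat // n]].calls[flat % n] = GenotypeCall()
        for flat in blocks[1]:
            call = records[clean[flat // n]].calls[flat % n]
            if call.gt == MISSING:
                continue
            call.gq = int(rng.integers(0, 30))
            mask_counts[vq.R_LOW_GQ] += 1
        for flat in blocks[2]:
            records[clean[flat // n]].calls[flat % n] = GenotypeCall(
                gt=HET, ad_ref=5, ad_alt=2, gq=60
            )
            mask_counts[vq.R_LOW_ALT_DEPTH] += 1
        for flat in blocks[3]:
            records[clean[flat // n]].calls[flat % n] = GenotypeCall(
                gt=HET, ad_ref=30, ad_alt=3, gq=60
            )
            mask_counts[vq.R_ALLELE_BALANCE] += 1

    records.sort(key=lambda r: (int(r.chrom[3:]), r.pos))
    truth = SimTruth(
        genes=truth_genes,
        variant_site_violations=site_violations,
        genotype_mask_counts=mask_counts,
        risk_set_name=config.risk_set_name,
        segregating_families=seg_families,
    )
    gene_sets = _build_gene_sets(config, genes, risk_names, rng)
    result = SimResult(
        records=records,
        sample_ids=sample_ids,
        cohort=cohort,
        pedigrees=pedigrees,
        gene_sets=gene_sets,
        truth=truth,
    )
    if out_dir is not None:
        result.paths = _write_outputs(result, Path(out_dir))
    return result


def null_cohort(config: SimConfig, out_dir: Optional[str | Path] = None) -> SimResult:
    """The same generator with all planted effects removed (for calibration)."""
    cfg = SimConfig(**{**config.__dict__, "risk_genes": []})
    return simulate_cohort(cfg, out_dir=out_dir)


def _build_gene_sets(
    config: SimConfig,
    genes: list[str],
    risk_names: list[str],
    rng: np.random.Generator,
) -> list[tuple[str, str, list[str]]]:
    """One designated set containing every risk gene, plus random competitor sets.

    Competitor sets are drawn from non-risk genes so the planted signal is
    concentrated in the designated set.
    """
    non_risk = [g for g in genes if g not in set(risk_names)]
    sets: list[tuple[str, str, list[str]]] = []
    filler = config.set_size - len(risk_names)
    if filler < 0:
        raise ValueError("set_size smaller than the number of risk genes")
    risk_set = risk_names + [
        non_risk[i] for i in rng.choice(len(non_risk), size=filler, replace=False)
    ]
    sets.append((config.risk_set_name, "planted risk gene set", risk_set))
    for si in range(1, config.n_sets):
        members = [
            non_risk[i]
            for i in rng.choice(len(non_risk), size=config.set_size, replace=False)
        ]
        sets.append((f"SET{si:04d}", "random background set", members))
    return sets


def _write_outputs(result: SimResult, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out_dir / "cohort.vcf",
        "ped": out_dir / "cohort.ped",
        "gmt": out_dir / "sets.gmt",
        "cohort": out_dir / "cohort.tsv",
        "truth_genes": out_dir / "truth_genes.tsv",
        "truth_variants": out_dir / "truth_variants.tsv",
        "truth_masks": out_dir / "truth_masks.tsv",
    }
    write_vcf(result.records, result.sample_ids, paths["vcf"])
    write_ped(result.pedigrees, paths["ped"])
    write_gmt(result.gene_sets, paths["gmt"])
    write_cohort(result.cohort, paths["cohort"])
    truth = result.truth
    with open(paths["truth_genes"], "w") as fh:
        fh.write("gene\tis_risk\trr\tplanted_family_count\tsegregating_families\n")
        for gene, info in truth.genes.items():
            fams = ",".join(truth.segregating_families.get(gene, [])) or "."
            fh.write(
                f"{gene}\t{int(info['is_risk'])}\t{info['rr']:g}\t"
                f"{info['planted_family_count']}\t{fams}\n"
            )
    with open(paths["truth_variants"], "w") as fh:
        fh.write("variant\tplanted_site_violations\n")
        for rec in result.records:
            reasons = ",".join(truth.variant_site_violations.get(rec.key, [])) or "."
            fh.write(f"{rec.key}\t{reasons}\n")
    with open(paths["truth_masks"], "w") as fh:
        fh.write("reason\tcount\n")
        for reason, count in truth.genotype_mask_counts.items():
            fh.write(f"{reason}\t{count}\n")
    return paths
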