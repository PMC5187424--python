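"""Readers/writers for the standard formats the pipeline touches, plus run configuration.

The pipeline consumes a multi-sample VCF annotated with gene symbols and
functional consequences, a 6-column PED pedigree file, a GMT gene-set
collection and a cohort table assigning each sequenced sample a role
(familial case, sporadic case or control).  Everything is held in small
typed containers so downstream statistics never re-parse text.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

logger = logging.getLogger("famburden")

# genotype codes (unphased diploid, one alt allele per record)
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = 3

_GT_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}

FAMILIAL_CASE = "familial_case"
SPORADIC_CASE = "sporadic_case"
CONTROL = "control"


class VcfParseError(ValueError):
    """Raised when a VCF cannot be interpreted; the message names the offending line."""


@dataclass(slots=True)
class GenotypeCall:
    """One diploid genotype call with the depth/quality fields the QC cascade inspects.

    A missing genotype carries no depth/quality requirements; depths are
    non-negative read counts and ``gq`` is the Phred-scaled genotype quality.
    """

    gt: int = MISSING
    ad_ref: int = 0
    ad_alt: int = 0
    gq: int = 0

    @property
    def gt_name(self) -> str:
        return _GT_NAMES[self.gt]

    @property
    def is_missing(self) -> bool:
        return self.gt == MISSING

    @property
    def is_carrier(self) -> bool:
        return self.gt in (HET, HOM_ALT)


@dataclass(slots=True)
class VariantRecord:
    """One annotated bi-allelic site (multi-allelic rows are split upstream)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str]
    consequence: Optional[str]
    tranche_pass: bool
    alignability: float
    in_simple_repeat: bool
    annotation_maf: Optional[float]
    calls: list[GenotypeCall]

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(slots=True)
class Sample:
    sample_id: str
    role: str
    pedigree_id: Optional[str] = None
    affected: bool = False


@dataclass
class CohortTable:
    """Sample roles and pedigree membership, indexed consistently with VCF columns."""

    samples: list[Sample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in cohort table")
        for s in self.samples:
            if s.role == FAMILIAL_CASE and s.pedigree_id is None:
                raise ValueError(f"familial case {s.sample_id} lacks a pedigree_id")
        self._index = {sid: i for i, sid in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.samples)

    def index_of(self, sample_id: str) -> int:
        return self._index[sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def indices(self, role: Optional[str] = None, affected: Optional[bool] = None) -> np.ndarray:
        out = []
        for i, s in enumerate(self.samples):
            if role is not None and s.role != role:
                continue
            if affected is not None and s.affected != affected:
                continue
            out.append(i)
        return np.asarray(out, dtype=int)

    def case_indices(self) -> np.ndarray:
        """All affected samples (familial plus sporadic)."""
        return np.asarray(
            [i for i, s in enumerate(self.samples) if s.role in (FAMILIAL_CASE, SPORADIC_CASE)],
            dtype=int,
        )

    def control_indices(self) -> np.ndarray:
        return self.indices(role=CONTROL)

    def reorder_to(self, sample_order: Sequence[str]) -> "CohortTable":
        """Return a cohort table whose row order matches ``sample_order`` (e.g. VCF columns)."""
        by_id = {s.sample_id: s for s in self.samples}
        missing = [sid for sid in sample_order if sid not in by_id]
        if missing:
            raise ValueError(f"samples in VCF but not in cohort table: {missing[:5]}")
        return CohortTable([by_id[sid] for sid in sample_order])


@dataclass(slots=True)
class PedigreeMember:
    individual_id: str
    father_id: Optional[str]  # None marks a founder
    mother_id: Optional[str]
    sex: int
    affected: bool
    sequenced_sample_id: Optional[str] = None


@dataclass(slots=True)
class Pedigree:
    pedigree_id: str
    members: list[PedigreeMember]

    def sequenced_affected(self) -> list[str]:
        return [
            m.sequenced_sample_id
            for m in self.members
            if m.affected and m.sequenced_sample_id is not None
        ]


@dataclass
class RunConfig:
    """All tunables of a pipeline run; defaults mirror the study design."""

    # genotype/site QC (see variant_qc.QCThresholds for meanings)
    gq_min: int = 30
    het_alt_depth_min: int = 3
    het_chi2_max: float = 10.83
    alignability_required: float = 1.0
    hwe_p_min: float = 1.0e-8
    call_rate_min: float = 0.75
    maf_max: float = 0.01
    # permutation budgets
    n_perm_burden: int = 100_000
    n_perm_gsea: int = 1_000
    # power grid
    power_freqs: list[float] = field(default_factory=lambda: [1e-5, 1e-4, 1e-3, 1e-2])
    power_rrs: list[float] = field(default_factory=lambda: [1.75, 2.5, 5.0, 10.0])
    power_reps: int = 10_000
    power_alpha: float = 8.0e-7
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# VCF


def _info_get(variant, key, default=None):
    val = variant.INFO.get(key)
    return default if val is None else val


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read an annotated VCF into :class:`VariantRecord` objects.

    Multi-allelic rows are split into one record per alternate allele; the AD
    field is re-read per split allele (reference depth, that allele's depth).
    A sample's genotype for a split record counts copies of that alternate
    allele; any no-call allele marks the genotype missing.  Missing FORMAT
    fields likewise yield missing genotypes.

    Returns the records and the VCF header sample order.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises plain Exceptions on bad headers
        raise VcfParseError(f"cannot parse VCF header of {path}: {exc}") from exc
    samples = list(vcf.samples)
    n = len(samples)
    records: list[VariantRecord] = []
    for v in vcf:
        ad = v.format("AD")  # (n, n_alleles) ints, negative = missing
        gq = v.format("GQ")
        if gq is not None:
            gq = np.asarray(gq).reshape(len(samples), -1)[:, 0]
        genos = v.genotypes  # [[a1, a2, phased], ...]
        gene = _info_get(v, "GENE")
        csq = _info_get(v, "CSQ")
        tranche = bool(_info_get(v, "TRANCHE_PASS", False))
        alignability = float(_info_get(v, "ALIGNABILITY", 1.0))
        simplerep = bool(_info_get(v, "SIMPLEREP", False))
        ann_maf = _info_get(v, "ANN_MAF")
        ann_maf = float(ann_maf) if ann_maf is not None else None
        for alt_idx, alt in enumerate(v.ALT):
            allele_code = alt_idx + 1
            calls = []
            for i in range(n):
                a1, a2 = genos[i][0], genos[i][1]
                if a1 < 0 or a2 < 0:
                    calls.append(GenotypeCall())
                    continue
                n_alt = int(a1 == allele_code) + int(a2 == allele_code)
                gt = (HOM_REF, HET, HOM_ALT)[n_alt]
                ad_ref = int(ad[i, 0]) if ad is not None and ad[i, 0] >= 0 else 0
                ad_alt = (
                    int(ad[i, allele_code])
                    if ad is not None and ad[i, allele_code] >= 0
                    else 0
                )
                q = int(gq[i]) if gq is not None and gq[i] >= 0 else 0
                calls.append(GenotypeCall(gt=gt, ad_ref=ad_ref, ad_alt=ad_alt, gq=q))
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    gene=gene,
                    consequence=csq,
                    tranche_pass=tranche,
                    alignability=alignability,
                    in_simple_repeat=simplerep,
                    annotation_maf=ann_maf,
                    calls=calls,
                )
            )
    return records, samples


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Functional consequence (Sequence Ontology term)">
##INFO=<ID=TRANCHE_PASS,Number=0,Type=Flag,Description="Upstream recalibration tranche pass">
##INFO=<ID=ALIGNABILITY,Number=1,Type=Float,Description="UCSC 100bp-window alignability">
##INFO=<ID=SIMPLEREP,Number=0,Type=Flag,Description="Site overlaps a simple repeat">
##INFO=<ID=ANN_MAF,Number=1,Type=Float,Description="Reference-panel minor allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""

_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(records: Iterable[VariantRecord], samples: Sequence[str], path: str | Path) -> None:
    """Write bi-allelic records back to a VCF v4.2 file (supported field subset)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in _contigs(records):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for rec in records:
            info = []
            if rec.gene is not None:
                info.append(f"GENE={rec.gene}")
            if rec.consequence is not None:
                info.append(f"CSQ={rec.consequence}")
            if rec.tranche_pass:
                info.append("TRANCHE_PASS")
            info.append(f"ALIGNABILITY={rec.alignability:g}")
            if rec.in_simple_repeat:
                info.append("SIMPLEREP")
            if rec.annotation_maf is not None:
                info.append(f"ANN_MAF={rec.annotation_maf:g}")
            fields = [
                rec.chrom,
                str(rec.pos),
                ".",
                rec.ref,
                rec.alt,
                ".",
                ".",
                ";".join(info) or ".",
                "GT:AD:GQ",
            ]
            for call in rec.calls:
                if call.is_missing:
                    fields.append("./.:.:.")
                else:
                    fields.append(
                        f"{_GT_STRINGS[call.gt]}:{call.ad_ref},{call.ad_alt}:{call.gq}"
                    )
            fh.write("\t".join(fields) + "\n")


def _contigs(records: Iterable[VariantRecord]) -> list[str]:
    seen: dict[str, None] = {}
    for r in records:
        seen.setdefault(r.chrom, None)
    return list(seen)


# ---------------------------------------------------------------------------
# PED


def read_ped(path: str | Path) -> list[Pedigree]:
    """Read a 6-column whitespace PED file (family, individual, father, mother, sex, phenotype).

    Phenotype 2 marks an affected individual; father/mother ``0`` marks a
    founder.  Every individual is assumed sequenced under its own id unless a
    7th column supplies the sample id ('.' or '0' = not sequenced).
    Unsequenced members are retained in the pedigree structure.
    """
    fams: dict[str, list[PedigreeMember]] = {}
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"PED line {lineno}: expected >=6 columns, got {len(parts)}")
            fam, ind, father, mother, sex, pheno = parts[:6]
            if (fam, ind) in seen:
                raise ValueError(f"PED line {lineno}: duplicate individual {ind} in family {fam}")
            seen.add((fam, ind))
            try:
                pheno_i = int(pheno)
            except ValueError:
                raise ValueError(f"PED line {lineno}: non-numeric phenotype {pheno!r}") from None
            sample_id: Optional[str] = ind
            if len(parts) >= 7:
                sample_id = None if parts[6] in (".", "0") else parts[6]
            fams.setdefault(fam, []).append(
                PedigreeMember(
                    individual_id=ind,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=int(sex),
                    affected=pheno_i == 2,
                    sequenced_sample_id=sample_id,
                )
            )
    pedigrees = [Pedigree(pedigree_id=fam, members=members) for fam, members in fams.items()]
    for ped in pedigrees:
        if not any(m.affected for m in ped.members):
            logger.warning("pedigree %s has no affected member", ped.pedigree_id)
    return pedigrees


def write_ped(pedigrees: Iterable[Pedigree], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ped in pedigrees:
            for m in ped.members:
                fh.write(
                    "\t".join(
                        [
                            ped.pedigree_id,
                            m.individual_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            str(m.sex),
                            "2" if m.affected else "1",
                            m.sequenced_sample_id or ".",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> list[tuple[str, str, list[str]]]:
    """Read a tab-separated GMT gene-set file.

    Duplicate genes within a set are de-duplicated (order preserved); empty
    sets and lines with fewer than three fields are rejected.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {lineno}: expected >=3 tab-separated fields")
            name, desc = parts[0], parts[1]
            genes = list(dict.fromkeys(g for g in parts[2:] if g))
            if not genes:
                raise ValueError(f"GMT line {lineno}: gene set {name!r} is empty")
            sets.append((name, desc, genes))
    return sets


def write_gmt(sets: Iterable[tuple[str, str, list[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, desc, genes in sets:
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# cohort table TSV


def read_cohort(path: str | Path) -> CohortTable:
    """Read a cohort TSV with columns sample_id, role, pedigree_id, affected."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "role", "pedigree_id", "affected"}
    if not required.issubset(df.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    samples = []
    for row in df.itertuples(index=False):
        ped = None if row.pedigree_id in (".", "", None) or pd.isna(row.pedigree_id) else row.pedigree_id
        samples.append(
            Sample(
                sample_id=row.sample_id,
                role=row.role,
                pedigree_id=ped,
                affected=str(row.affected) in ("1", "True", "true"),
            )
        )
    return CohortTable(samples)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\trole\tpedigree_id\taffected\n")
        for s in cohort.samples:
            fh.write(
                f"{s.sample_id}\t{s.role}\t{s.pedigree_id or '.'}\t{int(s.affected)}\n"
            )
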