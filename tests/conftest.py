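import numpy as np
import pytest

import famburden as fb


@pytest.fixture
def toy_vcf(tmp_path):
    """3-sample, 2-site VCF plus one multi-allelic row for split testing."""
    text = """##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="g">
##INFO=<ID=CSQ,Number=1,Type=String,Description="c">
##INFO=<ID=TRANCHE_PASS,Number=0,Type=Flag,Description="t">
##INFO=<ID=ALIGNABILITY,Number=1,Type=Float,Description="a">
##INFO=<ID=SIMPLEREP,Number=0,Type=Flag,Description="s">
##INFO=<ID=ANN_MAF,Number=1,Type=Float,Description="m">
##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="gq">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
chr1\t100\t.\tA\tG\t.\t.\tGENE=G1;CSQ=stop_gained;TRANCHE_PASS;ALIGNABILITY=1\tGT:AD:GQ\t0/1:10,9:60\t0/0:20,0:70\t./.:.:.
chr1\t200\t.\tAT\tA\t.\t.\tGENE=G1;CSQ=frameshift_variant;TRANCHE_PASS;ALIGNABILITY=1;ANN_MAF=0.001\tGT:AD:GQ\t0/0:15,0:80\t0/1:12,11:55\t1/1:0,22:90
chr1\t300\t.\tA\tC,T\t.\t.\tGENE=G2;CSQ=missense_variant;TRANCHE_PASS;ALIGNABILITY=1\tGT:AD:GQ\t0/1:9,8,0:50\t0/2:9,0,7:50\t1/2:0,6,5:45
"""
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return path


@pytest.fixture
def toy_ped(tmp_path):
    text = (
        "FAM1\tA1\t0\t0\t1\t2\n"
        "FAM1\tA2\tA1\tA3\t1\t2\n"
        "FAM1\tA3\t0\t0\t2\t1\n"
        "FAM2\tB1\t0\t0\t1\t2\n"
        "FAM2\tB2\t0\t0\t2\t2\n"
        "FAM2\tB3\tB1\tB2\t1\t1\n"
    )
    path = tmp_path / "toy.ped"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def noisy_sim():
    """Small cohort with every QC violation class injected, plus planted signal."""
    cfg = fb.SimConfig(
        n_families=40,
        affected_per_family_probs={2: 1.0},
        n_sporadic=50,
        n_controls=300,
        n_genes=200,
        variants_per_gene_mean=2.0,
        n_sets=20,
        set_size=8,
        risk_genes=[fb.RiskGene("GENE0001", rr=10.0, n_segregating_families=2)],
        seed=11,
    )
    return fb.simulate_cohort(cfg)


def make_variant(gts, gene="G1", csq="stop_gained", ref="A", alt="G", **kw):
    """Variant with clean calls for the given genotype codes."""
    calls = []
    for gt in gts:
        if gt == fb.MISSING:
            calls.append(fb.GenotypeCall())
        elif gt == fb.HET:
            calls.append(fb.GenotypeCall(gt=gt, ad_ref=10, ad_alt=10, gq=60))
        elif gt == fb.HOM_ALT:
            calls.append(fb.GenotypeCall(gt=gt, ad_ref=0, ad_alt=20, gq=60))
        else:
            calls.append(fb.GenotypeCall(gt=gt, ad_ref=20, ad_alt=0, gq=60))
    defaults = dict(
        chrom="chr1",
        pos=100,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=csq,
        tranche_pass=True,
        alignability=1.0,
        in_simple_repeat=False,
        annotation_maf=None,
    )
    defaults.update(kw)
    return fb.VariantRecord(calls=calls, **defaults)


@pytest.fixture
def variant_factory():
    return make_variant


def simple_cohort(n_cases, n_controls):
    samples = [
        fb.Sample(f"P{i}", fb.FAMILIAL_CASE, pedigree_id=f"F{i}", affected=True)
        for i in range(n_cases)
    ]
    samples += [fb.Sample(f"C{i}", fb.CONTROL) for i in range(n_controls)]
    return fb.CohortTable(samples)


@pytest.fixture
def cohort_factory():
    return simple_cohort
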