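import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

import famburden as fb
from famburden import variant_qc as vq
from tests.conftest import make_variant, simple_cohort


def fisher_two_sided_oracle(a, b, c, d):
    """Independent exact-rational hypergeometric summation for a 2x2 table."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    def prob(x):
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))
    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs:
            total += px
    return float(total)


def qv(variant):
    return vq.QualifyingVariant(variant=variant, variant_class=vq.NONSENSE, cohort_maf=0.001)


class TestAssignProbands:
    def _peds(self, n, affected=2):
        peds = []
        for i in range(n):
            members = [
                fb.PedigreeMember(f"F{i}_a{j}", None, None, 1, True, f"F{i}_a{j}")
                for j in range(affected)
            ]
            peds.append(fb.Pedigree(f"F{i}", members))
        return peds

    def test_one_proband_per_pedigree(self):
        peds = self._peds(150)
        probands = fb.assign_probands(peds, seed=1)
        assert len(probands) == 150
        for ped in peds:
            assert probands[ped.pedigree_id] in ped.sequenced_affected()

    def test_single_candidate_always_chosen(self):
        peds = self._peds(3, affected=1)
        for seed in (0, 1, 99):
            assert set(fb.assign_probands(peds, seed).values()) == {
                "F0_a0", "F1_a0", "F2_a0",
            }

    def test_deterministic_under_seed(self):
        peds = self._peds(50, affected=3)
        assert fb.assign_probands(peds, seed=42) == fb.assign_probands(peds, seed=42)

    def test_no_sequenced_affected_is_error(self):
        ped = fb.Pedigree("F0", [fb.PedigreeMember("x", None, None, 1, False, "x")])
        with pytest.raises(ValueError, match="F0"):
            fb.assign_probands([ped], seed=0)


class TestCarrierCounts:
    def test_counts(self):
        # carriers: samples 0,1 (cases of 3), sample 4 (control of 3)
        v = make_variant([fb.HET, fb.HOM_ALT, fb.HOM_REF, fb.HOM_REF, fb.HET, fb.HOM_REF])
        a, n1, b, n2 = fb.t1_carrier_counts([qv(v)], np.arange(3), np.arange(3, 6))
        assert (a, n1, b, n2) == (2, 3, 1, 3)

    def test_multiple_variants_count_carrier_once(self):
        v1 = make_variant([fb.HET, fb.HOM_REF])
        v2 = make_variant([fb.HET, fb.HOM_REF], pos=200)
        a, n1, b, n2 = fb.t1_carrier_counts([qv(v1), qv(v2)], np.array([0]), np.array([1]))
        assert (a, b) == (1, 0)

    def test_no_carriers(self):
        v = make_variant([fb.HOM_REF] * 4)
        assert fb.t1_carrier_counts([qv(v)], np.arange(2), np.arange(2, 4)) == (0, 2, 0, 2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.permutations(range(4)))
    def test_invariant_to_variant_order_and_duplication(self, order):
        variants = [
            make_variant([fb.HET, fb.HOM_REF, fb.HOM_REF], pos=100),
            make_variant([fb.HOM_REF, fb.HET, fb.HOM_REF], pos=200),
            make_variant([fb.HOM_REF, fb.HET, fb.HOM_REF], pos=200),
            make_variant([fb.MISSING, fb.HOM_REF, fb.HOM_REF], pos=300),
        ]
        qvs = [qv(variants[i]) for i in order] + [qv(variants[0])]
        flags = fb.carrier_flags(qvs, np.arange(3))
        assert flags.tolist() == [True, True, False]


class TestFrequencyRatioOr:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(2, 6, 3.6), (3, 11, 2.9), (3, 13, 2.5), (3, 18, 1.8), (2, 16, 1.3)],
    )
    def test_reported_carrier_counts(self, a, b, expected):
        """Proband-vs-control frequency ratios at the published cohort sizes."""
        assert round(fb.frequency_ratio_or(a, 150, b, 1609), 1) == expected

    def test_zero_case_carriers(self):
        assert fb.frequency_ratio_or(0, 150, 5, 1609) == 0.0

    def test_zero_control_carriers_infinite(self):
        assert math.isinf(fb.frequency_ratio_or(2, 150, 0, 1609))
        cc = fb.continuity_corrected_or(2, 150, 0, 1609)
        assert 0 < cc < math.inf

    def test_zero_group_size_error(self):
        with pytest.raises(ValueError):
            fb.frequency_ratio_or(1, 0, 1, 10)


class TestPermutationBurden:
    def test_zero_statistic_gives_one(self):
        carrier = np.array([False, False, True, True])
        case = np.array([True, True, False, False])
        assert fb.permutation_burden_p(carrier, case, exhaustive=True) == 1.0

    def test_no_carriers_gives_one(self):
        carrier = np.zeros(6, dtype=bool)
        case = np.array([True] * 3 + [False] * 3)
        assert fb.permutation_burden_p(carrier, case, n_perm=10, seed=0) == 1.0

    def test_tiny_instance_matches_hypergeometric(self):
        # 4 cases, 4 controls, both carriers in cases: tail = C(4,2)/C(8,2) = 6/28
        carrier = np.array([True, True] + [False] * 6)
        case = np.array([True] * 4 + [False] * 4)
        p = fb.permutation_burden_p(carrier, case, exhaustive=True)
        assert p == pytest.approx(6 / 28)

    def test_exhaustive_equals_hypergeom_tail_small_designs(self):
        for n in range(2, 9):
            for n1 in range(1, n):
                for k in range(1, n):
                    for a in range(max(0, k + n1 - n), min(k, n1) + 1):
                        carrier = np.zeros(n, dtype=bool)
                        case = np.zeros(n, dtype=bool)
                        case[:n1] = True
                        carrier[:a] = True  # a carriers among cases
                        carrier[n1 : n1 + (k - a)] = True
                        p = fb.permutation_burden_p(carrier, case, exhaustive=True)
                        expected = hypergeom.sf(a - 1, n, k, n1)
                        assert p == pytest.approx(expected, rel=1e-12)

    def test_monte_carlo_close_to_exact(self):
        carrier = np.array([True] * 3 + [False] * 9)
        case = np.array([True] * 4 + [False] * 8)
        exact = hypergeom.sf(2, 12, 3, 4)  # all 3 carriers are cases
        n_perm = 20_000
        p = fb.permutation_burden_p(carrier, case, n_perm=n_perm, seed=5)
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(p - exact) < 4 * se + 1 / n_perm

    def test_deterministic_under_seed(self):
        carrier = np.array([True, False] * 10)
        case = np.array([True] * 10 + [False] * 10)
        args = dict(n_perm=2000, seed=123)
        assert fb.permutation_burden_p(carrier, case, **args) == fb.permutation_burden_p(
            carrier, case, **args
        )


class TestFisherExact:
    def test_balanced_table(self):
        assert fb.fisher_exact_two_sided(1, 1, 1, 1) == 1.0

    def test_diagonal_table(self):
        assert fb.fisher_exact_two_sided(5, 0, 0, 5) == pytest.approx(2 / 252)

    def test_zero_margin(self):
        assert fb.fisher_exact_two_sided(0, 0, 3, 7) == 1.0

    @pytest.mark.parametrize(
        "table",
        [(3, 631, 0, 27173), (2, 148, 1, 1608), (10, 90, 10, 90), (0, 10, 5, 5), (7, 3, 2, 8)],
    )
    def test_matches_enumeration_oracle(self, table):
        assert fb.fisher_exact_two_sided(*table) == pytest.approx(
            fisher_two_sided_oracle(*table), rel=1e-9
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 25)] * 4))
    def test_oracle_agreement_random_tables(self, table):
        assert fb.fisher_exact_two_sided(*table) == pytest.approx(
            fisher_two_sided_oracle(*table), rel=1e-9
        )


class TestSegregation:
    def _setup(self):
        # pedigrees: F1 (2 affected), F2 (2 affected), F3 (1 affected)
        cohort = fb.CohortTable(
            [
                fb.Sample("F1_a", fb.FAMILIAL_CASE, "F1", True),
                fb.Sample("F1_b", fb.FAMILIAL_CASE, "F1", True),
                fb.Sample("F2_a", fb.FAMILIAL_CASE, "F2", True),
                fb.Sample("F2_b", fb.FAMILIAL_CASE, "F2", True),
                fb.Sample("F3_a", fb.FAMILIAL_CASE, "F3", True),
                fb.Sample("C1", fb.CONTROL),
            ]
        )
        peds = [
            fb.Pedigree(f, [
                fb.PedigreeMember(s, None, None, 1, True, s)
                for s in [f"{f}_a"] + ([f"{f}_b"] if f != "F3" else [])
            ])
            for f in ("F1", "F2", "F3")
        ]
        return cohort, peds

    def test_two_full_families_pass(self):
        cohort, peds = self._setup()
        v = make_variant([fb.HET, fb.HET, fb.HET, fb.HET, fb.HOM_REF, fb.HOM_REF])
        genes = fb.segregating_genes({"G1": [qv(v)]}, peds, cohort)
        assert genes == ["G1"]

    def test_partial_sharing_does_not_segregate(self):
        cohort, peds = self._setup()
        v = make_variant([fb.HET, fb.HOM_REF, fb.HET, fb.HET, fb.HOM_REF, fb.HOM_REF])
        records, counts = fb.segregation_scan({"G1": [qv(v)]}, peds, cohort)
        assert counts == {"G1": 1}  # only F2 fully shares
        assert fb.segregating_genes({"G1": [qv(v)]}, peds, cohort) == []

    def test_single_affected_pedigree_cannot_segregate(self):
        cohort, peds = self._setup()
        # only F3's single affected carries
        v = make_variant([fb.HOM_REF] * 4 + [fb.HET, fb.HOM_REF])
        _, counts = fb.segregation_scan({"G1": [qv(v)]}, peds, cohort)
        assert counts == {}

    def test_different_variants_per_family_count_for_gene(self):
        cohort, peds = self._setup()
        v1 = make_variant([fb.HET, fb.HET, fb.HOM_REF, fb.HOM_REF, fb.HOM_REF, fb.HOM_REF])
        v2 = make_variant([fb.HOM_REF, fb.HOM_REF, fb.HET, fb.HET, fb.HOM_REF, fb.HOM_REF], pos=200)
        assert fb.segregating_genes({"G1": [qv(v1), qv(v2)]}, peds, cohort) == ["G1"]


class TestRankGenes:
    def _result(self, gene, p, orr):
        return fb.BurdenResult(gene, 2, 150, 1, 1609, orr, p)

    def test_rank_order_by_p(self):
        ranked = fb.rank_genes([self._result("B", 6.4e-2, 3.6), self._result("A", 9.9e-3, 21.4)])
        assert [(r.gene, r.rank) for r in ranked] == [("A", 1), ("B", 2)]

    def test_tie_broken_by_or_then_symbol(self):
        ranked = fb.rank_genes(
            [self._result("Z", 0.01, 2.0), self._result("A", 0.01, 5.0), self._result("B", 0.01, 2.0)]
        )
        assert [r.gene for r in ranked] == ["A", "B", "Z"]

    def test_empty(self):
        assert fb.rank_genes([]) == []


class TestReplication:
    def test_case_only_carriers(self):
        p, orr = fb.replication_counts_test(3, 634, {"MAP4": (0, 27173)}, "MAP4")
        assert 0 < p < 1 and math.isinf(orr)

    def test_no_carriers_anywhere(self):
        p, orr = fb.replication_counts_test(0, 634, {"G": (0, 27173)}, "G")
        assert p == 1.0 and orr == 0.0

    def test_identical_rates(self):
        p, orr = fb.replication_counts_test(10, 100, {"G": (10, 100)}, "G")
        assert p == 1.0 and orr == pytest.approx(1.0)

    def test_absent_gene_skipped(self, caplog):
        with caplog.at_level("WARNING", logger="famburden"):
            assert fb.replication_counts_test(1, 10, {}, "NOPE") is None

    def test_external_counts_tsv(self, tmp_path):
        path = tmp_path / "ext.tsv"
        path.write_text("gene\tcarriers\ttotal\nMAP4\t0\t27173\n")
        assert fb.read_external_counts(path) == {"MAP4": (0, 27173)}


class TestNullCalibrationProperty:
    def test_super_uniform_p_values(self):
        """Permutation p-values of a discrete statistic are valid (super-uniform):
        P(p <= alpha) cannot exceed alpha by more than Monte-Carlo slack."""
        rng = np.random.default_rng(7)
        n1, n2 = 50, 200
        n_genes = 200
        hits = {0.05: 0, 0.01: 0}
        for _ in range(n_genes):
            carrier = rng.random(n1 + n2) < 0.01
            case = np.zeros(n1 + n2, dtype=bool)
            case[:n1] = True
            p = fb.permutation_burden_p(carrier, case, n_perm=500, seed=rng)
            for alpha in hits:
                hits[alpha] += p < alpha
        for alpha, h in hits.items():
            frac = h / n_genes
            slack = 3 * math.sqrt(alpha * (1 - alpha) / n_genes)
            assert frac <= alpha + slack
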