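"""Fisher exact differential testing, BH-FDR and distribution summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cfdna_ancestry.diff import (
    benjamini_hochberg,
    chromosome_distribution,
    consequence_proportions,
    fisher_exact_2x2,
    test_all_variants as run_variant_tests,
)
from cfdna_ancestry.errors import ValidationError
from cfdna_ancestry.variants import (
    AnnotatedVariant,
    CohortVariantMatrix,
    VariantKey,
)


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration over the whole table support."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    pmf = {
        k: math.comb(col1, k) * math.comb(n - col1, row1 - k) / math.comb(n, row1)
        for k in range(lo, hi + 1)
    }
    observed = pmf[a]
    return sum(p for p in pmf.values() if p <= observed * (1 + 1e-7))


class TestFisherExact:
    def test_balanced_table_has_p_one(self):
        assert fisher_exact_2x2(1, 1, 1, 1)[1] == pytest.approx(1.0)

    def test_perfect_association_small_table(self):
        odds, p = fisher_exact_2x2(2, 0, 0, 2)
        assert p == pytest.approx(1 / 3)
        assert odds == np.inf

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2(0, 0, 0, 0)

    def test_odds_ratio_conventions(self):
        assert fisher_exact_2x2(3, 2, 1, 4)[0] == pytest.approx(6.0)
        assert fisher_exact_2x2(0, 2, 1, 4)[0] == 0.0
        assert math.isnan(fisher_exact_2x2(0, 2, 0, 4)[0])

    @settings(max_examples=300, deadline=None)
    @given(a=st.integers(0, 12), b=st.integers(0, 12),
           c=st.integers(0, 12), d=st.integers(0, 12))
    def test_agrees_with_enumeration_and_scipy(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        _, p = fisher_exact_2x2(a, b, c, d)
        assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-9)
        # independent cross-check against scipy's implementation
        assert p == pytest.approx(
            float(stats.fisher_exact([[a, b], [c, d]])[1]), rel=1e-6
        )


def bh_step_up_oracle(p):
    """Hand step-up: q_(i) = min_{j>=i} p_(j) * m / j on sorted p."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(1.0, running)
    return q


class TestBenjaminiHochberg:
    def test_single_p(self):
        assert benjamini_hochberg([0.01]).tolist() == [0.01]

    def test_hand_step_up_example(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.5, 1.2])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    def test_matches_oracle_and_step_up_properties(self, p):
        q = benjamini_hochberg(p)
        assert q == pytest.approx(bh_step_up_oracle(p), rel=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-15)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        assert benjamini_hochberg(p) == pytest.approx(
            multipletests(p, method="fdr_bh")[1], rel=1e-12
        )


def make_matrix(a_carriers, c_carriers, n_aam=22, n_cm=66):
    """Matrix with given per-variant carrier counts in each cohort."""
    n_var = len(a_carriers)
    patients = [(f"A{i}", "AAM") for i in range(n_aam)] + [
        (f"C{i}", "CM") for i in range(n_cm)
    ]
    carrier = np.zeros((n_var, n_aam + n_cm), dtype=np.int8)
    for v, (ka, kc) in enumerate(zip(a_carriers, c_carriers)):
        carrier[v, :ka] = 1
        carrier[v, n_aam : n_aam + kc] = 1
    keys = [VariantKey("chr1", 1000 + v, "A", "G") for v in range(n_var)]
    return CohortVariantMatrix(keys, patients, carrier)


class TestTestAllVariants:
    def test_ubiquitous_variant_not_significant(self):
        matrix = make_matrix([22, 18], [66, 3])
        results = run_variant_tests(matrix)
        assert results[0].p == 1.0
        assert not results[0].significant

    def test_planted_variant_detected_with_aam_dominance(self):
        matrix = make_matrix([18, 5, 6], [3, 15, 18])
        results = run_variant_tests(matrix)
        assert results[0].significant and results[0].dominant == "AAM"

    def test_counts_partition_cohorts(self):
        matrix = make_matrix([4, 9], [10, 30])
        for r in run_variant_tests(matrix):
            assert r.a + r.b == 22
            assert r.c + r.d == 66

    def test_label_swap_preserves_p_and_flips_dominance(self):
        rng = np.random.default_rng(9)
        ka = rng.integers(0, 23, 30)
        kc = rng.integers(0, 67, 30)
        fwd = run_variant_tests(make_matrix(ka, kc))
        # swap: CM carriers become the 22-cohort? sizes differ, so swap roles
        rev = run_variant_tests(make_matrix(kc, ka, n_aam=66, n_cm=22))
        for f, r in zip(fwd, rev):
            assert f.p == pytest.approx(r.p, rel=1e-12)
            if f.dominant != "none":
                assert {f.dominant, r.dominant} == {"AAM", "CM"}

    def test_significant_set_monotone_in_alpha(self):
        rng = np.random.default_rng(13)
        matrix = make_matrix(rng.integers(0, 23, 60), rng.integers(0, 67, 60))
        sizes = [
            sum(r.significant for r in run_variant_tests(matrix, alpha))
            for alpha in (0.01, 0.05, 0.2, 1.0)
        ]
        assert sizes == sorted(sizes)

    def test_single_cohort_rejected(self):
        patients = [(f"A{i}", "AAM") for i in range(5)]
        matrix = CohortVariantMatrix(
            [VariantKey("chr1", 1, "A", "G")], patients, np.ones((1, 5), dtype=np.int8)
        )
        with pytest.raises(ValidationError):
            run_variant_tests(matrix)

    def test_bh_family_is_whole_run(self):
        matrix = make_matrix([18, 5], [3, 15])
        results = run_variant_tests(matrix)
        expected_q = benjamini_hochberg([r.p for r in results])
        assert [r.q for r in results] == pytest.approx(expected_q)


class TestConsequenceProportions:
    def _annotations(self, counts):
        ann = {}
        i = 0
        for cons, n in counts.items():
            for _ in range(n):
                key = VariantKey("chr1", 10 + i, "A", "G")
                ann[key] = AnnotatedVariant(key, f"G{i}", cons)
                i += 1
        return ann

    def test_identical_sets_are_homogeneous(self):
        ann = self._annotations({"intronic": 10, "missense": 10})
        keys = list(ann)
        _, p = consequence_proportions(ann, {"s1": keys, "s2": keys})
        assert p == 1.0

    def test_matches_chi_square_oracle(self):
        ann = self._annotations({"intronic": 12, "missense": 6, "UTR": 6})
        keys = list(ann)
        sets = {"s1": keys[:10], "s2": keys[10:]}
        frame, p = consequence_proportions(ann, sets)
        table = (
            frame.pivot(index="set", columns="consequence", values="count")
            .fillna(0)
            .to_numpy()
        )
        assert p == pytest.approx(stats.chi2_contingency(table, correction=False)[1])

    def test_empty_set_excluded(self):
        ann = self._annotations({"intronic": 4})
        frame, p = consequence_proportions(ann, {"s1": list(ann), "empty": []})
        assert set(frame["set"]) == {"s1"}
        assert math.isnan(p)


class TestChromosomeDistribution:
    def test_counts_in_karyotype_order(self):
        matrix = make_matrix([18, 5, 9], [3, 15, 12])
        results = run_variant_tests(matrix)
        # relocate keys across contigs
        results = [
            r.__class__(VariantKey(c, r.key.pos, "A", "G"), r.a, r.b, r.c, r.d,
                        r.odds_ratio, r.p, r.q, r.significant, r.dominant)
            for r, c in zip(results, ["chr7", "chr7", "chrY"])
        ]
        dist = chromosome_distribution(results)
        assert dist.loc[dist.contig == "chr7", "n_variants"].iloc[0] == 2
        assert dist.loc[dist.contig == "chrY", "n_variants"].iloc[0] == 1
        assert dist.loc[dist.contig == "chr18", "n_variants"].iloc[0] == 0
        assert list(dist.contig[:3]) == ["chr1", "chr2", "chr3"]

    def test_empty_input_all_zeros(self):
        dist = chromosome_distribution([])
        assert dist["n_variants"].sum() == 0
        assert len(dist) == 24
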