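"""Variant identity, VCF ingestion, consensus filtering and the cohort matrix."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cfdna_ancestry.errors import FormatError, ValidationError
from cfdna_ancestry.variants import (
    CohortVariantMatrix,
    VariantCall,
    VariantKey,
    build_cohort_matrix,
    filter_calls,
    harmonize_contig,
    intersect_callers,
    normalize_variant,
    read_sample_vcf,
)

from conftest import write_vcf


def minimal_representation_oracle(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Brute force: try every valid (suffix, prefix) trim; pick the shortest
    alleles, breaking ties toward the smallest position (left-anchored)."""
    candidates = []
    for s in range(min(len(ref), len(alt))):  # suffix bases removed
        if s and ref[-s:] != alt[-s:]:
            break
        r1, a1 = ref[: len(ref) - s], alt[: len(alt) - s]
        if not r1 or not a1:
            continue
        for p in range(min(len(r1), len(a1))):
            if p and r1[:p] != a1[:p]:
                break
            r2, a2 = r1[p:], a1[p:]
            if r2 and a2:
                candidates.append((len(r2) + len(a2), pos + p, r2, a2))
    _, best_pos, best_ref, best_alt = min(candidates)
    return best_pos, best_ref, best_alt


class TestNormalizeVariant:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            (("chr7", 100, "A", "G"), ("chr7", 100, "A", "G")),
            (("chr1", 100, "AT", "AG"), ("chr1", 101, "T", "G")),
            (("chr2", 50, "CAA", "CA"), ("chr2", 50, "CA", "C")),
            (("chr3", 10, "GAT", "GCT"), ("chr3", 11, "A", "C")),
            (("chrX", 5, "TTT", "TT"), ("chrX", 5, "TT", "T")),
        ],
    )
    def test_examples_match_brute_force_oracle(self, raw, expected):
        contig, pos, ref, alt = raw
        key = normalize_variant(contig, pos, ref, alt)
        assert (key.contig, key.pos, key.ref, key.alt) == expected
        assert (key.pos, key.ref, key.alt) == minimal_representation_oracle(pos, ref, alt)

    @pytest.mark.parametrize(
        "bad",
        [("chr1", 10, "", "A"), ("chr1", 10, "A", ""), ("chr1", 10, "AN", "A"),
         ("chr1", 10, "A", "a-"), ("chr1", 0, "A", "G"), ("chr1", 10, "A", "A")],
    )
    def test_malformed_input_rejected(self, bad):
        with pytest.raises(ValidationError):
            normalize_variant(*bad)

    def test_bare_contig_harmonized(self):
        assert normalize_variant("7", 1, "A", "G").contig == "chr7"
        assert harmonize_contig("MT") == "chrM"

    @settings(max_examples=200, deadline=None)
    @given(
        pos=st.integers(1, 10_000),
        core_ref=st.text("ACGT", min_size=1, max_size=4),
        core_alt=st.text("ACGT", min_size=1, max_size=4),
        prefix=st.text("ACGT", max_size=3),
        suffix=st.text("ACGT", max_size=3),
    )
    def test_idempotent_and_matches_oracle(self, pos, core_ref, core_alt, prefix, suffix):
        ref, alt = prefix + core_ref + suffix, prefix + core_alt + suffix
        if ref == alt:
            return
        key = normalize_variant("chr1", pos, ref, alt)
        again = normalize_variant(key.contig, key.pos, key.ref, key.alt)
        assert key == again
        assert (key.pos, key.ref, key.alt) == minimal_representation_oracle(pos, ref, alt)

    def test_keys_totally_ordered(self):
        keys = [VariantKey("chr2", 5, "A", "G"), VariantKey("chr1", 9, "C", "T"),
                VariantKey("chr1", 9, "A", "T"), VariantKey("chr1", 2, "G", "C")]
        assert sorted(keys) == [keys[3], keys[2], keys[1], keys[0]]


class TestReadSampleVcf:
    def test_single_biallelic_row(self, tmp_path):
        path = write_vcf(tmp_path / "s.vcf", ["chr1\t100\t.\tA\tG\t45.0\tPASS\tDP=250"])
        calls = read_sample_vcf(path, "freebayes", "S1")
        assert len(calls) == 1
        call = calls[0]
        assert call.key == VariantKey("chr1", 100, "A", "G")
        assert (call.depth, call.quality, call.caller) == (250, 45.0, "freebayes")

    def test_multiallelic_split_into_distinct_keys(self, tmp_path):
        path = write_vcf(tmp_path / "s.vcf", ["chr1\t100\t.\tA\tG,T\t45.0\tPASS\tDP=300"])
        calls = read_sample_vcf(path, "lofreq", "S1")
        assert {c.key for c in calls} == {
            VariantKey("chr1", 100, "A", "G"),
            VariantKey("chr1", 100, "A", "T"),
        }
        assert all(c.depth == 300 for c in calls)

    def test_empty_body_gives_empty_list(self, tmp_path):
        path = write_vcf(tmp_path / "s.vcf", [])
        assert read_sample_vcf(path, "freebayes", "S1") == []

    def test_missing_depth_defaults_to_zero(self, tmp_path):
        path = write_vcf(tmp_path / "s.vcf", ["chr1\t100\t.\tA\tG\t45.0\tPASS\t."])
        assert read_sample_vcf(path, "freebayes", "S1")[0].depth == 0

    def test_unreadable_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.vcf"
        bad.write_text("this is not a vcf\n")
        with pytest.raises(FormatError):
            read_sample_vcf(bad, "freebayes", "S1")


def _call(depth, quality, key=None, sample="S1", caller="freebayes"):
    key = key or VariantKey("chr1", 100, "A", "G")
    return VariantCall(key, sample, caller, depth, quality)


class TestFilterCalls:
    @pytest.mark.parametrize(
        "depth, quality, kept",
        [(199, 30.0, True), (198, 99.0, False), (500, 29.9, False),
         (199, 29.999, False), (10_000, 30.0, True)],
    )
    def test_strictly_lower_values_excluded(self, depth, quality, kept):
        out = filter_calls([_call(depth, quality)])
        assert (len(out) == 1) is kept

    def test_empty_input(self):
        assert filter_calls([]) == []


class TestIntersectCallers:
    def test_consensus_semantics(self):
        k1 = VariantKey("chr1", 100, "A", "G")
        k2 = VariantKey("chr1", 200, "C", "T")
        fb = [_call(300, 50, k1), _call(300, 50, k2)]
        lf = [_call(280, 44, k1, caller="lofreq")]
        assert intersect_callers(fb, lf) == [k1]
        assert intersect_callers(fb, []) == []

    def test_mixed_sample_ids_rejected(self):
        k = VariantKey("chr1", 100, "A", "G")
        with pytest.raises(ValidationError):
            intersect_callers([_call(300, 50, k, "S1"), _call(300, 50, k, "S2")], [])

    def test_filter_and_intersect_commute_with_shared_depths(self):
        """When both callers report identical depth/quality per key, filtering
        before or after intersecting yields the same consensus set."""
        rng = np.random.default_rng(5)
        keys = [VariantKey("chr1", int(p), "A", "G") for p in range(100, 160)]
        fb, lf = [], []
        for k in keys:
            d, q = int(rng.integers(100, 400)), float(rng.uniform(10, 60))
            fb.append(_call(d, q, k))
            if rng.random() < 0.7:
                lf.append(_call(d, q, k, caller="lofreq"))
        first_filter = intersect_callers(filter_calls(fb), filter_calls(lf))
        both = set(intersect_callers(fb, lf))
        first_intersect = sorted(
            {c.key for c in filter_calls([c for c in fb if c.key in both])}
        )
        assert first_filter == first_intersect


class TestBuildCohortMatrix:
    def test_carrier_counts_small(self, metadata_frame):
        k = VariantKey("chr1", 100, "A", "G")
        matrix = build_cohort_matrix(
            {"A1": [k], "A2": [], "C1": [], "C2": [], "C3": []}, metadata_frame
        )
        assert matrix.carrier_counts("AAM").tolist() == [1]
        assert matrix.carrier_counts("CM").tolist() == [0]
        assert matrix.cohort_sizes == {"AAM": 2, "CM": 3}

    def test_duplicate_keys_counted_once(self, metadata_frame):
        k = VariantKey("chr1", 100, "A", "G")
        matrix = build_cohort_matrix(
            {"A1": [k, k], "A2": [], "C1": [k], "C2": [], "C3": []}, metadata_frame
        )
        assert matrix.carrier.sum() == 2

    def test_sample_without_metadata_listed_in_error(self, metadata_frame):
        with pytest.raises(ValidationError, match="ZZ9"):
            build_cohort_matrix({"ZZ9": []}, metadata_frame)

    def test_dimensions_match_generator_metadata(self, bundle):
        from cfdna_ancestry.synthetic import generate_carrier_matrix

        matrix, truth = generate_carrier_matrix(bundle["cfg"])
        assert len(matrix.patients) == 88
        assert matrix.cohort_sizes == {"AAM": 22, "CM": 66}
        assert len(matrix.variants) == len(truth.table)
        # matrix invariant: every variant has at least one carrier
        assert (matrix.carrier.sum(axis=1) >= 1).all()

    def test_matrix_sums_match_set_union_oracle(self, metadata_frame):
        rng = np.random.default_rng(11)
        keys = [VariantKey("chr1", int(p), "A", "G") for p in range(100, 130)]
        consensus = {
            sid: [k for k in keys if rng.random() < 0.4]
            for sid in metadata_frame["sample_id"]
        }
        matrix = build_cohort_matrix(consensus, metadata_frame)
        for i, v in enumerate(matrix.variants):
            expected = sum(1 for s in consensus.values() if v in s)
            assert matrix.carrier[i].sum() == expected
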