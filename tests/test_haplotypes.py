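"""Variant QC, haplotype enumeration and sequence construction."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfs.haplotypes import (
    UnphasedGenotypeError,
    VariantRecord,
    build_sequence,
    enumerate_haplotypes,
    hwe_exact_test,
    qc_filter,
)


def variant(genotypes, pos=150, ref="A", alt="G", info=None, phased=None):
    return VariantRecord("chr1", pos, ref, alt, np.array(genotypes),
                         phased=phased, info_score=info)


def hwe_oracle(n_het, n_hom_ref, n_hom_alt):
    """Exact-rational enumeration of the conditional het-count law."""
    n = n_het + n_hom_ref + n_hom_alt
    na = 2 * n_hom_ref + n_het  # count of one allele
    nb = 2 * n - na
    probs = {}
    for h in range(min(na, nb) % 2, min(na, nb) + 1, 2):
        hr = (na - h) // 2
        hb = (nb - h) // 2
        if hr < 0 or hb < 0:
            continue
        # multinomial genotype configurations over ordered allele draws
        probs[h] = Fraction(
            2**h * comb(n, h) * comb(n - h, hr), 1
        )
    total = sum(probs.values())
    probs = {h: p / total for h, p in probs.items()}
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHWE:
    @pytest.mark.parametrize(
        "het,hom_ref,hom_alt",
        [(5, 10, 2), (0, 20, 5), (10, 0, 0), (3, 3, 3), (50, 25, 25), (1, 99, 0)],
    )
    def test_matches_enumeration_oracle(self, het, hom_ref, hom_alt):
        assert hwe_exact_test(het, hom_ref, hom_alt) == pytest.approx(
            hwe_oracle(het, hom_ref, hom_alt), rel=1e-9
        )

    def test_monomorphic_is_one(self):
        assert hwe_exact_test(0, 50, 0) == 1.0


class TestQCFilter:
    def make_cohort(self, n=200, alt_freq=0.3, seed=0):
        rng = np.random.default_rng(seed)
        return rng.binomial(1, alt_freq, size=(n, 2)).astype(np.int8)

    def test_clean_variant_retained(self):
        v = variant(self.make_cohort(), info=0.95)
        kept, dropped = qc_filter([v], 200)
        assert kept == [v] and dropped == []

    def test_low_info_removed(self):
        v = variant(self.make_cohort(), info=0.79)
        assert qc_filter([v], 200)[0] == []

    def test_absent_info_passes(self):
        v = variant(self.make_cohort(), info=None)
        assert qc_filter([v], 200)[0] == [v]

    def test_allele_count_boundary(self):
        # 9 alt alleles in 200 individuals -> removed; 10 -> kept
        for mac, expected in [(9, 0), (10, 1)]:
            g = np.zeros((200, 2), dtype=np.int8)
            g[:mac, 0] = 1
            v = variant(g)
            # force HWE pass irrelevant: few hets only
            assert len(qc_filter([v], 200)[0]) == expected

    def test_hwe_violation_removed(self):
        # all heterozygous: gross HWE violation at n = 100
        g = np.tile([0, 1], (100, 1)).astype(np.int8)
        v = variant(g)
        assert hwe_exact_test(100, 0, 0) < 1e-6
        assert qc_filter([v], 100)[0] == []

    def test_missing_rate_and_individual_drop(self):
        g = self.make_cohort(100)
        g[:25, :] = -1  # 25% missing -> variant dropped
        assert qc_filter([variant(g)], 100)[0] == []
        g2 = self.make_cohort(100, seed=1)
        g2[0, :] = -1  # 1% missing: variant kept, individual 0 misses 100%
        kept, dropped = qc_filter([variant(g2)], 100)
        assert len(kept) == 1 and dropped == [0]

    def test_empty_result_not_error(self):
        assert qc_filter([], 10) == ([], [])
        with pytest.raises(ValueError):
            qc_filter([], 0)


class TestEnumerateHaplotypes:
    def test_all_homozygous_reference(self):
        v = variant(np.zeros((3, 2), dtype=np.int8))
        t = enumerate_haplotypes([v], "L1")
        assert t.n_haplotypes == 1
        assert (t.individual_map == 0).all()
        assert t.hap_counts.tolist() == [6]

    def test_single_het(self):
        g = np.zeros((3, 2), dtype=np.int8)
        g[0] = [0, 1]
        t = enumerate_haplotypes([variant(g)], "L1")
        assert t.n_haplotypes == 2
        assert t.individual_map[0].tolist() == [0, 1]
        assert t.hap_counts.tolist() == [5, 1]

    def test_four_distinct_from_two_snps(self):
        # phased pairs 0|0 1|1 and 1|0 0|1 over two SNPs
        v1 = variant(np.array([[0, 1], [1, 0]]), pos=110)
        v2 = variant(np.array([[0, 1], [0, 1]]), pos=120)
        t = enumerate_haplotypes([v1, v2], "L1")
        haps = {tuple(row) for row in t.alleles}
        assert haps == {(0, 0), (1, 1), (1, 0), (0, 1)}
        assert t.n_haplotypes == 4

    def test_reference_always_index_zero(self):
        g = np.ones((3, 2), dtype=np.int8)  # nobody carries the reference
        t = enumerate_haplotypes([variant(g)], "L1")
        assert t.alleles[0].tolist() == [0]
        assert t.hap_counts[0] == 0

    def test_unphased_het_raises(self):
        g = np.array([[0, 1]], dtype=np.int8)
        v = variant(g, phased=np.array([False]))
        with pytest.raises(UnphasedGenotypeError, match="individual 0"):
            enumerate_haplotypes([v], "L1")

    def test_counts_invariant_under_reordering(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 2, size=(20, 2)).astype(np.int8)
        t1 = enumerate_haplotypes([variant(g)], "L")
        t2 = enumerate_haplotypes([variant(g[::-1].copy())], "L")
        assert sorted(t1.hap_counts) == sorted(t2.hap_counts)


REF = ("ACGT" * 1024)


class TestBuildSequence:
    def test_reference_round_trip(self):
        v = variant(np.zeros((1, 2), np.int8), pos=101, ref="A", alt="G")
        assert build_sequence(REF, [0], [v], locus_start=0) == REF

    def test_single_snp(self):
        v = variant(np.zeros((1, 2), np.int8), pos=101, ref="A", alt="G")
        out = build_sequence(REF, [1], [v], locus_start=0)
        diffs = [i for i in range(4096) if out[i] != REF[i]]
        assert diffs == [100] and out[100] == "G"

    def test_deletion_pads_n(self):
        # 5-bp deletion: REF = 6 bases, ALT = first base
        v = variant(np.zeros((1, 2), np.int8), pos=101, ref=REF[100:106], alt=REF[100])
        out = build_sequence(REF, [1], [v], locus_start=0)
        assert len(out) == 4096
        assert out.endswith("N" * 5) and not out.endswith("N" * 6)
        assert out[:100] == REF[:100] and out[101:110] == REF[106:115]

    def test_insertion_truncates_three_prime(self):
        v = variant(np.zeros((1, 2), np.int8), pos=101, ref=REF[100], alt=REF[100] + "TTT")
        out = build_sequence(REF, [1], [v], locus_start=0)
        assert len(out) == 4096
        assert out == (REF[:101] + "TTT" + REF[101:])[:4096]

    def test_ref_mismatch_raises(self):
        v = variant(np.zeros((1, 2), np.int8), pos=101, ref="T", alt="G")  # REF has A
        with pytest.raises(ValueError, match="REF mismatch"):
            build_sequence(REF, [1], [v], locus_start=0)

    def test_overlapping_indels_raise(self):
        v1 = variant(np.zeros((1, 2), np.int8), pos=101, ref=REF[100:110], alt=REF[100])
        v2 = variant(np.zeros((1, 2), np.int8), pos=105, ref=REF[104], alt="T")
        with pytest.raises(ValueError, match="overlapping"):
            build_sequence(REF, [1, 1], [v1, v2], locus_start=0)

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_length_always_4096(self, data):
        """Any combination of SNPs and indels yields exactly 4096 bp."""
        rng_positions = data.draw(
            st.lists(st.integers(10, 4000), min_size=1, max_size=8, unique=True)
        )
        variants = []
        prev_end = -1
        for pos0 in sorted(rng_positions):
            if pos0 <= prev_end:
                continue
            kind = data.draw(st.sampled_from(["snp", "ins", "del"]))
            if kind == "snp":
                ref, alt = REF[pos0], "G" if REF[pos0] != "G" else "C"
                prev_end = pos0
            elif kind == "ins":
                ref, alt = REF[pos0], REF[pos0] + data.draw(st.text("ACGT", min_size=1, max_size=10))
                prev_end = pos0
            else:
                dlen = data.draw(st.integers(1, 10))
                ref, alt = REF[pos0 : pos0 + dlen + 1], REF[pos0]
                prev_end = pos0 + dlen
            variants.append(
                variant(np.zeros((1, 2), np.int8), pos=pos0 + 1, ref=ref, alt=alt)
            )
        out = build_sequence(REF, [1] * len(variants), variants, locus_start=0)
        assert len(out) == 4096
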