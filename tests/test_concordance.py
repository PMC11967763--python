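import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdoconcord import (
    CopyProfilePair,
    GeneCopyState,
    InsufficientDataError,
    PairingError,
    SomaticVariant,
    cnv_similarity,
    compare_af,
    correct_allelic_fraction,
    filter_confident_variants,
    gene_distance,
    partition_variants,
)

from conftest import brute_force_similarity, random_pair


def gcs(gene, a, b):
    return GeneCopyState(gene, a, b)


def make_pair(tumor, organoid):
    return CopyProfilePair(
        sample_id="P",
        tumor=tuple(gcs(f"G{i}", *t) for i, t in enumerate(tumor)),
        organoid=tuple(gcs(f"G{i}", *o) for i, o in enumerate(organoid)),
    )


class TestGeneDistance:
    @pytest.mark.parametrize(
        "t, o, expected",
        [
            ((2, 1), (2, 1), 0.0),
            ((3, 0), (2, 0), 1.0),
            ((2, 0), (2, 2), 2.0),  # sorted to major/minor: (2,0) vs (2,2)
        ],
    )
    def test_hand_values(self, t, o, expected):
        assert gene_distance(gcs("G", *t), gcs("G", *o)) == pytest.approx(expected)

    def test_euclidean_on_both_alleles(self):
        # sqrt((2-0)^2 ... ) requires valid cnA>=cnB states; use (2,0) vs (4,2)
        d = gene_distance(gcs("G", 2, 0), gcs("G", 4, 2))
        assert d == pytest.approx(math.sqrt(8), abs=1e-9)

    def test_gene_mismatch_raises(self):
        with pytest.raises(PairingError):
            gene_distance(gcs("A", 1, 1), gcs("B", 1, 1))

    def test_copy_state_ordering_enforced(self):
        with pytest.raises(ValueError):
            GeneCopyState("G", 1, 2)


class TestCnvSimilarity:
    def test_identical_profiles_score_one(self):
        pair = make_pair([(2, 1), (3, 0)], [(2, 1), (3, 0)])
        res = cnv_similarity(pair)
        assert res.summary_s == 1.0
        assert res.degenerate

    def test_three_gene_hand_computation(self):
        pair = make_pair([(2, 1), (3, 0), (2, 2)], [(2, 1), (2, 0), (4, 2)])
        res = cnv_similarity(pair)
        assert res.per_gene_d == pytest.approx([0.0, 1.0, 2.0])
        assert res.per_gene_s == pytest.approx([1.0, 0.5, 0.0])
        assert res.summary_s == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            pair = random_pair(rng)
            res = cnv_similarity(pair)
            d, s, summary = brute_force_similarity(pair)
            np.testing.assert_allclose(res.per_gene_d, d, atol=1e-12)
            np.testing.assert_allclose(res.per_gene_s, s, atol=1e-12)
            assert res.summary_s == pytest.approx(summary, abs=1e-12)

    def test_symmetry_under_sample_swap(self):
        rng = np.random.default_rng(3)
        pair = random_pair(rng)
        swapped = CopyProfilePair("P", pair.organoid, pair.tumor)
        a, b = cnv_similarity(pair), cnv_similarity(swapped)
        np.testing.assert_allclose(a.per_gene_s, b.per_gene_s)
        assert a.summary_s == b.summary_s

    def test_similarity_bounded_fuzz(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            res = cnv_similarity(random_pair(rng, n_genes=int(rng.integers(1, 30))))
            assert np.all(res.per_gene_s >= 0) and np.all(res.per_gene_s <= 1)
            assert 0.0 <= res.summary_s <= 1.0

    def test_increasing_one_distance_cannot_raise_its_similarity(self):
        base = make_pair([(2, 1), (3, 0), (2, 2)], [(2, 1), (2, 0), (4, 2)])
        moved = make_pair([(2, 1), (3, 0), (2, 2)], [(2, 1), (2, 0), (6, 2)])
        assert cnv_similarity(moved).per_gene_s[2] <= \
            cnv_similarity(base).per_gene_s[2]

    def test_median_summary_option(self):
        pair = make_pair([(2, 1), (3, 0), (2, 2)], [(2, 1), (2, 0), (4, 2)])
        assert cnv_similarity(pair, summary="median").summary_s == 0.5

    def test_misaligned_genes_raise(self):
        with pytest.raises(PairingError):
            CopyProfilePair("P", (gcs("A", 1, 1),), (gcs("B", 1, 1),))

    def test_empty_profile_raises(self):
        with pytest.raises(InsufficientDataError):
            CopyProfilePair("P", (), ())


def var(chrom, pos, vaf=0.3, deleterious=True, ref="A", alt="T"):
    return SomaticVariant(chrom=chrom, pos=pos, ref=ref, alt=alt, vaf=vaf,
                          deleterious=deleterious)


class TestVariantFilterAndPartition:
    def test_vaf_filter_is_strict(self):
        vs = [var("1", 1, 0.04), var("1", 2, 0.05), var("1", 3, 0.20)]
        kept = filter_confident_variants(vs)
        assert [v.pos for v in kept] == [3]

    def test_filter_passthrough_and_empty(self):
        vs = [var("1", 1, 0.2), var("1", 2, 0.6)]
        assert filter_confident_variants(vs) == vs
        assert filter_confident_variants([]) == []

    def test_partition_set_arithmetic(self):
        tumor = [var("1", p) for p in (1, 2, 3)]
        organoid = [var("1", p) for p in (2, 3, 4)]
        part = partition_variants(tumor, organoid)
        assert len(part.shared) == 2
        assert len(part.tumor_private) == 1
        assert len(part.organoid_private) == 1
        assert part.proportions == pytest.approx((0.5, 0.25, 0.25))

    def test_identical_and_disjoint_sets(self):
        same = [var("1", p) for p in (1, 2)]
        assert partition_variants(same, same).proportions == (1.0, 0.0, 0.0)
        t = [var("1", p) for p in (1, 2, 3)]
        o = [var("2", p) for p in (1, 2)]
        assert partition_variants(t, o).proportions == pytest.approx((0, 0.6, 0.4))

    def test_proportions_sum_and_tumor_identity(self):
        rng = np.random.default_rng(5)
        t = [var("1", int(p)) for p in rng.choice(100, 30, replace=False)]
        o = [var("1", int(p)) for p in rng.choice(100, 40, replace=False)]
        part = partition_variants(t, o)
        assert sum(part.proportions) == pytest.approx(1.0)
        assert len(part.shared) + len(part.tumor_private) == len(t)

    def test_duplicate_key_raises(self):
        with pytest.raises(ValueError, match="duplicate"):
            partition_variants([var("1", 1), var("1", 1)], [])

    def test_deleterious_only_flag(self):
        t = [var("1", 1, deleterious=True), var("1", 2, deleterious=False)]
        o = [var("1", 1, deleterious=True)]
        part = partition_variants(t, o, deleterious_only=True)
        assert len(part.shared) == 1 and len(part.tumor_private) == 0


class TestCorrectedAF:
    @pytest.mark.parametrize(
        "vaf, purity, expected",
        [(0.25, 0.5, 0.5), (0.33, 1.0, 0.33), (0.8, 0.5, 1.0)],
    )
    def test_correction_and_cap(self, vaf, purity, expected):
        assert correct_allelic_fraction(var("1", 1, vaf), purity) == \
            pytest.approx(expected)

    def test_invalid_purity(self):
        with pytest.raises(ValueError):
            correct_allelic_fraction(var("1", 1, 0.2), 0.0)


class TestCompareAF:
    def test_identical_groups_give_large_p(self):
        _, p = compare_af([0.3, 0.4, 0.5], [0.3, 0.4, 0.5])
        assert p > 0.99

    def test_exact_p_matches_enumeration_oracle(self):
        shared = [0.9, 0.8, 0.85, 0.95]
        private = [0.1, 0.15, 0.2, 0.05]
        u, p = compare_af(shared, private)
        # enumerate all C(8,4) rank assignments of the shared group
        vals = sorted(shared + private)
        observed_u = sum(
            1 for a in shared for b in private if a > b
        )
        n1 = len(shared)
        count_as_extreme = 0
        total = 0
        for idx in combinations(range(8), n1):
            grp = [vals[i] for i in idx]
            rest = [vals[i] for i in range(8) if i not in idx]
            u_perm = sum(1 for a in grp for b in rest if a > b)
            # two-sided: U as far from the mean (8) as observed
            if abs(u_perm - 8) >= abs(observed_u - 8):
                count_as_extreme += 1
            total += 1
        assert total == 70
        assert p == pytest.approx(count_as_extreme / total, abs=1e-12)

    def test_empty_group_raises(self):
        with pytest.raises(InsufficientDataError):
            compare_af([], [0.1])

    def test_separated_groups_reject_at_scale(self):
        rng = np.random.default_rng(11)
        shared = rng.beta(15, 35, 200)  # mean 0.30
        private = rng.beta(5, 45, 200)  # mean 0.10
        _, p = compare_af(shared, private)
        assert p < 1e-6


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.floats(0, 6, allow_nan=False), st.floats(0, 6, allow_nan=False)
        ),
        min_size=1,
        max_size=20,
    ),
    st.lists(
        st.tuples(
            st.floats(0, 6, allow_nan=False), st.floats(0, 6, allow_nan=False)
        ),
        min_size=1,
        max_size=20,
    ),
)
def test_similarity_in_unit_interval_property(tumor_cn, organoid_cn):
    """s stays in [0,1] for arbitrary valid copy states (fuzz invariant)."""
    n = min(len(tumor_cn), len(organoid_cn))
    pair = make_pair(
        [(max(a, b), min(a, b)) for a, b in tumor_cn[:n]],
        [(max(a, b), min(a, b)) for a, b in organoid_cn[:n]],
    )
    res = cnv_similarity(pair)
    assert np.all((res.per_gene_s >= 0) & (res.per_gene_s <= 1))
    assert 0.0 <= res.summary_s <= 1.0
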