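"""Activity cooperativity (cosine), TFBS similarity (Jaccard) and
distance-matched background sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sskit.caller import stitch
from sskit.cooperativity import (
    MATCHED_BACKGROUND,
    PairSample,
    cooperativity_score,
    matched_background_pairs,
    random_background_pairs,
    score_pairs,
    shared_tf_fraction,
    ternary_activity,
    tfbs_similarity,
)
from sskit.core import (
    ActivityMatrix,
    GenomicInterval,
    IntervalIndex,
    SskitError,
    TFBSMatrix,
)

from conftest import make_elements

ternary_vec = st.lists(st.sampled_from([-1, 0, 1]), min_size=1, max_size=30)


class TestTernaryActivity:
    element = GenomicInterval("chr1", 1000, 2000)

    def idx(self, *ivs):
        return IntervalIndex(ivs)

    def test_ac_only_is_active(self):
        assert ternary_activity(self.element, self.idx(GenomicInterval("chr1", 1500, 1600)), self.idx()) == 1

    def test_me3_only_is_repressed(self):
        assert ternary_activity(self.element, self.idx(), self.idx(GenomicInterval("chr1", 0, 1001))) == -1

    def test_both_marks_uncertain(self):
        peak = GenomicInterval("chr1", 900, 2100)
        assert ternary_activity(self.element, self.idx(peak), self.idx(peak)) == 0

    def test_neither_mark_no_evidence(self):
        assert ternary_activity(self.element, self.idx(), self.idx()) == 0


class TestCooperativityScore:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((1, -1, 0), (1, -1, 0), 1.0),
            ((1, 0, 0), (0, 1, 0), 0.0),
            ((1, 0, 1), (1, 1, 0), 0.5),
            ((1, 1), (-1, -1), -1.0),
        ],
    )
    def test_forced_arithmetic(self, a, b, expected):
        assert cooperativity_score(a, b) == pytest.approx(expected)

    def test_zero_vector_undefined(self):
        with pytest.raises(SskitError):
            cooperativity_score([0, 0], [1, 0])

    @given(a=ternary_vec, b=ternary_vec)
    @settings(max_examples=300, deadline=None)
    def test_symmetry_bounds_and_joint_sign_flip(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        if not any(a) or not any(b):
            return
        s = cooperativity_score(a, b)
        assert -1.0 - 1e-12 <= s <= 1.0 + 1e-12
        assert s == pytest.approx(cooperativity_score(b, a))
        flipped = cooperativity_score([-x for x in a], [-x for x in b])
        assert s == pytest.approx(flipped)
        assert cooperativity_score(a, a) == pytest.approx(1.0)


class TestTFBSSimilarity:
    def test_examples(self):
        # {A,B} vs {B,C} over G = {A,B,C,D}
        assert tfbs_similarity([1, 1, 0, 0], [0, 1, 1, 0]) == pytest.approx(1 / 3)
        assert tfbs_similarity([1, 0, 1], [1, 0, 1]) == 1.0
        assert tfbs_similarity([1, 0], [0, 1]) == 0.0
        assert tfbs_similarity([0, 0], [0, 0]) == 0.0  # both empty

    def test_equals_set_algebra_on_random_instances(self, rng):
        for _ in range(300):
            g = int(rng.integers(1, 40))
            a = rng.random(g) < 0.3
            b = rng.random(g) < 0.3
            sa, sb = set(np.nonzero(a)[0]), set(np.nonzero(b)[0])
            expected = len(sa & sb) / len(sa | sb) if (sa | sb) else 0.0
            assert tfbs_similarity(a.astype(int), b.astype(int)) == pytest.approx(expected)


class TestSharedTFFraction:
    def test_single_shared_tf_over_panel(self):
        elements = make_elements([0, 2000, 4000], prefix="c")
        (region,) = stitch(elements, 12_500)
        values = np.zeros((3, 168), dtype=int)
        values[0, 7] = values[1, 7] = 1  # one TF bound in two constituents
        values[2, 9] = 1
        tfbs = TFBSMatrix(values, [e.id for e in elements], [f"TF{i}" for i in range(168)])
        assert shared_tf_fraction(region, tfbs) == pytest.approx(1 / 168)

    def test_no_shared_tf_gives_zero(self):
        elements = make_elements([0, 2000], prefix="c")
        (region,) = stitch(elements, 12_500)
        tfbs = TFBSMatrix(np.eye(2, 10, dtype=int), [e.id for e in elements],
                          [f"TF{i}" for i in range(10)])
        assert shared_tf_fraction(region, tfbs) == 0.0

    def test_matches_exhaustive_column_scan(self, rng):
        elements = make_elements(np.arange(10) * 3000, prefix="c")
        (region,) = stitch(elements, 12_500)
        values = (rng.random((10, 20)) < 0.4).astype(int)
        tfbs = TFBSMatrix(values, [e.id for e in elements], [f"TF{i}" for i in range(20)])
        expected = sum(values[:, g].sum() >= 2 for g in range(20)) / 20
        assert shared_tf_fraction(region, tfbs) == pytest.approx(expected)

    def test_fewer_than_two_constituents_flagged(self):
        (region,) = stitch(make_elements([0]), 100)
        tfbs = TFBSMatrix(np.zeros((1, 5), dtype=int), ["e0"], list("ABCDE"))
        with pytest.raises(SskitError):
            shared_tf_fraction(region, tfbs)


def _uniform_pool(rng, n=2000, chrom_len=10_000_000):
    starts = np.sort(rng.integers(0, chrom_len, n))
    return make_elements(starts, lengths=1500, prefix="bk")


class TestMatchedBackgroundPairs:
    def test_deterministic_given_seed(self, rng):
        pool = _uniform_pool(rng, 800)
        target = rng.lognormal(np.log(30_000), 0.5, 200).astype(int)
        a = matched_background_pairs(target, pool, 100, seed=5)
        b = matched_background_pairs(target, pool, 100, seed=5)
        assert a == b
        assert all(p.group == MATCHED_BACKGROUND for p in a)

    def test_single_bin_target_stays_in_bin(self, rng):
        pool = _uniform_pool(rng, 1000)
        target = [15_000] * 50  # all in bin 1 at 10 kb width
        pairs = matched_background_pairs(target, pool, 40, bin_width_bp=10_000, seed=1)
        assert all(10_000 <= p.distance_bp < 20_000 for p in pairs)

    def test_distance_distribution_fidelity(self, rng):
        pool = _uniform_pool(rng, 3000)
        target = rng.lognormal(np.log(30_000), 0.6, 500).astype(int)
        pairs = matched_background_pairs(target, pool, 500, seed=3)
        ks = stats.ks_2samp(target, [p.distance_bp for p in pairs]).statistic
        assert ks < 0.1

    def test_empty_pool_is_an_error(self):
        with pytest.raises(SskitError):
            matched_background_pairs([1000], [], 10)


def test_score_pairs_excludes_zero_activity_vectors():
    elements = make_elements([0, 2000, 50_000], prefix="z")
    activity = ActivityMatrix(
        [[1, -1], [0, 0], [1, -1]], [e.id for e in elements], ["CT1", "CT2"]
    )
    pairs = [
        PairSample(("z0", "z1"), 2000, "within_region"),
        PairSample(("z0", "z2"), 50_000, "within_region"),
    ]
    scores = score_pairs(pairs, activity)
    assert np.isnan(scores.loc[0, "cooperativity"])  # z1 is all-zero
    assert scores.loc[1, "cooperativity"] == pytest.approx(1.0)


def test_random_background_pairs_deterministic(rng):
    pool = _uniform_pool(rng, 500)
    assert random_background_pairs(pool, 50, seed=9) == random_background_pairs(pool, 50, seed=9)
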