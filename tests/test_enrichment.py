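"""Variant density, fraction-based enrichment, LD expansion and
element-set Jaccard."""

import numpy as np
import pytest
from scipy.stats import binom

from sskit.core import GenomicInterval, SskitError, VariantRecord
from sskit.enrichment import (
    category_fraction,
    classify_partner,
    density_fold,
    density_per_kb,
    elementset_jaccard,
    enrichment_fold,
    flanks,
    ld_expand,
    recurrent_fraction,
    replicated_fraction,
    variants_in_set,
)

from conftest import make_elements


def snv(chrom, pos, cats=(), samples=(), vid=""):
    return VariantRecord(
        GenomicInterval(chrom, pos, pos + 1), "SNV",
        frozenset(cats), frozenset(samples), id=vid or f"{chrom}:{pos}",
    )


class TestDensityPerKb:
    def test_forced_arithmetic(self):
        elements = [GenomicInterval("chr1", 0, 10_000)]
        variants = [snv("chr1", p) for p in (1, 100, 5000, 7000, 9999)]
        assert density_per_kb(variants, elements) == pytest.approx(0.5)

    def test_no_variants(self):
        assert density_per_kb([], [GenomicInterval("chr1", 0, 1000)]) == 0.0

    def test_zero_length_error(self):
        with pytest.raises(SskitError):
            density_per_kb([], [])

    def test_overlapping_elements_counted_once(self, rng):
        """Density over overlapping elements equals a merge-then-scan oracle."""
        starts = rng.integers(0, 50_000, 30)
        elements = [GenomicInterval("chr1", int(s), int(s) + 3000) for s in starts]
        variants = [snv("chr1", int(p)) for p in rng.integers(0, 60_000, 200)]
        got = density_per_kb(variants, elements)
        covered = set()
        for e in elements:
            covered.update(range(e.start, e.end))
        hits = sum(1 for v in variants if v.position.start in covered)
        assert got == pytest.approx(hits / (len(covered) / 1000))

    def test_invariant_to_splitting_an_element(self):
        variants = [snv("chr1", p) for p in (10, 600, 900)]
        whole = density_per_kb(variants, [GenomicInterval("chr1", 0, 1000)])
        split = density_per_kb(
            variants,
            [GenomicInterval("chr1", 0, 400), GenomicInterval("chr1", 400, 1000)],
        )
        assert whole == pytest.approx(split)


class TestCategoryFraction:
    def test_examples(self):
        tagged = [snv("chr1", i, ("b_cell_cancer",)) for i in range(8)]
        untagged = [snv("chr1", 100 + i) for i in range(92)]
        assert category_fraction(tagged + untagged, "b_cell_cancer") == pytest.approx(0.08)
        assert category_fraction(tagged, "b_cell_cancer") == 1.0
        assert category_fraction(untagged, "b_cell_cancer") == 0.0

    def test_empty_flagged(self):
        with pytest.raises(SskitError):
            category_fraction([], "x")


class TestEnrichmentFold:
    def test_fold_arithmetic(self):
        fold, _ = enrichment_fold(0.10, 0.05, 100)
        assert fold == pytest.approx(2.0)

    def test_null_identity(self):
        fold, p = enrichment_fold(0.05, 0.05, 100)
        assert fold == pytest.approx(1.0)
        assert p > 0.5

    def test_p_equals_exact_tail_summation(self):
        """Two-sided binomial p from direct pmf summation (k=8, n=100, p0=0.02)."""
        k, n, p0 = 8, 100, 0.02
        _, p = enrichment_fold(k / n, p0, n)
        pmf = binom.pmf(np.arange(n + 1), n, p0)
        expected = pmf[pmf <= pmf[k] * (1 + 1e-9)].sum()
        assert p == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("ref", [0.0, 1.0])
    def test_degenerate_reference_rejected(self, ref):
        with pytest.raises(ValueError):
            enrichment_fold(0.5, ref, 10)


class TestDensityFold:
    def test_fold_one_bracketed_on_equal_rates(self, rng):
        set_a = [GenomicInterval("chr1", 0, 200_000)]
        set_b = [GenomicInterval("chr1", 300_000, 800_000)]
        variants = [snv("chr1", int(p)) for p in rng.integers(0, 800_000, 700)
                    if int(p) < 200_000 or int(p) >= 300_000]
        fold, lo, hi = density_fold(variants, set_a, set_b)
        assert lo <= 1.0 <= hi
        assert lo < fold < hi


class TestLdExpand:
    pairs = [("s1", "x", 0.9), ("s1", "y", 0.8), ("z", "s2", 0.85), ("a", "b", 0.99)]

    def test_strictly_above_threshold_partners_added(self):
        assert ld_expand({"s1"}, self.pairs) == {"s1", "x"}  # 0.8 exactly excluded

    def test_both_directions_and_superset(self):
        out = ld_expand({"s1", "s2"}, self.pairs)
        assert out == {"s1", "s2", "x", "z"}
        assert out >= {"s1", "s2"}

    def test_no_pairs_identity_and_idempotence(self):
        assert ld_expand({"s1"}, []) == {"s1"}
        once = ld_expand({"s1"}, self.pairs)
        assert ld_expand(once, [p for p in self.pairs if p[2] <= 0.8]) == once


class TestReplicatedAndRecurrent:
    def test_replicated_fraction(self):
        m = {"a": {"s1", "s2"}, "b": {"s1"}, "c": {"s3", "s4", "s5"}, "d": {"s9"}}
        assert replicated_fraction(m) == 0.5
        assert replicated_fraction({"a": {"s1"}}) == 0.0

    def test_recurrent_fraction_matches_brute_force(self, rng):
        m = {
            f"v{i}": set(f"p{j}" for j in rng.integers(0, 50, rng.integers(1, 5)))
            for i in range(200)
        }
        expected = sum(len(s) >= 2 for s in m.values()) / len(m)
        assert recurrent_fraction(m) == pytest.approx(expected)

    def test_empty_maps_flagged(self):
        with pytest.raises(SskitError):
            replicated_fraction({})
        with pytest.raises(SskitError):
            recurrent_fraction({})


class TestElementsetJaccard:
    def test_identical_and_disjoint(self):
        a = [GenomicInterval("chr1", i * 10_000, i * 10_000 + 1000) for i in range(5)]
        b = [GenomicInterval("chr1", 500_000 + i * 10_000, 500_000 + i * 10_000 + 1000) for i in range(5)]
        assert elementset_jaccard(a, a) == 1.0
        assert elementset_jaccard(a, b) == 0.0

    def test_constructed_partial_match(self):
        """10 vs 10 with exactly 4 overlapping pairs -> 4 / 16."""
        a = [GenomicInterval("chr1", i * 100_000, i * 100_000 + 2000) for i in range(10)]
        b = [
            GenomicInterval("chr1", i * 100_000 + 1000, i * 100_000 + 3000) for i in range(4)
        ] + [GenomicInterval("chr2", i * 50_000, i * 50_000 + 1000) for i in range(6)]
        assert elementset_jaccard(a, b, min_bp=1) == pytest.approx(4 / 16)

    def test_both_empty_undefined(self):
        with pytest.raises(SskitError):
            elementset_jaccard([], [])


class TestPartnerClassification:
    groups = {
        "SS": [GenomicInterval("chr1", 1_000_000, 1_002_000)],
        "SE": [GenomicInterval("chr1", 1_000_500, 1_001_500)],
        "TS": [GenomicInterval("chr2", 0, 2000)],
    }

    def test_super_silencer_precedence(self):
        bp = GenomicInterval("chr1", 1_001_000, 1_001_001)
        assert classify_partner(bp, self.groups, flank_bp=0) == "SS"

    def test_flank_assignment_and_none(self):
        near = GenomicInterval("chr2", 30_000, 30_001)
        assert classify_partner(near, self.groups, flank_bp=50_000) == "TS"
        assert classify_partner(near, self.groups, flank_bp=1000) == "none"


def test_flanks_exclude_element_footprint():
    elements = make_elements([100_000, 120_000], lengths=2000)
    out = flanks(elements, flank_bp=10_000)
    footprint = {(iv.start, iv.end) for iv in out}
    assert (90_000, 100_000) in footprint
    # no flank base overlaps an element
    for iv in out:
        for e in elements:
            assert min(iv.end, e.interval.end) - max(iv.start, e.interval.start) <= 0


def test_variants_in_set_uses_position_membership():
    elements = [GenomicInterval("chr1", 100, 200)]
    inside = snv("chr1", 150)
    edge = snv("chr1", 200)  # half-open: excluded
    assert variants_in_set([inside, edge], elements) == [inside]
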