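"""CGI classification, TAD geometry, gene linkage, tau and methylation."""

import numpy as np
import pandas as pd
import pytest

from sskit.annotate import (
    BOUNDARY,
    CENTER,
    CGI,
    NON_CGI,
    SHORE,
    ContactGeneLinker,
    GeneIndex,
    cgi_class,
    contact_genes,
    counterpart_shore,
    gene_tau_table,
    mean_methylation,
    nearest_gene,
    tad_section,
    tau,
)
from sskit.core import (
    ContactRecord,
    GeneRecord,
    GenomicInterval,
    IntervalIndex,
    SskitError,
    TADSet,
)


class TestCgiClass:
    element = GenomicInterval("chr1", 1000, 3000)

    @pytest.mark.parametrize("cgi_end,expected", [(1201, CGI), (1200, NON_CGI)])
    def test_strict_200bp_threshold(self, cgi_end, expected):
        cgis = IntervalIndex([GenomicInterval("chr1", 0, cgi_end)])
        assert cgi_class(self.element, cgis) == expected

    def test_no_overlap(self):
        assert cgi_class(self.element, IntervalIndex([])) == NON_CGI

    def test_best_single_overlap_not_total(self):
        # two CGIs of 150 bp each: total 300 but no single one > 200
        cgis = IntervalIndex([
            GenomicInterval("chr1", 1000, 1150), GenomicInterval("chr1", 2000, 2150)
        ])
        assert cgi_class(self.element, cgis) == NON_CGI


class TestTadSection:
    tads = TADSet([GenomicInterval("chr1", 0, 1_000_000),
                   GenomicInterval("chr1", 1_000_000, 2_000_000)])

    def element_at(self, mid):
        return GenomicInterval("chr1", mid - 500, mid + 500)

    @pytest.mark.parametrize(
        "mid,label",
        [(1_010_000, BOUNDARY), (1_030_000, SHORE), (1_050_000, SHORE), (1_100_000, CENTER)],
    )
    def test_band_thresholds(self, mid, label):
        sec = tad_section(self.element_at(mid), self.tads)
        assert sec.label == label

    def test_unassigned_without_tads(self):
        assert tad_section(self.element_at(5000), TADSet([])) is None

    def test_labels_partition_elements(self, rng):
        mids = rng.integers(10_000, 1_990_000, 200)
        labels = [tad_section(self.element_at(int(m)), self.tads).label for m in mids]
        assert all(l in (BOUNDARY, SHORE, CENTER) for l in labels)
        counts = {l: labels.count(l) for l in set(labels)}
        assert sum(counts.values()) == 200


class TestCounterpartShore:
    def test_right_query_gives_left_band(self):
        band = counterpart_shore("chr1", 1_000_000, "right")
        assert (band.start, band.end) == (950_000, 980_000)

    def test_left_query_gives_right_band(self):
        band = counterpart_shore("chr1", 1_000_000, "left")
        assert (band.start, band.end) == (1_020_000, 1_050_000)

    def test_truncated_at_chromosome_start(self):
        band = counterpart_shore("chr1", 30_000, "right")
        assert (band.start, band.end) == (0, 10_000)

    def test_side_involution(self):
        """The counterpart of a shore's counterpart is the shore itself."""
        b = 1_000_000
        left_band = counterpart_shore("chr1", b, "right")   # lies left of b
        right_band = counterpart_shore("chr1", b, "left")   # lies right of b
        # querying from the side each band lies on returns the other band
        assert counterpart_shore("chr1", b, "left") == right_band
        assert counterpart_shore("chr1", b, "right") == left_band
        assert left_band.end <= b <= right_band.start


class TestNearestGene:
    genes = [
        GeneRecord("A", "chr1", 10_000),
        GeneRecord("B", "chr1", 60_000),
        GeneRecord("C", "chr2", 5_000),
    ]

    def test_closest_tss_wins(self):
        e = GenomicInterval("chr1", 14_000, 16_000)  # midpoint 15 kb
        assert nearest_gene(e, self.genes) == "A"

    def test_tie_breaks_lexicographically(self):
        e = GenomicInterval("chr1", 34_000, 36_000)  # equidistant from A and B
        assert nearest_gene(e, self.genes) == "A"

    def test_no_gene_on_chromosome(self):
        assert nearest_gene(GenomicInterval("chr9", 0, 100), self.genes) is None

    def test_index_matches_exhaustive_scan(self, rng):
        genes = [
            GeneRecord(f"g{i:03d}", "chr1", int(t))
            for i, t in enumerate(rng.integers(0, 1_000_000, 80))
        ]
        index = GeneIndex(genes)
        for _ in range(100):
            s = int(rng.integers(0, 1_000_000))
            e = GenomicInterval("chr1", s, s + 1000)
            assert index.nearest(e) == nearest_gene(e, genes)


class TestContactGenes:
    def test_single_contact_links_promoter(self):
        gene = GeneRecord("g1", "chr1", 501_000)
        contact = ContactRecord(
            GenomicInterval("chr1", 100_000, 110_000), GenomicInterval("chr1", 500_000, 510_000)
        )
        element = GenomicInterval("chr1", 105_000, 106_500)
        assert contact_genes(element, [contact], [gene]) == {"g1"}
        assert contact_genes(GenomicInterval("chr1", 0, 1000), [contact], [gene]) == set()

    def test_linker_matches_brute_force(self, rng):
        genes = [
            GeneRecord(f"g{i}", "chr1", int(t)) for i, t in enumerate(rng.integers(0, 2_000_000, 40))
        ]
        contacts = []
        for _ in range(60):
            a = int(rng.integers(0, 1_990_000)) // 10_000 * 10_000
            b = int(rng.integers(0, 1_990_000)) // 10_000 * 10_000
            if a == b:
                continue
            contacts.append(ContactRecord(
                GenomicInterval("chr1", a, a + 10_000), GenomicInterval("chr1", b, b + 10_000)
            ))
        linker = ContactGeneLinker(contacts, genes)
        for _ in range(50):
            s = int(rng.integers(0, 1_990_000))
            e = GenomicInterval("chr1", s, s + 2000)
            assert linker.genes_for(e) == contact_genes(e, contacts, genes)


class TestTau:
    @pytest.mark.parametrize("expr,expected", [((1, 1, 1), 0.0), ((1, 0, 0), 1.0), ((2, 1, 1), 0.5)])
    def test_forced_arithmetic(self, expr, expected):
        assert tau(expr) == pytest.approx(expected)

    def test_scale_invariance_and_bounds(self, rng):
        for _ in range(50):
            x = rng.random(int(rng.integers(2, 12))) * 10
            if x.max() == 0:
                continue
            t = tau(x)
            assert 0.0 <= t <= 1.0
            assert tau(3.7 * x) == pytest.approx(t)

    def test_all_zero_flagged(self):
        with pytest.raises(SskitError):
            tau([0.0, 0.0])


class TestMeanMethylation:
    def test_mean_of_inside_sites(self):
        meth = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [100, 200, 900], "beta": [0.2, 0.8, 0.9]})
        assert mean_methylation(GenomicInterval("chr1", 50, 250), meth) == pytest.approx(0.5)

    def test_no_sites_is_missing(self):
        meth = pd.DataFrame({"chrom": ["chr1"], "pos": [10], "beta": [0.5]})
        assert np.isnan(mean_methylation(GenomicInterval("chr1", 100, 200), meth))

    def test_matches_direct_average(self, rng):
        meth = pd.DataFrame({
            "chrom": "chr1", "pos": rng.integers(0, 100_000, 500),
            "beta": rng.random(500),
        })
        for _ in range(50):
            s = int(rng.integers(0, 95_000))
            e = GenomicInterval("chr1", s, s + int(rng.integers(500, 5000)))
            inside = meth[(meth.pos >= e.start) & (meth.pos < e.end)]["beta"]
            got = mean_methylation(e, meth)
            if len(inside) == 0:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(inside.mean())


def test_gene_tau_table_skips_degenerate_profiles():
    genes = [
        GeneRecord("a", "chr1", 0, "+", {"x": 1.0, "y": 0.0}),
        GeneRecord("b", "chr1", 0, "+", {"x": 0.0, "y": 0.0}),
        GeneRecord("c", "chr1", 0, "+", {"x": 2.0}),
    ]
    table = gene_tau_table(genes)
    assert list(table.gene_id) == ["a"]
    assert table.tau.iloc[0] == pytest.approx(1.0)
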