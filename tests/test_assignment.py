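"""Peak-gene assignment strategies, annotation categories, locus complexity."""

import numpy as np
import pytest

from peakconcord import (
    GeneModel,
    GenomicInterval,
    TadDomain,
    annotate_peaks,
    assign_peaks,
    locus_complexity,
)


def gene(gid, tss, chrom="chr1", strand="+", length=5_000):
    return GeneModel(gid, chrom, tss, strand, tss, tss + length)


def point_peak(pos, chrom="chr1", name=None):
    """Width-2 peak whose midpoint (reference point) is exactly ``pos``."""
    return GenomicInterval(chrom, pos - 1, pos + 1, name)


def brute_force_nearest(peaks, genes):
    links = {}
    for p in peaks:
        cands = [g for g in genes if g.chrom == p.chrom]
        if not cands:
            continue
        best = min(cands, key=lambda g: (abs(p.midpoint - g.tss), g.tss, g.gene_id))
        links[p.label] = best.gene_id
    return links


class TestNearest:
    def test_single_gene_takes_everything(self):
        genes = [gene("gA", 1_000)]
        peaks = [point_peak(10), point_peak(90_000)]
        asg = assign_peaks(peaks, genes, "nearest")
        assert set(asg.links["gene_id"]) == {"gA"}

    def test_distance_is_signed_from_tss(self):
        genes = [gene("gA", 1_000), gene("gB", 10_000)]
        asg = assign_peaks([point_peak(3_000)], genes, "nearest")
        row = asg.links.iloc[0]
        assert (row["gene_id"], row["distance"]) == ("gA", 2_000)

    def test_equidistant_tie_goes_to_smaller_tss(self):
        genes = [gene("gB", 10_000), gene("gA", 1_000)]
        asg = assign_peaks([point_peak(5_500)], genes, "nearest")
        assert asg.links.iloc[0]["gene_id"] == "gA"

    def test_same_tss_tie_goes_to_lexicographic_id(self):
        genes = [gene("gZ", 1_000), gene("gA", 1_000)]
        asg = assign_peaks([point_peak(900)], genes, "nearest")
        assert asg.links.iloc[0]["gene_id"] == "gA"

    def test_agrees_with_exhaustive_search(self, rng):
        genes = [
            gene(f"g{i:03d}", int(t), chrom=f"chr{1 + i % 2}")
            for i, t in enumerate(np.sort(rng.integers(10_000, 5_000_000, 50)))
        ]
        peaks = [
            point_peak(int(p), chrom=f"chr{1 + int(c)}", name=f"p{k}")
            for k, (p, c) in enumerate(
                zip(rng.integers(0, 5_100_000, 500), rng.integers(0, 2, 500))
            )
        ]
        asg = assign_peaks(peaks, genes, "nearest")
        got = dict(zip(asg.links["peak_id"], asg.links["gene_id"]))
        assert got == brute_force_nearest(peaks, genes)


class TestWindowPromoterDistal:
    def test_window_boundary_is_closed(self):
        genes = [gene("gA", 100_000)]
        peaks = [point_peak(149_000, name="in"),
                 point_peak(150_000, name="edge"),
                 point_peak(151_000, name="out")]
        asg = assign_peaks(peaks, genes, "window")
        assert set(asg.links["peak_id"]) == {"in", "edge"}

    def test_distal_excludes_inner_20kb_strictly(self):
        genes = [gene("gA", 100_000)]
        peaks = [point_peak(100_000 + d, name=str(d))
                 for d in (5_000, 20_000, 20_001, 50_000, 50_001)]
        asg = assign_peaks(peaks, genes, "distal")
        assert set(asg.links["peak_id"]) == {"20001", "50000"}

    def test_promoter_subset_window_and_disjoint_distal(self, rng):
        genes = [gene(f"g{i}", int(t))
                 for i, t in enumerate(np.sort(rng.integers(0, 2_000_000, 25)))]
        peaks = [point_peak(int(p), name=f"p{k}")
                 for k, p in enumerate(rng.integers(0, 2_000_000, 300))]
        window = set(map(tuple, assign_peaks(peaks, genes, "window")
                         .links[["peak_id", "gene_id"]].values))
        promoter = set(map(tuple, assign_peaks(peaks, genes, "promoter")
                           .links[["peak_id", "gene_id"]].values))
        distal = set(map(tuple, assign_peaks(peaks, genes, "distal")
                         .links[["peak_id", "gene_id"]].values))
        assert promoter <= window
        assert distal <= window
        assert not (promoter & distal)

    def test_mismatched_chromosomes_warn(self):
        with pytest.warns(UserWarning, match="chromosome"):
            assign_peaks([point_peak(10, chrom="1")],
                         [gene("gA", 10, chrom="chr1")], "window")


class TestTad:
    def test_requires_tads(self):
        with pytest.raises(ValueError, match="TAD"):
            assign_peaks([point_peak(10)], [gene("gA", 10)], "tad")

    def test_links_only_within_shared_domain(self):
        tads = [TadDomain("chr1", 0, 100_000, "t1"),
                TadDomain("chr1", 100_000, 200_000, "t2")]
        genes = [gene("gA", 50_000), gene("gB", 150_000)]
        peaks = [point_peak(20_000, name="pa"),
                 point_peak(120_000, name="pb"),
                 point_peak(250_000, name="outside")]
        asg = assign_peaks(peaks, genes, "tad", tads=tads)
        got = set(map(tuple, asg.links[["peak_id", "gene_id"]].values))
        assert got == {("pa", "gA"), ("pb", "gB")}


class TestAnnotation:
    def test_priority_and_categories(self):
        genes = [gene("gA", 10_000, length=50_000)]
        peaks = [point_peak(10_000, name="at_tss"),
                 point_peak(20_000, name="mid_body"),
                 point_peak(61_000, name="past_end"),
                 point_peak(400_000, name="far")]
        anns = {a.peak_id: a for a in annotate_peaks(peaks, genes)}
        assert anns["at_tss"].category == "promoter"
        assert anns["mid_body"].category == "gene_body"
        assert anns["past_end"].category == "downstream"
        assert anns["far"].category == "intergenic"
        assert anns["far"].anchor_gene is None

    def test_downstream_is_strand_aware(self):
        g = GeneModel("gM", "chr1", 60_000, "-", 10_000, 60_000)
        anns = {a.peak_id: a
                for a in annotate_peaks([point_peak(8_000, name="p")], [g])}
        assert anns["p"].category == "downstream"

    def test_empty_chromosome_is_intergenic(self):
        (a,) = annotate_peaks([point_peak(100, chrom="chrX", name="p")],
                              [gene("gA", 10)])
        assert (a.category, a.anchor_gene) == ("intergenic", None)

    def test_every_peak_gets_exactly_one_category(self, rng):
        genes = [gene(f"g{i}", int(t))
                 for i, t in enumerate(np.sort(rng.integers(0, 500_000, 12)))]
        peaks = [point_peak(int(p), name=f"p{k}")
                 for k, p in enumerate(rng.integers(0, 600_000, 200))]
        anns = annotate_peaks(peaks, genes)
        assert len(anns) == len(peaks)
        assert {a.category for a in anns} <= {
            "promoter", "gene_body", "downstream", "intergenic"
        }


class TestLocusComplexity:
    def _assignment(self, counts):
        peaks, genes = [], []
        k = 0
        for gi, n in enumerate(counts):
            tss = 100_000 + gi * 400_000
            genes.append(gene(f"g{gi + 1}", tss))
            for _ in range(n):
                peaks.append(point_peak(tss + 500 + 10 * k, name=f"p{k}"))
                k += 1
        return assign_peaks(peaks, genes, "nearest"), genes

    def test_fixed_cutoff_seven(self):
        asg, genes = self._assignment([8, 7])
        comp = {c.gene_id: c for c in locus_complexity(asg, "fixed:7", genes)}
        assert comp["g1"].complexity == "high"
        assert comp["g2"].complexity == "low"

    def test_identical_counts_all_low_under_tertile(self):
        asg, genes = self._assignment([4, 4, 4])
        comp = locus_complexity(asg, "tertile", genes)
        assert all(c.complexity == "low" for c in comp)

    def test_tertile_on_one_to_nine(self):
        asg, genes = self._assignment(list(range(1, 10)))
        comp = {c.gene_id: c for c in locus_complexity(asg, "tertile", genes)}
        assert comp["g1"].cutoff == 7
        high = {g for g, c in comp.items() if c.complexity == "high"}
        assert high == {"g8", "g9"}

    def test_requires_nearest_method(self):
        asg, genes = self._assignment([2])
        asg.method = "window"
        with pytest.raises(ValueError):
            locus_complexity(asg)
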