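"""CNV consensus, mask fractions and filter boundaries."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiovar.cnv import (
    CnvCall,
    GenomicMask,
    cnv_gene_overlap,
    consensus_filter,
    mask_overlap_fraction,
    reciprocal_overlap,
)
from cardiovar.regions import RegulatoryRegion


def call(start, end, sample="s1", cn_type="deletion", caller="A", chrom="chr1"):
    return CnvCall(sample_id=sample, chrom=chrom, start=start, end=end,
                   cn_type=cn_type, caller=caller)


class TestReciprocalOverlap:
    def test_identical(self):
        assert reciprocal_overlap(("chr1", 0, 100), ("chr1", 0, 100)) == (1.0, 1.0)

    def test_half_overlap_boundary(self):
        f = reciprocal_overlap(("chr1", 0, 100), ("chr1", 50, 150))
        assert f == (0.5, 0.5)

    def test_asymmetric_matches_brute_force(self):
        f1, f2 = reciprocal_overlap(("chr1", 0, 100), ("chr1", 90, 300))
        inter = len(set(range(0, 100)) & set(range(90, 300)))
        assert f1 == inter / 100 and f2 == inter / 210

    def test_different_chromosomes(self):
        assert reciprocal_overlap(("chr1", 0, 100), ("chr2", 0, 100)) == (0.0, 0.0)

    @given(
        st.tuples(st.integers(0, 500), st.integers(1, 200)),
        st.tuples(st.integers(0, 500), st.integers(1, 200)),
    )
    @settings(deadline=None, max_examples=60)
    def test_swap_symmetry(self, a, b):
        i1 = ("chr1", a[0], a[0] + a[1])
        i2 = ("chr1", b[0], b[0] + b[1])
        assert reciprocal_overlap(i1, i2) == tuple(reversed(reciprocal_overlap(i2, i1)))


class TestMaskOverlap:
    def test_fully_inside(self):
        mask = GenomicMask("segdup", {"chr1": [(0, 2000)]})
        assert mask_overlap_fraction(("chr1", 100, 200), mask) == 1.0

    def test_exact_seventy_percent(self):
        mask = GenomicMask("segdup", {"chr1": [(0, 700)]})
        assert mask_overlap_fraction(("chr1", 0, 1000), mask) == 0.7

    def test_disjoint(self):
        mask = GenomicMask("segdup", {"chr1": [(5000, 6000)]})
        assert mask_overlap_fraction(("chr1", 0, 1000), mask) == 0.0

    @given(
        st.integers(0, 200),
        st.integers(1, 100),
        st.lists(st.tuples(st.integers(0, 300), st.integers(1, 60)), max_size=8),
    )
    @settings(deadline=None, max_examples=60)
    def test_matches_base_counting(self, start, width, mask_pairs):
        interval = ("chr1", start, start + width)
        mask = GenomicMask("segdup", {"chr1": [(s, s + w) for s, w in mask_pairs]})
        masked = {b for s, w in mask_pairs for b in range(s, s + w)}
        brute = len(masked & set(range(start, start + width))) / width
        assert mask_overlap_fraction(interval, mask) == pytest.approx(brute)


def empty_masks():
    return {name: GenomicMask(name, {}) for name in ("telomere", "centromere", "segdup", "cn_prone")}


class TestConsensusFilter:
    def test_clean_consensus_retained(self):
        out = consensus_filter(
            [call(0, 5000)], [call(500, 5500, caller="B")], empty_masks()
        )
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (500, 5000)  # intersection

    def test_sub_kb_consensus_removed(self):
        # identical 900 bp calls: strict "> 1 kb" fails
        out = consensus_filter([call(0, 900)], [call(0, 900, caller="B")], empty_masks())
        assert out == []
        kept = consensus_filter([call(0, 1001)], [call(0, 1001, caller="B")], empty_masks())
        assert len(kept) == 1

    def test_reciprocal_boundary_inclusive(self):
        # [0,2000) vs [1000,3000): both fractions exactly 0.5 -> consensus,
        # but the 1000 bp intersection then fails the length filter
        out = consensus_filter([call(0, 2000)], [call(1000, 3000, caller="B")], empty_masks())
        assert out == []
        # wider pair at exactly 50%: [0,4000) vs [2000,6000) -> 2000 bp kept
        out = consensus_filter([call(0, 4000)], [call(2000, 6000, caller="B")], empty_masks())
        assert len(out) == 1

    def test_mask_boundary_strict(self):
        masks = empty_masks()
        masks["segdup"] = GenomicMask("segdup", {"chr1": [(0, 1400)]})
        # consensus [0,2000): mask covers exactly 70% -> fails strict bound
        out = consensus_filter([call(0, 2000)], [call(0, 2000, caller="B")], masks)
        assert out == []
        masks["segdup"] = GenomicMask("segdup", {"chr1": [(0, 1399)]})
        out = consensus_filter([call(0, 2000)], [call(0, 2000, caller="B")], masks)
        assert len(out) == 1

    def test_panel_frequency_strict(self):
        region = (("chr1", 0, 2000), "deletion", 0.012)
        out = consensus_filter(
            [call(0, 2000)], [call(0, 2000, caller="B")], empty_masks(), [region]
        )
        assert out == []
        rare = (("chr1", 0, 2000), "deletion", 0.009)
        out = consensus_filter(
            [call(0, 2000)], [call(0, 2000, caller="B")], empty_masks(), [rare]
        )
        assert len(out) == 1

    def test_type_mismatch_no_consensus(self):
        out = consensus_filter(
            [call(0, 5000)], [call(0, 5000, cn_type="duplication", caller="B")], empty_masks()
        )
        assert out == []

    def test_single_caller_no_rescue(self):
        assert consensus_filter([call(0, 5000)], [], empty_masks()) == []

    def test_shrinking_mask_never_removes_calls(self):
        masks_big = empty_masks()
        masks_big["segdup"] = GenomicMask("segdup", {"chr1": [(0, 1300)]})
        masks_small = empty_masks()
        masks_small["segdup"] = GenomicMask("segdup", {"chr1": [(0, 600)]})
        a = [call(0, 2000), call(10_000, 16_000)]
        b = [call(0, 2000, caller="B"), call(10_500, 16_500, caller="B")]
        kept_big = {(c.start, c.end) for c in consensus_filter(a, b, masks_big)}
        kept_small = {(c.start, c.end) for c in consensus_filter(a, b, masks_small)}
        assert kept_big <= kept_small

    @given(
        st.lists(
            st.tuples(st.integers(0, 30), st.integers(1, 20), st.integers(0, 30), st.integers(1, 20)),
            max_size=6,
        ),
        st.lists(st.tuples(st.integers(0, 600), st.integers(1, 300)), max_size=4),
    )
    @settings(deadline=None, max_examples=40)
    def test_retained_calls_pass_all_bounds(self, pairs, mask_pairs):
        scale = 200  # intervals in units of 200 bp so lengths straddle 1 kb
        a = [call(s * scale, s * scale + w * scale) for s, w, _, _ in pairs]
        b = [call(s2 * scale, s2 * scale + w2 * scale, caller="B") for _, _, s2, w2 in pairs]
        masks = empty_masks()
        masks["segdup"] = GenomicMask(
            "segdup", {"chr1": [(s * 10, s * 10 + w * 10) for s, w in mask_pairs]}
        )
        for c in consensus_filter(a, b, masks):
            assert c.length > 1000
            assert mask_overlap_fraction((c.chrom, c.start, c.end), masks["segdup"]) < 0.7


def test_cnv_gene_overlap_labels():
    exons = [("JPH2", ("chr1", 1000, 2000)), ("NEXN", ("chr1", 5000, 6000))]
    promoter = RegulatoryRegion("chr1", 500, 1000, "promoter", ["JPH2"])
    enhancer = RegulatoryRegion("chr1", 8000, 9000, "enhancer", ["NEXN"])
    spanning = call(600, 1500)
    labels = cnv_gene_overlap(spanning, exons, [promoter, enhancer])
    assert labels["coding"] == ["JPH2"]
    assert labels["regulatory"] == [("promoter", ["JPH2"])]
    enhancer_only = call(8100, 8200)
    labels = cnv_gene_overlap(enhancer_only, exons, [promoter, enhancer])
    assert labels["coding"] == [] and labels["regulatory"] == [("enhancer", ["NEXN"])]
    nothing = call(20_000, 21_000)
    labels = cnv_gene_overlap(nothing, exons, [promoter, enhancer])
    assert labels["coding"] == [] and labels["regulatory"] == []
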