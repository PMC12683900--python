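"""cRE calling and S-LDSC annotation partition."""

import numpy as np
import pytest

from chromv2g.core import GeneAnnotation, GenomicInterval, Loop, Ocr, make_promoters
from chromv2g.cre import (
    AnnotCategory,
    define_cres,
    export_ldsc_annot,
    partition_annotations,
)


class TestDefineCres:
    def test_looped_ocr_to_open_promoter_is_cre(self, tiny_genome):
        _genes, promoters, ocrs, loops = tiny_genome
        cres = define_cres(ocrs, loops, promoters)
        by_id = {c.cre_id: c for c in cres}
        assert "peakA" in by_id
        assert by_id["peakA"].contacted_genes == frozenset({"G1"})
        assert by_id["peakA"].supporting_loops == frozenset({"loop_g1"})

    def test_closed_promoter_counts_without_open_requirement(self, tiny_genome):
        _genes, promoters, ocrs, loops = tiny_genome
        cres = define_cres(ocrs, loops, promoters, require_open_promoter=False)
        by_id = {c.cre_id: c for c in cres}
        assert by_id["peakA"].contacted_genes == frozenset({"G1", "G2"})
        assert by_id["peakA"].supporting_loops == frozenset({"loop_g1", "loop_g2"})

    def test_unlooped_ocr_is_not_cre(self, tiny_genome):
        _genes, promoters, ocrs, loops = tiny_genome
        cres = define_cres(ocrs, loops, promoters)
        assert "peakB" not in {c.cre_id for c in cres}

    def test_promoter_ocr_not_cre_via_self_contact(self, tiny_genome):
        # peakP1 sits under loop_g1's promoter-side anchor, which also overlaps
        # the G1 promoter; a single anchor covering both never creates a cRE
        _genes, promoters, ocrs, loops = tiny_genome
        cres = define_cres(ocrs, loops, promoters)
        assert "peakP1" not in {c.cre_id for c in cres}

    def test_mixed_cell_types_rejected(self, tiny_genome):
        _genes, promoters, ocrs, loops = tiny_genome
        bad = ocrs + [Ocr(GenomicInterval("chr1", 1, 2), "bcell", "x")]
        with pytest.raises(ValueError, match="single cell type"):
            define_cres(bad, loops, promoters)

    def test_removing_supporting_loops_removes_cre(self, sim_config, sim_truth):
        """Loop-dependence: a cRE disappears when its loops are withdrawn."""
        ct = sim_config.cell_types[0]
        promoters = make_promoters(sim_truth.genes, chrom_sizes=sim_config.chrom_sizes)
        ocrs = sim_truth.ocrs_by_cell[ct]
        loops = sim_truth.loops_by_cell[ct]
        cres = define_cres(ocrs, loops, promoters)
        assert cres, "fixture must plant at least one cRE"
        victim = cres[0]
        pruned = [l for l in loops if l.loop_id not in victim.supporting_loops]
        cres_after = define_cres(ocrs, pruned, promoters)
        assert victim.cre_id not in {c.cre_id for c in cres_after}


def _random_partition_fixture(rng):
    genes = [
        GeneAnnotation(f"G{i}", f"G{i}", "chr1", int(p), "+")
        for i, p in enumerate(sorted(rng.choice(np.arange(5_000, 500_000, 5_000), 5, replace=False)))
    ]
    promoters = make_promoters(genes, chrom_sizes={"chr1": 1_000_000})
    starts = rng.choice(np.arange(0, 990_000, 700), size=20, replace=False)
    ocrs = [
        Ocr(GenomicInterval("chr1", int(s), int(s) + int(rng.integers(100, 600))), "ct", f"pk{i}")
        for i, s in enumerate(starts)
    ]
    loops = []
    for j in range(6):
        tgt = promoters[int(rng.integers(0, len(promoters)))]
        ocr = ocrs[int(rng.integers(0, len(ocrs)))]
        loops.append(
            Loop(
                GenomicInterval("chr1", max(0, tgt.interval.start - 200), tgt.interval.end + 200),
                GenomicInterval("chr1", max(0, ocr.interval.start - 100), ocr.interval.end + 100),
                "ct", f"loop{j}", source="pcc",
            )
        )
    return promoters, ocrs, loops


class TestPartition:
    def test_category_semantics_on_tiny_fixture(self, tiny_genome):
        _genes, promoters, ocrs, loops = tiny_genome
        cres = define_cres(ocrs, loops, promoters)
        part = partition_annotations(ocrs, cres, promoters)
        cats = part.categories
        assert len(cats[AnnotCategory.ALL_OCR]) == 3
        assert len(cats[AnnotCategory.PROMOTER_OCR]) == 1  # peakP1
        assert len(cats[AnnotCategory.CRE]) == 1  # peakA
        assert len(cats[AnnotCategory.NON_CRE_NON_PROM]) == 1  # peakB

    def test_flank_merges_nearby_cres(self):
        genes = [GeneAnnotation("G1", "G1", "chr1", 50_000, "+")]
        promoters = make_promoters(genes, chrom_sizes={"chr1": 1_000_000})
        # two OCRs 600 bp apart, both looped to the open promoter
        ocrs = [
            Ocr(GenomicInterval("chr1", 10_000, 10_400), "ct", "a"),
            Ocr(GenomicInterval("chr1", 11_000, 11_400), "ct", "b"),
            Ocr(GenomicInterval("chr1", 48_600, 49_000), "ct", "prom"),
        ]
        loops = [
            Loop(GenomicInterval("chr1", 48_000, 50_000), GenomicInterval("chr1", 9_900, 11_500),
                 "ct", "L1", source="pcc"),
        ]
        cres = define_cres(ocrs, loops, promoters)
        assert {c.cre_id for c in cres} == {"a", "b"}
        part = partition_annotations(ocrs, cres, promoters, flank=500)
        flanked = part.categories[AnnotCategory.CRE_FLANK500]
        assert len(flanked) == 1
        assert (flanked[0].start, flanked[0].end) == (9_500, 11_900)

    def test_negative_flank_rejected(self, tiny_genome):
        _genes, promoters, ocrs, loops = tiny_genome
        cres = define_cres(ocrs, loops, promoters)
        with pytest.raises(ValueError):
            partition_annotations(ocrs, cres, promoters, flank=-1)

    @pytest.mark.parametrize("seed", range(20))
    def test_partition_set_algebra_on_random_fixtures(self, seed):
        """PROMOTER u CRE u NEGATIVE covers ALL; NEGATIVE disjoint from both."""
        rng = np.random.default_rng(seed)
        promoters, ocrs, loops = _random_partition_fixture(rng)
        cres = define_cres(ocrs, loops, promoters, require_open_promoter=False)
        part = partition_annotations(ocrs, cres, promoters)
        cats = part.categories
        key = lambda iv: (iv.chrom, iv.start, iv.end)
        all_set = {key(iv) for iv in cats[AnnotCategory.ALL_OCR]}
        prom = {key(iv) for iv in cats[AnnotCategory.PROMOTER_OCR]}
        cre = {key(iv) for iv in cats[AnnotCategory.CRE]}
        neg = {key(iv) for iv in cats[AnnotCategory.NON_CRE_NON_PROM]}
        assert prom | cre | neg == all_set
        assert not neg & (prom | cre)
        # CRE_FLANK500 covers every cRE interval
        for iv in cats[AnnotCategory.CRE]:
            assert any(
                f.start <= iv.start and iv.end <= f.end
                for f in cats[AnnotCategory.CRE_FLANK500]
            )


class TestLdscExport:
    def _template(self):
        return [("chr1", bp, f"rs{bp}", 0.0) for bp in (50, 150, 151, 200, 201, 999)]

    def _partition(self, tiny_genome):
        _genes, promoters, ocrs, loops = tiny_genome
        cres = define_cres(ocrs, loops, promoters)
        return partition_annotations(ocrs, cres, promoters)

    def test_membership_half_open(self, tiny_genome):
        part = self._partition(tiny_genome)
        part.categories[AnnotCategory.CRE] = [GenomicInterval("chr1", 100, 200)]
        recs = export_ldsc_annot(part, self._template(), AnnotCategory.CRE)
        # bp 150/151/200 are 0-based points 149/150/199 -> inside; 201 -> 200 outside
        assert [r.annot for r in recs] == [0, 1, 1, 1, 0, 0]
        assert len(recs) == 6

    def test_row_count_matches_template_even_when_empty(self, tiny_genome):
        part = self._partition(tiny_genome)
        part.categories[AnnotCategory.CRE] = []
        recs = export_ldsc_annot(part, self._template(), AnnotCategory.CRE)
        assert len(recs) == 6 and all(r.annot == 0 for r in recs)

    def test_unsorted_template_rejected(self, tiny_genome):
        part = self._partition(tiny_genome)
        template = [("chr1", 200, "a", 0.0), ("chr1", 100, "b", 0.0)]
        with pytest.raises(ValueError, match="sorted"):
            export_ldsc_annot(part, template, AnnotCategory.CRE)
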