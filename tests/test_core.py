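"""Interval model, promoter windows, and format round-trips."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromv2g.core import (
    GeneAnnotation,
    GenomicInterval,
    make_promoters,
    merge_intervals,
    overlaps,
    parse_region,
)
from chromv2g.io import (
    FormatError,
    read_bed,
    read_loops,
    read_sumstats,
    write_bed,
    write_loops_ibed,
)


class TestGenomicInterval:
    def test_rejects_inverted_and_empty(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("chr1", 100, 200), ("chr1", 199, 300), True),
            (("chr1", 100, 200), ("chr1", 200, 300), False),  # half-open abutment
            (("chr1", 100, 200), ("chr2", 100, 200), False),
            (("chr1", 100, 200), ("chr1", 100, 200), True),
        ],
    )
    def test_overlaps(self, a, b, expected):
        assert overlaps(GenomicInterval(*a), GenomicInterval(*b)) is expected

    @given(
        st.integers(0, 10_000), st.integers(1, 500),
        st.integers(0, 10_000), st.integers(1, 500),
    )
    @settings(max_examples=200, derandomize=True)
    def test_overlap_symmetric_and_abutment_false(self, s1, l1, s2, l2):
        a = GenomicInterval("chr1", s1, s1 + l1)
        b = GenomicInterval("chr1", s2, s2 + l2)
        assert overlaps(a, b) == overlaps(b, a)
        assert overlaps(a, b) == (a.start < b.end and b.start < a.end)


class TestMakePromoters:
    def test_plus_strand_window(self):
        g = GeneAnnotation("G", "G", "chr1", 10_000, "+")
        (w,) = make_promoters([g])
        assert (w.interval.start, w.interval.end) == (8_499, 10_499)

    def test_minus_strand_window_mirrored(self):
        g = GeneAnnotation("G", "G", "chr1", 10_000, "-")
        (w,) = make_promoters([g])
        assert (w.interval.start, w.interval.end) == (9_500, 11_500)

    def test_clamped_at_chromosome_start(self):
        g = GeneAnnotation("G", "G", "chr1", 1_000, "+")
        (w,) = make_promoters([g], chrom_sizes={"chr1": 100_000})
        assert (w.interval.start, w.interval.end) == (0, 1_499)

    def test_unknown_chromosome_errors(self):
        g = GeneAnnotation("G", "G", "chrZ", 5_000, "+")
        with pytest.raises(KeyError):
            make_promoters([g], chrom_sizes={"chr1": 100_000})

    @given(st.lists(st.tuples(st.integers(1, 1_000_000), st.sampled_from("+-")), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_one_window_per_tss_and_contains_tss(self, specs):
        genes = [
            GeneAnnotation(f"G{i}", f"G{i}", "chr1", tss, strand)
            for i, (tss, strand) in enumerate(specs)
        ]
        windows = make_promoters(genes, chrom_sizes={"chr1": 2_000_000})
        assert len(windows) == len(genes)
        for g, w in zip(genes, windows):
            assert w.interval.contains_point(g.chrom, g.tss - 1)
            assert len(w.interval) <= 2_000


class TestBedIO:
    def test_parse_and_roundtrip(self, tmp_path):
        path = tmp_path / "peaks.bed"
        path.write_text("chr1\t100\t200\tpk1\nchr2\t50\t80\n")
        ocrs = read_bed(path, "tcell")
        assert [(o.interval.chrom, o.interval.start, o.interval.end, o.peak_id) for o in ocrs] == [
            ("chr1", 100, 200, "pk1"),
            ("chr2", 50, 80, "chr2:50-80"),
        ]
        out = tmp_path / "out.bed"
        write_bed(out, ocrs)
        again = read_bed(out, "tcell")
        assert [(o.interval, o.peak_id) for o in again] == [(o.interval, o.peak_id) for o in ocrs]

    def test_empty_file_gives_empty_collection(self, tmp_path):
        path = tmp_path / "empty.bed"
        path.write_text("")
        assert read_bed(path, "tcell") == []

    def test_inverted_coordinates_error_names_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t200\t100\n")
        with pytest.raises(FormatError, match="line 1"):
            read_bed(path, "tcell")


class TestLoopIO:
    IBED_HEADER = "\t".join(
        ["bait_chr", "bait_start", "bait_end", "bait_name", "otherEnd_chr",
         "otherEnd_start", "otherEnd_end", "otherEnd_name", "N_reads", "score"]
    )

    def test_ibed_parse(self, tmp_path):
        path = tmp_path / "loops.ibed"
        path.write_text(
            self.IBED_HEADER + "\n" + "chr2\t100\t500\tb1\tchr2\t9000\t9400\toe1\t12\t6.1\n"
        )
        (loop,) = read_loops(path, "ibed", "tcell", "pcc")
        assert loop.anchor1.start == 100 and loop.anchor2.start == 9000
        assert loop.score == pytest.approx(6.1)

    def test_interchromosomal_bedpe_dropped(self, tmp_path):
        path = tmp_path / "loops.bedpe"
        path.write_text("chr1\t100\t200\tchr5\t300\t400\nchr1\t100\t200\tchr1\t300\t400\n")
        loops = read_loops(path, "bedpe", "tcell", "hic")
        assert len(loops) == 1 and loops[0].anchor2.start == 300

    def test_duplicate_lines_kept_with_distinct_ids(self, tmp_path):
        path = tmp_path / "loops.bedpe"
        line = "chr1\t100\t200\tchr1\t300\t400\n"
        path.write_text(line * 2)
        loops = read_loops(path, "bedpe", "tcell", "hic")
        assert len(loops) == 2
        assert loops[0].loop_id != loops[1].loop_id

    def test_ibed_roundtrip_preserves_coordinates(self, tmp_path, tiny_genome):
        _genes, _promoters, _ocrs, loops = tiny_genome
        path = tmp_path / "rt.ibed"
        write_loops_ibed(path, loops)
        again = read_loops(path, "ibed", "tcell", "pcc")
        assert [(l.anchor1, l.anchor2) for l in again] == [(l.anchor1, l.anchor2) for l in loops]

    def test_missing_columns_is_format_error(self, tmp_path):
        path = tmp_path / "bad.ibed"
        path.write_text("bait_chr\tbait_start\nchr1\t5\n")
        with pytest.raises(FormatError, match="missing columns"):
            read_loops(path, "ibed", "tcell", "pcc")


class TestSumstats:
    def _write(self, tmp_path, rows, header="variant_id\tchrom\tpos\teffect_allele\tother_allele\tor\tse"):
        path = tmp_path / "stats.tsv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    def test_odds_ratio_converted_to_log_odds(self, tmp_path):
        path = self._write(tmp_path, ["rs1\tchr1\t100\tA\tG\t1.0\t0.1", "rs2\tchr1\t200\tC\tT\t2.0\t0.1"])
        recs = read_sumstats(path, {"or": "or"})
        assert recs[0].beta == pytest.approx(0.0)
        assert recs[1].beta == pytest.approx(math.log(2.0), abs=1e-4)

    def test_nonpositive_se_rows_dropped(self, tmp_path):
        path = self._write(tmp_path, ["rs1\tchr1\t100\tA\tG\t1.5\t0.0", "rs2\tchr1\t200\tC\tT\t1.5\t0.1"])
        recs = read_sumstats(path, {"or": "or"})
        assert [r.variant_id for r in recs] == ["rs2"]

    def test_unmapped_mandatory_column_errors(self, tmp_path):
        path = self._write(tmp_path, ["rs1\tchr1\t100\tA\tG\t1.5\t0.1"])
        with pytest.raises(FormatError):
            read_sumstats(path, {"se": "standard_error", "or": "or"})


def test_merge_intervals_merges_overlapping_only():
    ivs = [
        GenomicInterval("chr1", 0, 100),
        GenomicInterval("chr1", 50, 150),
        GenomicInterval("chr1", 150, 200),  # abutting: kept separate
        GenomicInterval("chr2", 0, 50),
    ]
    merged = merge_intervals(ivs)
    assert [(m.chrom, m.start, m.end) for m in merged] == [
        ("chr1", 0, 150), ("chr1", 150, 200), ("chr2", 0, 50),
    ]


def test_parse_region():
    iv = parse_region("chr6:25000000-34000000")
    assert (iv.chrom, iv.start, iv.end) == ("chr6", 25_000_000, 34_000_000)
    with pytest.raises(ValueError):
        parse_region("chr6")
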