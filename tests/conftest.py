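import pytest

from chromv2g.core import GeneAnnotation, GenomicInterval, Loop, Ocr, make_promoters
from chromv2g.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=42)


@pytest.fixture(scope="session")
def sim_truth(sim_config):
    """Default synthetic dataset with planted ground truth (seed 42)."""
    return simulate_all(sim_config)


@pytest.fixture(scope="session")
def sim_dataset_dir(tmp_path_factory, sim_config, sim_truth):
    """The same dataset written to disk in pipeline interchange formats."""
    from chromv2g.simulate import write_dataset

    outdir = tmp_path_factory.mktemp("simdata")
    write_dataset(sim_config, sim_truth, str(outdir))
    return outdir


@pytest.fixture
def tiny_genome():
    """A hand-built single-cell-type fixture small enough to reason about.

    One chromosome; two genes (G1 open promoter, G2 promoter not open);
    three OCRs (distal A, promoter-overlapping P1, isolated B); loops:
    A <-> promoter(G1), A <-> promoter(G2), and a desert-to-desert control.
    """
    genes = [
        GeneAnnotation("G1", "GeneOne", "chr1", 10_000, "+"),
        GeneAnnotation("G2", "GeneTwo", "chr1", 60_000, "+"),
    ]
    promoters = make_promoters(genes, chrom_sizes={"chr1": 1_000_000})
    ocrs = [
        Ocr(GenomicInterval("chr1", 30_000, 30_500), "tcell", "peakA"),
        Ocr(GenomicInterval("chr1", 9_000, 9_400), "tcell", "peakP1"),  # in G1 promoter
        Ocr(GenomicInterval("chr1", 45_000, 45_400), "tcell", "peakB"),
    ]
    loops = [
        Loop(GenomicInterval("chr1", 8_600, 9_600), GenomicInterval("chr1", 29_900, 30_600),
             "tcell", "loop_g1", source="pcc", score=6.0),
        Loop(GenomicInterval("chr1", 58_600, 59_600), GenomicInterval("chr1", 29_900, 30_600),
             "tcell", "loop_g2", source="pcc", score=6.5),
        Loop(GenomicInterval("chr1", 200_000, 200_400), GenomicInterval("chr1", 300_000, 300_400),
             "tcell", "loop_neg", source="pcc", score=5.1),
    ]
    return genes, promoters, ocrs, loops
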