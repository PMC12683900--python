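"""End-to-end orchestration of the V2G pipeline stages.

Each stage is a thin wrapper over the library modules that reads its inputs
from the run directory, writes its TSV outputs, and records what it did in
a JSON manifest (input checksums, parameters, package version), so a run is
reproducible and auditable from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .core import GenomicInterval, parse_region
from .cre import AnnotCategory, define_cres, partition_annotations, write_category_bed
from .io import read_bed, read_chrom_sizes, read_gene_list, read_loops, read_tss_table
from .core import make_promoters
from .coloc import (
    ColocPriors,
    assign_egenes,
    build_loci,
    concordance_summary,
    write_locus_bed,
)
from .sharing import classify_pairs, precision_recall, summarize_sharing, tally_by_group
from .v2g import (
    MHC_GRCH38,
    filter_proxies,
    genes_per_variant,
    map_variants_to_genes,
    read_proxy_table,
    write_pair_table,
)

logger = logging.getLogger(__name__)

STAGES = ("cre", "annot", "v2g", "sharing", "benchmark", "loci", "coloc", "motif")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    data_dir: Path
    out_dir: Path
    cell_types: list[str]
    seed: int = 42
    r2_min: float = 0.8
    mhc: Optional[GenomicInterval] = MHC_GRCH38
    promoter_upstream: int = 1500
    promoter_downstream: int = 500
    locus_flank: int = 250_000
    coloc_priors: ColocPriors = field(default_factory=ColocPriors)
    truth_genes_path: Optional[Path] = None
    require_open_promoter: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = raw.get("params", {})
        mhc_text = params.get("mhc")
        cfg = cls(
            data_dir=Path(raw["data_dir"]),
            out_dir=Path(raw["out_dir"]),
            cell_types=list(raw["cell_types"]),
            seed=int(raw.get("seed", 42)),
            r2_min=float(params.get("r2_min", 0.8)),
            mhc=parse_region(mhc_text) if mhc_text else MHC_GRCH38,
            promoter_upstream=int(params.get("promoter_upstream", 1500)),
            promoter_downstream=int(params.get("promoter_downstream", 500)),
            locus_flank=int(params.get("locus_flank", 250_000)),
            truth_genes_path=Path(raw["truth_genes"]) if raw.get("truth_genes") else None,
        )
        if not cfg.data_dir.exists():
            raise FileNotFoundError(f"data_dir {cfg.data_dir} does not exist")
        return cfg


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


class PipelineRun:
    """Stateful runner executing stages in dependency order."""

    def __init__(self, config: RunConfig) -> None:
        self.config = config
        self.manifest: dict = {"version": __version__, "stages": {}, "inputs": {}}
        self._cres_by_cell: dict = {}
        self._pairs: Optional[pd.DataFrame] = None
        self._loci = None
        self._filtered_proxies = None
        self._sentinels = None
        config.out_dir.mkdir(parents=True, exist_ok=True)

    # -- stage implementations -------------------------------------------
    def _load_genome(self):
        cfg = self.config
        genes = read_tss_table(cfg.data_dir / "genes.tsv")
        sizes = read_chrom_sizes(cfg.data_dir / "chrom.sizes")
        promoters = make_promoters(
            genes, cfg.promoter_upstream, cfg.promoter_downstream, sizes
        )
        return genes, sizes, promoters

    def stage_cre(self) -> None:
        cfg = self.config
        _genes, _sizes, promoters = self._load_genome()
        counts = {}
        for ct in cfg.cell_types:
            ocrs = read_bed(cfg.data_dir / f"{ct}.ocr.bed", ct)
            loops = read_loops(cfg.data_dir / f"{ct}.loops.ibed", "ibed", ct, "pcc")
            cres = define_cres(ocrs, loops, promoters, cfg.require_open_promoter)
            self._cres_by_cell[ct] = cres
            with open(cfg.out_dir / f"{ct}.cre.bed", "w") as fh:
                for c in cres:
                    iv = c.ocr.interval
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.cre_id}\t"
                        f"{','.join(sorted(c.contacted_genes))}\n"
                    )
            counts[ct] = {"n_ocr": len(ocrs), "n_loops": len(loops), "n_cre": len(cres)}
        self._record("cre", counts)

    def stage_annot(self) -> None:
        cfg = self.config
        self._require("cre", self._cres_by_cell)
        _genes, _sizes, promoters = self._load_genome()
        counts = {}
        for ct in cfg.cell_types:
            ocrs = read_bed(cfg.data_dir / f"{ct}.ocr.bed", ct)
            partition = partition_annotations(ocrs, self._cres_by_cell[ct], promoters)
            for category in AnnotCategory:
                write_category_bed(
                    partition, category, str(cfg.out_dir / f"{ct}.{category.value}.bed")
                )
            counts[ct] = {c.value: len(ivs) for c, ivs in partition.categories.items()}
        self._record("annot", counts)

    def stage_v2g(self) -> None:
        cfg = self.config
        self._require("cre", self._cres_by_cell)
        sentinels, raw_proxies = read_proxy_table(cfg.data_dir / "proxies.tsv")
        self._sentinels = sentinels
        self._filtered_proxies = filter_proxies(raw_proxies, sentinels, cfg.r2_min, cfg.mhc)
        self._pairs = map_variants_to_genes(self._filtered_proxies, self._cres_by_cell)
        write_pair_table(self._pairs, str(cfg.out_dir / "v2g_pairs.tsv"))
        if self._pairs.empty:
            stats = {"n_pairs": 0}
        else:
            _counts, mean_genes = genes_per_variant(self._pairs)
            stats = {
                "n_pairs": len(self._pairs),
                "n_variants": int(self._pairs["proxy_id"].nunique()),
                "n_genes": int(self._pairs["gene_id"].nunique()),
                "mean_genes_per_variant": mean_genes,
            }
        self._record("v2g", stats)

    def stage_sharing(self) -> None:
        cfg = self.config
        self._require("v2g", self._pairs)
        summary = summarize_sharing(self._pairs)
        classified = classify_pairs(self._pairs)
        classified.to_csv(cfg.out_dir / "pairs_classified.tsv", sep="\t", index=False)
        for axis in ("trait", "cell_type"):
            tally_by_group(self._pairs, axis).to_csv(
                cfg.out_dir / f"tally_by_{axis}.tsv", sep="\t", index=False
            )
        self._record("sharing", summary.__dict__)

    def stage_benchmark(self) -> None:
        cfg = self.config
        self._require("v2g", self._pairs)
        if cfg.truth_genes_path is None:
            self._record("benchmark", {"skipped": "no truth gene list configured"})
            return
        truth = read_gene_list(cfg.truth_genes_path)
        predicted = set(self._pairs["gene_id"])
        precision, recall = precision_recall(predicted, truth)
        self._record("benchmark", {"precision": precision, "recall": recall,
                                    "n_predicted": len(predicted), "n_truth": len(truth)})

    def stage_loci(self) -> None:
        cfg = self.config
        self._require("v2g", self._filtered_proxies)
        ld_path = cfg.data_dir / "sentinel_ld.tsv"
        ld_r2: dict = {}
        if ld_path.exists():
            ld_df = pd.read_csv(ld_path, sep="\t")
            ld_r2 = {
                frozenset({r.sentinel_a, r.sentinel_b}): float(r.r2)
                for r in ld_df.itertuples(index=False)
            }
        self._loci = build_loci(
            self._sentinels, self._filtered_proxies, flank=cfg.locus_flank, ld_r2=ld_r2
        )
        write_locus_bed(self._loci, str(cfg.out_dir / "loci.bed"))
        self._record("loci", {"n_loci": len(self._loci)})

    def stage_coloc(self) -> None:
        cfg = self.config
        self._require("loci", self._loci)
        eqtl_path = cfg.data_dir / "eqtl.tsv"
        if not eqtl_path.exists():
            self._record("coloc", {"skipped": "no eqtl.tsv in data_dir"})
            return
        eqtl = pd.read_csv(eqtl_path, sep="\t", dtype={"chrom": str, "gene_chrom": str})
        egenes = assign_egenes(self._loci, eqtl, proxies=self._filtered_proxies)
        egenes.to_csv(cfg.out_dir / "egenes.tsv", sep="\t", index=False)
        v2g_genes = set(self._pairs["gene_id"]) if self._pairs is not None else set()
        summary = concordance_summary(v2g_genes, set(egenes["gene_id"]))
        self._record("coloc", {"n_egene_rows": len(egenes), **summary})

    def stage_motif(self) -> None:
        cfg = self.config
        pfm_path = cfg.data_dir / "motifs.pfm"
        variants_path = cfg.data_dir / "variant_contexts.tsv"
        if not (pfm_path.exists() and variants_path.exists()):
            self._record("motif", {"skipped": "no motifs.pfm / variant_contexts.tsv"})
            return
        from .motif import hits_to_rows, read_jaspar_pfms, scan_variant

        pwms = read_jaspar_pfms(str(pfm_path))
        contexts = pd.read_csv(variants_path, sep="\t")
        rows = []
        for rec in contexts.itertuples(index=False):
            for pwm in pwms:
                rows.extend(
                    hits_to_rows(scan_variant(pwm, rec.ref_context, rec.alt_context,
                                              variant_id=rec.variant_id))
                )
        pd.DataFrame(rows).to_csv(cfg.out_dir / "motif_hits.tsv", sep="\t", index=False)
        self._record("motif", {"n_hits": len(rows), "n_motifs": len(pwms)})

    # -- plumbing ---------------------------------------------------------
    def _require(self, stage: str, artefact) -> None:
        if artefact is None or (isinstance(artefact, dict) and not artefact):
            raise RuntimeError(f"stage dependency not satisfied: run {stage!r} first")

    def _record(self, stage: str, info: dict) -> None:
        self.manifest["stages"][stage] = {"time": time.time(), **_jsonable(info)}

    def run(self, stages: Sequence[str] = STAGES) -> Path:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        ordered = [s for s in STAGES if s in set(stages)]
        for path in sorted(self.config.data_dir.glob("*")):
            if path.is_file():
                self.manifest["inputs"][path.name] = _checksum(path)
        for stage in ordered:
            t0 = time.time()
            getattr(self, f"stage_{stage}")()
            logger.info("stage %s finished in %.2fs", stage, time.time() - t0)
        manifest_path = self.config.out_dir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return self.config.out_dir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (int, float, str, bool)) or obj is None:
        return obj
    return str(obj)


def run_pipeline(config: RunConfig, stages: Sequence[str] = STAGES) -> Path:
    """Execute the requested stages and return the output directory."""
    return PipelineRun(config).run(stages)
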