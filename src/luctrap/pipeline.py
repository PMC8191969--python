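"""Pipeline configuration and orchestration.

``run_pipeline`` executes extract -> map -> call -> quantify -> classify ->
summarize over on-disk inputs and writes a per-barcode records TSV plus a
JSON cohort summary; a run log records counts in and out of every filter.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import calling, classify, io, junctions, quantify, summary

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("luctrap")


@dataclass
class PipelineConfig:
    """Paths and thresholds for one analysis run."""

    genome_fasta: str
    annotation_gff: str
    wt_regions: str
    junction_fastq: str
    dna_fastq: str
    rna_fastq: str
    out_dir: str = "luctrap_out"
    # extraction / mapping
    max_template_mismatch: int = 2
    max_mismatches: int = 3
    min_flank_len: int = 20
    index_k: int = 10
    max_n: int = 2
    # calling
    merge_window: int = 5
    min_reads: int = 2
    min_dominance: float = 0.6
    # quantification
    min_count: int = 5
    scale: float = 10_000.0
    # classification
    wt_strand_aware: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_dominance <= 1.0:
            raise ValueError("min_dominance must be within [0, 1]")
        if self.max_mismatches < 0 or self.merge_window < 0 or self.min_reads < 1:
            raise ValueError("thresholds outside documented ranges")
        if self.min_flank_len < 1 or self.index_k < 1 or self.min_count < 0:
            raise ValueError("thresholds outside documented ranges")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate_inputs(self) -> None:
        for name in ("genome_fasta", "annotation_gff", "wt_regions",
                     "junction_fastq", "dna_fastq", "rna_fastq"):
            path = Path(getattr(self, name))
            if not path.exists():
                raise FileNotFoundError(f"{name}: {path}")


RECORD_COLUMNS = [
    "barcode", "status", "chromosome", "position", "strand",
    "support_reads", "dominance", "dna_reads", "rna_reads", "level",
    "insertion_type", "wt_type", "wt_fpkm", "decade", "percentile_bin",
]


def _map_junctions(
    extracted: list[junctions.ExtractedJunction],
    index: junctions.GenomeIndex,
    config: PipelineConfig,
) -> tuple[list[tuple[str, Optional[junctions.FlankAlignment]]], dict[str, int]]:
    cache: dict[str, junctions.MapResult] = {}
    pairs = []
    tally: dict[str, int] = {}
    for junc in extracted:
        result = cache.get(junc.flank)
        if result is None:
            result = junctions.map_flank(
                junc.flank, index,
                max_mismatches=config.max_mismatches,
                min_flank_len=config.min_flank_len,
                max_n=config.max_n,
            )
            cache[junc.flank] = result
        tally[result.reason] = tally.get(result.reason, 0) + 1
        pairs.append((junc.barcode, result.alignment))
    return pairs, tally


def run_pipeline(config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Run the full analysis; returns (records table, cohort summary).

    Writes ``records.tsv``, ``summary.json`` and ``run_log.json`` into
    ``config.out_dir``.
    """
    config.validate_inputs()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"stage": None}
    template = junctions.TDnaTemplate()

    try:
        log["stage"] = "load"
        genome_seqs = io.read_fasta(config.genome_fasta)
        genes = io.read_gff3_genes(config.annotation_gff)
        annotation = classify.GeneAnnotation(genes, chromosomes=genome_seqs.keys())
        wt = classify.WtTranscriptome(io.read_wt_regions(config.wt_regions))

        log["stage"] = "extract"
        extracted, extract_tally = junctions.extract_junctions(
            io.read_fastq(config.junction_fastq), template,
            config.max_template_mismatch, config.min_flank_len,
        )
        log["extract"] = extract_tally
        logger.info("extract: %s", extract_tally)

        log["stage"] = "map"
        index = junctions.build_genome_index(genome_seqs, k=config.index_k)
        pairs, map_tally = _map_junctions(extracted, index, config)
        log["map"] = map_tally
        logger.info("map: %s", map_tally)

        log["stage"] = "call"
        supports = calling.aggregate_pairs(pairs, merge_window=config.merge_window)
        calls = calling.call_lines(supports, config.min_reads, config.min_dominance)
        log["call"] = {
            status: sum(c.status == status for c in calls)
            for status in ("called", "low_support", "low_dominance", "multi_insert", "unmapped")
        }
        logger.info("call: %s", log["call"])

        log["stage"] = "quantify"
        dna_counts, dna_total = quantify.count_barcodes(config.dna_fastq, template)
        rna_counts, rna_total = quantify.count_barcodes(config.rna_fastq, template)
        levels = quantify.compute_levels(
            dict(dna_counts), dna_total, dict(rna_counts), rna_total,
            min_count=config.min_count, scale=config.scale,
        )
        log["quantify"] = {
            "dna_total": dna_total,
            "rna_total": rna_total,
            "barcodes": len(levels),
            "omitted": int((levels["status"] == "omitted").sum()),
        }
        logger.info("quantify: %s", log["quantify"])

        log["stage"] = "classify"
        rows = []
        for call in calls:
            level = np.nan
            dna_reads = rna_reads = 0
            if call.barcode in levels.index:
                entry = levels.loc[call.barcode]
                dna_reads, rna_reads = int(entry["dna_reads"]), int(entry["rna_reads"])
                if entry["status"] == "ok":
                    level = float(entry["level"])
            row = {
                "barcode": call.barcode,
                "status": call.status,
                "chromosome": None,
                "position": None,
                "strand": None,
                "support_reads": call.support_reads,
                "dominance": call.dominance,
                "dna_reads": dna_reads,
                "rna_reads": rna_reads,
                "level": level,
                "insertion_type": None,
                "wt_type": None,
                "wt_fpkm": None,
                "decade": None,
                "percentile_bin": None,
            }
            if call.status == "called":
                chrom, pos, strand = call.locus
                row.update(chromosome=chrom, position=pos, strand=strand)
                row["insertion_type"] = classify.classify_insertion_type(
                    chrom, pos, strand, annotation
                )
                if not math.isnan(level):
                    wt_type, fpkm = classify.classify_wt_overlap(
                        chrom, pos, level, wt,
                        strand=strand, strand_aware=config.wt_strand_aware,
                    )
                    row.update(wt_type=wt_type, wt_fpkm=fpkm)
                    row["decade"] = str(summary.level_decade(level))
            rows.append(row)
        records = pd.DataFrame(rows, columns=RECORD_COLUMNS)

        log["stage"] = "summarize"
        usable = records[(records["status"] == "called") & records["level"].notna()].copy()
        transcribed = usable[usable["level"] > 0]
        if len(transcribed) >= 3:
            bins = summary.percentile_bins(transcribed["level"].tolist())
            records.loc[transcribed.index, "percentile_bin"] = bins
            usable.loc[transcribed.index, "percentile_bin"] = bins
        cohort = summary.summarize(usable) if len(usable) else {"n_called": 0}
        log["summarize"] = {"usable_records": len(usable)}
    except Exception:
        logger.exception(
            "pipeline aborted at stage %r (counts so far: %s)", log.get("stage"), log
        )
        raise

    records.to_csv(out_dir / "records.tsv", sep="\t", index=False)
    with open(out_dir / "summary.json", "w") as out:
        json.dump(cohort, out, indent=2)
    with open(out_dir / "run_log.json", "w") as out:
        json.dump({"config": asdict(config), "log": log}, out, indent=2)
    return records, cohort
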