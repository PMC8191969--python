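"""Synthetic promoter-trap screen generator.

Produces every input the analysis consumes, with known ground truth:

* a multi-chromosome mini-genome with non-overlapping protein-coding genes
  on both strands covering ~half of the sequence (the genic/intergenic
  split of the *A. thaliana* genome is roughly even);
* a wild-type transcriptome: 70.4% of genes transcribed, plus a small
  complement of intergenic transcribed regions so that 97.8% of regions
  are genic, each with a log-normal FPKM;
* a cohort of barcoded single-insert reporter lines placed uniformly over
  the genome.  Lines trapping a gene in sense orientation activate with
  their own probability and draw log10 levels around 5; antisense and
  intergenic lines model de novo activation with log10 levels around 4.
  Levels are truncated to [10^1, 10^7], the dynamic range of the assay;
* junction reads laid out as revcomp(LUC head) + revcomp(barcode) +
  revcomp(border) + genomic flank, with optional artefacts (barcode
  substitutions, chimeric flanks, barcode collisions, multi-insert lines);
* DNA and RNA barcode-count libraries: multinomial draws with near-equal
  DNA weights (optional copy-number jitter) and RNA weights proportional
  to DNA weight x true level.

Everything is deterministic for a fixed seed.  Base qualities are a
constant placeholder: quality handling is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import Gene, GeneAnnotation, WtRegion
from .junctions import TDnaTemplate, revcomp

__all__ = [
    "GenomeModel",
    "WtExpressionModel",
    "CohortConfig",
    "generate_genome",
    "generate_wt_expression",
    "generate_cohort",
    "simulate_junction_reads",
    "simulate_junction_library",
    "simulate_count_libraries",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TRUTH_COLUMNS = [
    "line_id", "barcode", "chromosome", "rb_position", "strand",
    "insertion_type", "true_transcribed", "true_level", "secondary", "collided",
]


@dataclass
class GenomeModel:
    """A mini reference: chromosome sequences plus gene features (0-based
    half-open; same-strand genes never overlap)."""

    chromosomes: list[tuple[str, str]]
    genes: list[Gene]

    def chrom_dict(self) -> dict[str, str]:
        return dict(self.chromosomes)

    def annotation(self) -> GeneAnnotation:
        return GeneAnnotation(self.genes, chromosomes=[n for n, _ in self.chromosomes])


@dataclass
class WtExpressionModel:
    """Wild-type transcribed regions with FPKM."""

    regions: list[WtRegion]


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic transgenic cohort.

    Activation probabilities and level distributions follow the screen this
    generator emulates: about one third of lines transcribed overall, levels
    spanning 10^1-10^7 with a mode near 10^4 (10^5 for genic-sense traps).
    Artefact rates default to zero; they are free parameters of the noise
    model, not estimates.
    """

    n_lines: int = 76
    p_activate_genic_sense: float = 0.66
    p_activate_genic_as: float = 0.27
    p_activate_intergenic: float = 0.27
    log10_level_mean_trap: float = 5.0
    log10_level_mean_denovo: float = 4.0
    log10_level_sd: float = 1.0
    barcode_length: int = 12
    seed: int = 0
    barcode_substitution_rate: float = 0.0
    chimera_rate: float = 0.0
    collision_rate: float = 0.0
    multi_insert_rate: float = 0.0
    margin: int = 200  # keep junctions this far from chromosome ends

    def __post_init__(self) -> None:
        if self.n_lines <= 0:
            raise ValueError("n_lines must be positive")
        for name in (
            "p_activate_genic_sense", "p_activate_genic_as", "p_activate_intergenic",
            "barcode_substitution_rate", "chimera_rate", "collision_rate",
            "multi_insert_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("log10_level_mean_trap", "log10_level_mean_denovo"):
            v = getattr(self, name)
            if not 1.0 <= v <= 7.0:
                raise ValueError(f"{name}={v} outside [1, 7]")
        if self.log10_level_sd <= 0:
            raise ValueError("log10_level_sd must be positive")
        if self.barcode_length <= 0:
            raise ValueError("barcode_length must be positive")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _partition(rng: np.random.Generator, total: int, parts: int, minimum: int) -> np.ndarray:
    """Split ``total`` into ``parts`` integers >= minimum with random jitter."""
    extra = total - parts * minimum
    if extra < 0:
        raise ValueError("partition infeasible: lower the density of the request")
    probs = rng.dirichlet(np.full(parts, 3.0))
    return minimum + rng.multinomial(extra, probs)


def generate_genome(
    n_chrom: int = 5,
    chrom_len: int = 120_000,
    n_genes: int = 120,
    genic_fraction: float = 0.5,
    seed: int = 0,
    min_gene_len: int = 300,
    min_gap_len: int = 100,
) -> GenomeModel:
    """Random mini-genome with non-overlapping genes covering
    ``genic_fraction`` of each chromosome.

    Genes are laid down left to right with randomly jittered lengths and
    gaps, so the genic fraction is met by construction and no two genes
    overlap on either strand.  Raises ``ValueError`` when the requested
    density cannot be placed.
    """
    if chrom_len < 10_000:
        raise ValueError("chrom_len must be at least 10 kb")
    if not 0.0 < genic_fraction < 1.0:
        raise ValueError("genic_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    per_chrom = [n_genes // n_chrom + (1 if c < n_genes % n_chrom else 0) for c in range(n_chrom)]
    chromosomes: list[tuple[str, str]] = []
    genes: list[Gene] = []
    serial = 0
    for c in range(n_chrom):
        name = f"chr{c + 1}"
        chromosomes.append((name, _random_sequence(rng, chrom_len)))
        g = per_chrom[c]
        if g == 0:
            continue
        genic_bp = int(round(genic_fraction * chrom_len))
        gene_lens = _partition(rng, genic_bp, g, min_gene_len)
        gaps = _partition(rng, chrom_len - genic_bp, g + 1, min_gap_len)
        cursor = 0
        for i in range(g):
            cursor += int(gaps[i])
            start, end = cursor, cursor + int(gene_lens[i])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(f"GENE{serial:05d}", name, start, end, strand))
            serial += 1
            cursor = end
    return GenomeModel(chromosomes, genes)


def generate_wt_expression(
    genome: GenomeModel,
    transcribed_gene_fraction: float = 0.704,
    genic_region_fraction: float = 0.978,
    log10_fpkm_mean: float = 1.0,
    log10_fpkm_sd: float = 0.6,
    intergenic_region_len: int = 800,
    seed: int = 0,
) -> WtExpressionModel:
    """Wild-type transcribed regions: a transcribed subset of the annotated
    genes plus a small intergenic complement.

    ``transcribed_gene_fraction`` of genes get a region spanning the gene;
    intergenic regions are added so that ``genic_region_fraction`` of all
    regions are genic.  FPKM is log10-normal and strictly positive.
    """
    rng = np.random.default_rng(seed)
    n_genic = int(round(transcribed_gene_fraction * len(genome.genes)))
    chosen = rng.choice(len(genome.genes), size=n_genic, replace=False) if n_genic else []
    regions: list[WtRegion] = []
    for i in sorted(chosen):
        g = genome.genes[i]
        fpkm = float(10 ** rng.normal(log10_fpkm_mean, log10_fpkm_sd))
        regions.append(WtRegion(g.chromosome, g.start, g.end, g.strand, fpkm))
    n_intergenic = int(round(n_genic * (1.0 - genic_region_fraction) / genic_region_fraction))
    annotation = genome.annotation()
    sizes = {name: len(seq) for name, seq in genome.chromosomes}
    placed = 0
    attempts = 0
    while placed < n_intergenic and attempts < 200 * max(n_intergenic, 1):
        attempts += 1
        name = str(rng.choice([n for n, _ in genome.chromosomes]))
        start = int(rng.integers(0, max(sizes[name] - intergenic_region_len, 1)))
        end = start + intergenic_region_len
        if annotation.overlapping(name, start) or annotation.overlapping(name, end - 1):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        fpkm = float(10 ** rng.normal(log10_fpkm_mean - 0.5, log10_fpkm_sd))
        regions.append(WtRegion(name, start, end, strand, fpkm))
        placed += 1
    return WtExpressionModel(regions)


def _random_barcode(rng: np.random.Generator, length: int) -> str:
    return _random_sequence(rng, length)


def generate_cohort(genome: GenomeModel, config: CohortConfig) -> pd.DataFrame:
    """Ground-truth table for a cohort of barcoded reporter lines.

    One row per insertion: uniform genomic placement (honouring the
    end ``margin``), random strand, activation drawn per insertion type,
    levels 10^Normal(mean_type, sd) truncated to [10^1, 10^7].  Multi-insert
    lines contribute a ``secondary`` row sharing the line's barcode;
    collided lines reuse another line's barcode.
    """
    rng = np.random.default_rng(config.seed)
    annotation = genome.annotation()
    names = [n for n, _ in genome.chromosomes]
    spans = np.array([len(s) - 2 * config.margin for _, s in genome.chromosomes], dtype=float)
    if (spans <= 0).any():
        raise ValueError("margin leaves no placeable span on some chromosome")
    probs = spans / spans.sum()
    p_by_type = {
        "genic_sense": config.p_activate_genic_sense,
        "genic_as": config.p_activate_genic_as,
        "intergenic": config.p_activate_intergenic,
    }
    used: set[str] = set()
    barcodes: list[str] = []
    rows: list[tuple] = []

    def draw_insertion(line_id: str, barcode: str, secondary: bool, collided: bool) -> None:
        ci = rng.choice(len(names), p=probs)
        name = names[ci]
        pos = int(rng.integers(config.margin, config.margin + int(spans[ci])))
        strand = "+" if rng.random() < 0.5 else "-"
        itype = annotation.classify(name, pos, strand)
        active = rng.random() < p_by_type[itype]
        if active:
            mean = (
                config.log10_level_mean_trap
                if itype == "genic_sense"
                else config.log10_level_mean_denovo
            )
            level = float(np.clip(10 ** rng.normal(mean, config.log10_level_sd), 1e1, 1e7))
        else:
            level = 0.0
        rows.append((line_id, barcode, name, pos, strand, itype, active, level, secondary, collided))

    for i in range(config.n_lines):
        collided = bool(barcodes) and rng.random() < config.collision_rate
        if collided:
            barcode = barcodes[int(rng.integers(0, len(barcodes)))]
        else:
            barcode = _random_barcode(rng, config.barcode_length)
            while barcode in used:
                barcode = _random_barcode(rng, config.barcode_length)
            used.add(barcode)
        barcodes.append(barcode)
        line_id = f"line{i:05d}"
        draw_insertion(line_id, barcode, False, collided)
        if rng.random() < config.multi_insert_rate:
            draw_insertion(line_id, barcode, True, collided)
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def _junction_read_seq(
    genome_seqs: dict[str, str],
    template: TDnaTemplate,
    barcode: str,
    chromosome: str,
    rb_position: int,
    strand: str,
    flank_len: int,
    luc_seg_len: int,
) -> str:
    """Assemble one clean junction read (canonical read orientation)."""
    ref = genome_seqs[chromosome]
    if strand == "+":
        lo = rb_position - flank_len + 1
        if lo < 0 or rb_position >= len(ref):
            raise ValueError("junction too close to the chromosome end for this flank")
        flank = revcomp(ref[lo: rb_position + 1])
    else:
        hi = rb_position + flank_len
        if rb_position < 0 or hi > len(ref):
            raise ValueError("junction too close to the chromosome end for this flank")
        flank = ref[rb_position: hi]
    return (
        revcomp(template.luc_head[:luc_seg_len])
        + revcomp(barcode)
        + revcomp(template.border)
        + flank
    )


def simulate_junction_reads(
    truth: pd.DataFrame,
    genome: GenomeModel,
    template: TDnaTemplate,
    depth_per_line: int = 10,
    read_len: int = 110,
    luc_seg_len: int = 16,
    barcode_substitution_rate: float = 0.0,
    chimera_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Junction library as (read_id, sequence) records.

    Each clean read is revcomp(LUC head segment) + revcomp(barcode) +
    revcomp(border) + genomic flank starting at the true junction on the
    insert strand.  Artefact reads carry a substituted barcode base or a
    chimeric flank from a random locus, at the configured per-read rates.
    """
    flank_len = read_len - luc_seg_len - template.barcode_len - len(template.border)
    if flank_len < 20:
        raise ValueError("read_len too short to span border + barcode + 20 nt flank")
    rng = np.random.default_rng(seed)
    seqs = genome.chrom_dict()
    names = list(seqs)
    reads: list[tuple[str, str]] = []
    serial = 0
    for row in truth.itertuples(index=False):
        for _ in range(depth_per_line):
            chrom, pos, strand = row.chromosome, int(row.rb_position), row.strand
            if chimera_rate and rng.random() < chimera_rate:
                chrom = names[int(rng.integers(0, len(names)))]
                pos = int(rng.integers(flank_len, len(seqs[chrom]) - flank_len))
                strand = "+" if rng.random() < 0.5 else "-"
            seq = _junction_read_seq(
                seqs, template, row.barcode, chrom, pos, strand, flank_len, luc_seg_len
            )
            if barcode_substitution_rate and rng.random() < barcode_substitution_rate:
                # barcode occupies [luc_seg_len, luc_seg_len + barcode_len) of the read
                i = luc_seg_len + int(rng.integers(0, template.barcode_len))
                old = seq[i]
                new = "ACGT"[int(rng.integers(0, 3))]
                if new == old:  # map the 3-way draw onto the other bases
                    new = "ACGT"[3]
                seq = seq[:i] + new + seq[i + 1:]
            reads.append((f"jr{serial:08d}|{row.line_id}", seq))
            serial += 1
    return reads


def simulate_junction_library(
    truth: pd.DataFrame,
    genome: GenomeModel,
    template: TDnaTemplate,
    path: str | Path,
    **kwargs,
) -> int:
    """Write the junction library to FASTQ (constant placeholder qualities);
    returns the number of reads.  Depth 0 yields an empty file."""
    reads = simulate_junction_reads(truth, genome, template, **kwargs)
    with open(path, "w") as out:
        for read_id, seq in reads:
            out.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
    return len(reads)


def _barcode_weights(
    truth: pd.DataFrame, rng: np.random.Generator, jitter_sd: float
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-barcode DNA and RNA sampling weights.

    Every insertion contributes one genome copy (log10-normal jitter models
    copy-number / amplification bias); its RNA weight is copy x true level.
    Rows sharing a barcode (collisions, multi-inserts) pool their weights.
    """
    order: list[str] = []
    dna: dict[str, float] = {}
    rna: dict[str, float] = {}
    for row in truth.itertuples(index=False):
        copies = float(10 ** rng.normal(0.0, jitter_sd)) if jitter_sd else 1.0
        if row.barcode not in dna:
            order.append(row.barcode)
            dna[row.barcode] = 0.0
            rna[row.barcode] = 0.0
        dna[row.barcode] += copies
        rna[row.barcode] += copies * float(row.true_level)
    return (
        order,
        np.array([dna[b] for b in order]),
        np.array([rna[b] for b in order]),
    )


def simulate_count_libraries(
    truth: pd.DataFrame,
    template: TDnaTemplate,
    dna_path: str | Path,
    rna_path: str | Path,
    dna_depth: int = 1_000_000,
    rna_depth: int = 1_000_000,
    dna_weight_jitter_sd: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, int], dict[str, int]]:
    """Write DNA and RNA barcode-count FASTQ libraries.

    Read counts are multinomial over barcodes: DNA with near-equal weights
    (optional copy-number jitter), RNA with weights proportional to
    DNA weight x true level.  Reads are barcode-bearing amplicons of the
    vector template (border + barcode + LUC head).  Returns the sampled
    (dna, rna) count dicts for convenience.
    """
    if dna_depth < 0 or rna_depth < 0:
        raise ValueError("depths must be >= 0")
    rng = np.random.default_rng(seed)
    order, dna_w, rna_w = _barcode_weights(truth, rng, dna_weight_jitter_sd)

    def draw(depth: int, weights: np.ndarray) -> np.ndarray:
        if depth == 0 or weights.sum() == 0:
            return np.zeros(len(weights), dtype=int)
        return rng.multinomial(int(depth), weights / weights.sum())

    dna_counts = draw(dna_depth, dna_w)
    rna_counts = draw(rna_depth, rna_w)
    tail = template.luc_head[:20]
    for path, counts, tag in ((dna_path, dna_counts, "dna"), (rna_path, rna_counts, "rna")):
        with open(path, "w") as out:
            for j, barcode in enumerate(order):
                c = int(counts[j])
                if c == 0:
                    continue
                seq = template.border + barcode + tail
                out.write(f"@{tag}_bc{j}\n{seq}\n+\n{'I' * len(seq)}\n" * c)
    return (
        {b: int(c) for b, c in zip(order, dna_counts) if c},
        {b: int(c) for b, c in zip(order, rna_counts) if c},
    )
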