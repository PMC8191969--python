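"""On-disk formats.

FASTA and FASTQ for sequences and reads, GFF3 (1-based inclusive on disk)
for gene annotation, BED-like TSV (0-based half-open) for WT transcribed
regions, TSV for truth and records tables.  All coordinate conversions
between disk (GFF3) and in-memory (0-based half-open) conventions happen
here and nowhere else.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import gffutils
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from pyfaidx import Fasta

from .classify import Gene, WtRegion
from .synthetic import GenomeModel, WtExpressionModel

__all__ = [
    "write_fasta", "read_fasta",
    "write_gff3", "read_gff3_genes",
    "write_wt_regions", "read_wt_regions",
    "write_truth", "read_truth",
    "write_fastq", "read_fastq",
]

_WT_COLUMNS = ["chromosome", "start", "end", "strand", "fpkm"]


def write_fasta(path: str | Path, chromosomes: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as out:
        for name, seq in chromosomes:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i: i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    with Fasta(str(path), as_raw=True, build_index=True, rebuild=True) as fasta:
        return {name: str(fasta[name][:]).upper() for name in fasta.keys()}


def write_gff3(path: str | Path, genome: GenomeModel, source: str = "luctrap") -> None:
    """Gene features only; disk coordinates are 1-based inclusive."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for name, seq in genome.chromosomes:
            out.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for g in genome.genes:
            attrs = f"ID={g.gene_id};biotype={g.biotype}"
            out.write(
                f"{g.chromosome}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_gff3_genes(path: str | Path) -> list[Gene]:
    """Protein-coding gene features from a GFF3 file (to 0-based half-open)."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        biotype = (feat.attributes.get("biotype") or ["protein_coding"])[0]
        genes.append(
            Gene(feat.id, feat.seqid, feat.start - 1, feat.end, feat.strand, biotype)
        )
    return genes


def write_wt_regions(path: str | Path, model: WtExpressionModel) -> None:
    rows = [(r.chromosome, r.start, r.end, r.strand, r.fpkm) for r in model.regions]
    # %.17g guarantees FPKM survives the text round trip bit-exactly
    pd.DataFrame(rows, columns=_WT_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_wt_regions(path: str | Path) -> list[WtRegion]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        WtRegion(str(r.chromosome), int(r.start), int(r.end), str(r.strand), float(r.fpkm))
        for r in df.itertuples(index=False)
    ]


def write_truth(path: str | Path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]]) -> int:
    """Write (read_id, sequence) records with constant placeholder qualities."""
    n = 0
    with open(path, "w") as out:
        for read_id, seq in reads:
            out.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    with open(path) as handle:
        for title, seq, _ in FastqGeneralIterator(handle):
            yield title.split()[0], seq
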