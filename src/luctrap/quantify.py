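"""Barcode counting and relative transcription levels.

The DNA library measures how many genomes carry each barcoded reporter; the
RNA library measures how many transcripts each produced.  The per-line
relative transcription level is

    level = (rna_reads / rna_total) / (dna_reads / dna_total) * 10,000

after two read-count filters: barcodes with <= 5 reads in the DNA library
are omitted entirely (their denominator is unreliable), and RNA counts
<= 5 are set to zero before normalisation (background from index hopping
and PCR artefacts).  Totals are the number of reads with a successfully
extracted barcode in each library, taken before either filter.
"""

from __future__ import annotations

from collections import Counter
from os import PathLike
from typing import Iterable, Union

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .junctions import TDnaTemplate, revcomp

__all__ = ["count_barcodes", "count_barcodes_from_seqs", "compute_levels"]


def _extract_exact(seq: str, border: str, border_rc: str, blen: int) -> str | None:
    """Barcode from a count-library amplicon by exact border match.

    The amplicon layout is ``border + barcode + LUC head`` (vector
    orientation); the reverse-complement layout is also recognised.
    """
    i = seq.find(border)
    if i != -1:
        bc = seq[i + len(border): i + len(border) + blen]
        return bc if len(bc) == blen else None
    i = seq.find(border_rc)
    if i != -1 and i >= blen:
        return revcomp(seq[i - blen: i])
    return None


def count_barcodes_from_seqs(
    seqs: Iterable[str], template: TDnaTemplate
) -> tuple[Counter, int]:
    """Tally exact barcodes from an iterable of read sequences.

    Returns ``(counts, total)`` where ``total`` counts only reads with a
    successfully extracted barcode; order of reads is irrelevant.
    """
    border = template.border
    border_rc = revcomp(border)
    blen = template.barcode_len
    counts: Counter = Counter()
    for seq in seqs:
        bc = _extract_exact(seq.upper(), border, border_rc, blen)
        if bc is not None:
            counts[bc] += 1
    return counts, sum(counts.values())


def count_barcodes(
    fastq_path: Union[str, PathLike], template: TDnaTemplate
) -> tuple[Counter, int]:
    """Tally exact barcodes in a FASTQ count library (DNA or RNA)."""
    with open(fastq_path) as handle:
        return count_barcodes_from_seqs(
            (seq for _, seq, _ in FastqGeneralIterator(handle)), template
        )


def compute_levels(
    dna_counts: dict[str, int],
    dna_total: int,
    rna_counts: dict[str, int],
    rna_total: int,
    min_count: int = 5,
    scale: float = 10_000.0,
) -> pd.DataFrame:
    """Relative transcription level per barcode.

    Returns a DataFrame indexed by barcode with columns ``dna_reads``,
    ``rna_reads``, ``status`` ("ok" or "omitted") and ``level`` (NaN for
    omitted barcodes).  Barcodes with ``dna_reads <= min_count`` are
    omitted; ``rna_reads <= min_count`` is zeroed before normalisation;
    barcodes absent from the RNA library get level 0.
    """
    if rna_total == 0 and any(v > 0 for v in rna_counts.values()):
        raise ValueError("rna_total is 0 but RNA counts are non-zero")
    if any(v < 0 for v in dna_counts.values()) or any(v < 0 for v in rna_counts.values()):
        raise ValueError("negative barcode counts")
    barcodes = sorted(set(dna_counts) | set(rna_counts))
    rows = []
    for bc in barcodes:
        dna = int(dna_counts.get(bc, 0))
        rna = int(rna_counts.get(bc, 0))
        if dna <= min_count:
            rows.append((bc, dna, rna, "omitted", np.nan))
            continue
        rna_eff = 0 if rna <= min_count else rna
        level = (rna_eff / rna_total) / (dna / dna_total) * scale if rna_eff else 0.0
        rows.append((bc, dna, rna, "ok", level))
    table = pd.DataFrame(
        rows, columns=["barcode", "dna_reads", "rna_reads", "status", "level"]
    ).set_index("barcode")
    table.attrs["dna_total"] = dna_total
    table.attrs["rna_total"] = rna_total
    return table
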