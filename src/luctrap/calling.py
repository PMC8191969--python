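"""Locus-barcode pair calling.

Junction reads are aggregated per barcode into a support table (read count
per candidate locus, plus the total number of reads carrying the barcode,
mapped or not).  A precise locus-barcode pair is then called with three
criteria: (1) the locus has at least ``min_reads`` supporting reads;
(2) those reads account for at least ``min_dominance`` (default 60%) of all
reads carrying the barcode, PCR/sequencing artefacts included; and (3) a
barcode supported by two or more distinct candidate loci is excluded as a
multi-insert line or a barcode collision.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .junctions import FlankAlignment

__all__ = ["Locus", "PairSupport", "LineCall", "aggregate_pairs", "call_lines"]

#: (chromosome, rb_position, strand)
Locus = tuple[str, int, str]


@dataclass
class PairSupport:
    """Read support for one barcode: per-locus counts and the barcode total."""

    barcode: str
    loci: dict[Locus, int] = field(default_factory=dict)
    total: int = 0  # all reads carrying the barcode, unmapped ones included

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.loci.values()) or self.total < 0:
            raise ValueError("negative read counts")
        if sum(self.loci.values()) > self.total:
            raise ValueError("per-locus counts exceed barcode total")


@dataclass(frozen=True)
class LineCall:
    """Outcome of pair calling for one barcode."""

    barcode: str
    locus: Optional[Locus]
    status: str  # called | low_support | low_dominance | multi_insert | unmapped
    support_reads: int
    dominance: float

    def __post_init__(self) -> None:
        if (self.status == "called") != (self.locus is not None):
            raise ValueError("locus must be present iff status == 'called'")


def _merge_positions(pos_counts: dict[int, int], window: int) -> dict[int, int]:
    """Collapse positions differing by <= window into clusters; each cluster is
    keyed by its modal position (ties -> smallest) and carries the summed count."""
    merged: dict[int, int] = {}
    cluster: list[tuple[int, int]] = []

    def flush() -> None:
        total = sum(c for _, c in cluster)
        top = max(c for _, c in cluster)
        modal = min(p for p, c in cluster if c == top)
        merged[modal] = merged.get(modal, 0) + total

    for pos in sorted(pos_counts):
        if cluster and pos - cluster[-1][0] > window:
            flush()
            cluster = []
        cluster.append((pos, pos_counts[pos]))
    if cluster:
        flush()
    return merged


def aggregate_pairs(
    read_alignments: Iterable[tuple[str, Optional[FlankAlignment]]],
    merge_window: int = 5,
) -> list[PairSupport]:
    """Group per-read (barcode, alignment-or-None) pairs into support tables.

    Loci on the same chromosome and strand whose junction positions differ
    by at most ``merge_window`` bases are collapsed (counts summed, modal
    position kept) to absorb small junction-trimming jitter.  Reads whose
    flank did not map contribute to the barcode total only.
    """
    if merge_window < 0:
        raise ValueError("merge_window must be >= 0")
    totals: Counter[str] = Counter()
    by_key: dict[tuple[str, str, str], Counter[int]] = defaultdict(Counter)
    for barcode, aln in read_alignments:
        totals[barcode] += 1
        if aln is not None:
            by_key[(barcode, aln.chromosome, aln.strand)][aln.position] += 1
    supports: dict[str, PairSupport] = {
        bc: PairSupport(bc, {}, total) for bc, total in totals.items()
    }
    for (barcode, chrom, strand), pos_counts in by_key.items():
        for pos, count in _merge_positions(dict(pos_counts), merge_window).items():
            supports[barcode].loci[(chrom, pos, strand)] = count
    return [supports[bc] for bc in sorted(supports)]


def call_lines(
    supports: Iterable[PairSupport],
    min_reads: int = 2,
    min_dominance: float = 0.6,
) -> list[LineCall]:
    """Apply the three pair-calling criteria to each barcode's support table.

    Candidate loci are those with at least ``min_reads`` reads.  Exactly one
    candidate whose reads make up >= ``min_dominance`` of every read carrying
    the barcode is called; one candidate below that dominance is
    ``low_dominance``; two or more candidates are excluded as
    ``multi_insert``; no candidate is ``low_support``, or ``unmapped`` when
    no read of the barcode mapped anywhere.

    Raises ``ValueError`` on duplicate barcodes (the aggregation contract
    guarantees one support table per barcode).
    """
    calls: list[LineCall] = []
    seen: set[str] = set()
    for sup in supports:
        if sup.barcode in seen:
            raise ValueError(f"duplicate support table for barcode {sup.barcode}")
        seen.add(sup.barcode)
        candidates = {loc: c for loc, c in sup.loci.items() if c >= min_reads}
        if len(candidates) >= 2:
            calls.append(LineCall(sup.barcode, None, "multi_insert", 0, 0.0))
            continue
        if not candidates:
            status = "unmapped" if sum(sup.loci.values()) == 0 else "low_support"
            calls.append(LineCall(sup.barcode, None, status, 0, 0.0))
            continue
        (locus, count), = candidates.items()
        dominance = count / sup.total if sup.total else 0.0
        if dominance >= min_dominance:
            calls.append(LineCall(sup.barcode, locus, "called", count, dominance))
        else:
            calls.append(LineCall(sup.barcode, None, "low_dominance", count, dominance))
    return calls
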