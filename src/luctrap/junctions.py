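"""T-DNA junction read processing.

A promoter-trap junction read runs from inside the promoterless *LUC* ORF
outward across the 12-nt line barcode and the T-DNA right-border (RB)
sequence into flanking host genomic DNA.  On the strand the read is
sequenced (the reverse complement of the strand on which the LUC CDS reads
5'->3') a clean read is laid out as::

    revcomp(LUC head) + revcomp(barcode) + revcomp(border) + genomic flank

This module locates the border in either read orientation with a bounded
number of substitutions, slices out barcode and flank, and maps the flank
back to the reference with a k-mer seed-and-verify search allowing up to
three mismatches (substitution-only, mirroring bowtie ``-v`` semantics).

Coordinate convention
---------------------
``position`` of a :class:`FlankAlignment` is the 0-based reference
coordinate of the genomic base immediately adjacent to the RB border (the
first base of the flank as it appears in the read).  ``strand`` is the
reference strand on which the LUC CDS reads 5'->3'.  A flank matching the
reference forward strand therefore implies an insert on '-', with the
junction at the leftmost aligned base; a flank matching in reverse
complement implies '+', with the junction at the rightmost aligned base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "DEFAULT_BORDER",
    "DEFAULT_LUC_HEAD",
    "TDnaTemplate",
    "ExtractedJunction",
    "FlankAlignment",
    "MapResult",
    "GenomeIndex",
    "revcomp",
    "extract_barcode_and_flank",
    "build_genome_index",
    "map_flank",
]

# Published vector context around the barcode slot:
# 5'-<border, lowercase in the vector map><12 x N barcode><LUC 5' fraction>-3'
DEFAULT_BORDER = "TCAAGGCCTCGACGTTATCAGCTTACAG"
DEFAULT_LUC_HEAD = "ATGGAAGACGCCAAAAACATAAAGAAAGGCCCGGCGCCATTCTATCCTCTAGAG"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ACGT = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class TDnaTemplate:
    """The T-DNA anchor: border sequence, barcode slot width and LUC 5' end."""

    border: str = DEFAULT_BORDER
    barcode_len: int = 12
    luc_head: str = DEFAULT_LUC_HEAD

    def __post_init__(self) -> None:
        object.__setattr__(self, "border", self.border.upper())
        object.__setattr__(self, "luc_head", self.luc_head.upper())
        for name in ("border", "luc_head"):
            value = getattr(self, name)
            if not value or set(value) - _ACGT:
                raise ValueError(f"{name} must be non-empty A/C/G/T, got {value!r}")
        if self.barcode_len <= 0:
            raise ValueError("barcode_len must be positive")


@dataclass(frozen=True)
class ExtractedJunction:
    """Barcode and genomic-side flank sliced out of one junction read."""

    read_id: str
    barcode: str
    flank: str
    orientation: str  # "forward": read already in canonical layout; "reverse": revcomp was

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass(frozen=True)
class FlankAlignment:
    """A unique best-scoring genomic placement of a junction flank."""

    chromosome: str
    position: int  # RB-junction base, 0-based (see module docstring)
    strand: str  # strand of the LUC CDS
    mismatches: int
    unique: bool
    start: int = field(default=-1)  # leftmost base of the aligned interval
    end: int = field(default=-1)  # exclusive right end of the aligned interval


class MapResult(NamedTuple):
    alignment: FlankAlignment | None
    reason: str  # "unique" | "multi_mapped" | "unmapped" | "low_quality" | "too_short"


def _approx_occurrences(seq: str, pattern: str, max_mismatch: int) -> list[int]:
    """All start positions where ``pattern`` matches ``seq`` with <= max_mismatch
    substitutions."""
    n, m = len(seq), len(pattern)
    if n < m:
        return []
    if max_mismatch == 0:
        hits, start = [], seq.find(pattern)
        while start != -1:
            hits.append(start)
            start = seq.find(pattern, start + 1)
        return hits
    windows = np.lib.stride_tricks.sliding_window_view(_as_bytes(seq), m)
    mism = (windows != _as_bytes(pattern)).sum(axis=1)
    return np.nonzero(mism <= max_mismatch)[0].tolist()


def extract_barcode_and_flank(
    read_id: str,
    seq: str,
    template: TDnaTemplate,
    max_template_mismatch: int = 2,
    min_flank_len: int = 20,
) -> tuple[ExtractedJunction | None, str]:
    """Locate the border in either orientation of ``seq`` and slice out the
    barcode and the genomic-side flank.

    Returns ``(junction, "ok")`` on success, else ``(None, reason)`` with
    reason one of ``no_template`` (border absent at the mismatch cap),
    ``ambiguous_template`` (more than one border occurrence), or
    ``truncated`` (barcode slot or flank incomplete).
    """
    seq = seq.upper()
    anchor = revcomp(template.border)  # border as it appears in the canonical layout
    candidates: list[tuple[str, int]] = []
    for orientation, oriented in (("forward", seq), ("reverse", revcomp(seq))):
        for pos in _approx_occurrences(oriented, anchor, max_template_mismatch):
            candidates.append((orientation, pos))
    if not candidates:
        return None, "no_template"
    if len(candidates) > 1:
        return None, "ambiguous_template"
    orientation, pos = candidates[0]
    oriented = seq if orientation == "forward" else revcomp(seq)
    if pos < template.barcode_len:
        return None, "truncated"
    flank = oriented[pos + len(template.border):]
    if len(flank) < min_flank_len:
        return None, "truncated"
    # In the canonical layout the 12 nt 5' of the border anchor are
    # revcomp(barcode); undo that to report the barcode as written in the vector.
    barcode = revcomp(oriented[pos - template.barcode_len: pos])
    return ExtractedJunction(read_id, barcode, flank, orientation), "ok"


class GenomeIndex:
    """Exact k-mer positional index over a set of chromosomes.

    Supports lookup of every exact occurrence of a k-mer on both strands;
    minus-strand hits are reported at the forward-strand coordinate of the
    occurrence of the reverse complement.
    """

    def __init__(self, chromosomes: dict[str, str], k: int = 10):
        if k <= 0:
            raise ValueError("k must be positive")
        if not chromosomes:
            raise ValueError("empty genome")
        if k > max(len(s) for s in chromosomes.values()):
            raise ValueError(f"k={k} exceeds the longest chromosome")
        self.k = k
        self.names: list[str] = list(chromosomes)
        self.seqs: dict[str, str] = {n: s.upper() for n, s in chromosomes.items()}
        self.arrays: dict[str, np.ndarray] = {n: _as_bytes(s) for n, s in self.seqs.items()}
        index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.seqs.items():
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i: i + k], []).append((name, i))
        self._index = index

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """All exact hits of ``kmer`` as (chromosome, forward-strand pos, strand)."""
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        kmer = kmer.upper()
        out = [(c, p, "+") for c, p in self._index.get(kmer, ())]
        rc = revcomp(kmer)
        out += [(c, p, "-") for c, p in self._index.get(rc, ())]
        return out

    def _forward_hits(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def build_genome_index(chromosomes: dict[str, str], k: int = 10) -> GenomeIndex:
    """Construct a :class:`GenomeIndex` (thin functional wrapper)."""
    return GenomeIndex(chromosomes, k=k)


def _verify(arr: np.ndarray, query: np.ndarray, start: int, max_mismatches: int) -> int:
    """Hamming distance of ``query`` vs ``arr[start:start+len]``, or -1 when the
    window is out of bounds or exceeds the cap."""
    end = start + query.size
    if start < 0 or end > arr.size:
        return -1
    d = int((arr[start:end] != query).sum())
    return d if d <= max_mismatches else -1


def _scan_all(index: GenomeIndex, query: np.ndarray, max_mismatches: int) -> list[tuple[str, int, int]]:
    """Brute-force all placements of ``query`` (forward orientation) on every
    chromosome; used when a flank is too short for pigeonhole seeding."""
    hits = []
    m = query.size
    for name, arr in index.arrays.items():
        if arr.size < m:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, m)
        mism = (windows != query).sum(axis=1)
        for pos in np.nonzero(mism <= max_mismatches)[0]:
            hits.append((name, int(pos), int(mism[pos])))
    return hits


def _seeded_hits(index: GenomeIndex, flank: str, max_mismatches: int) -> list[tuple[str, int, int]]:
    """All full-length placements of ``flank`` (forward orientation, Hamming
    distance <= max_mismatches) found by non-overlapping k-mer seeding.

    With ``len(flank) >= (max_mismatches + 1) * k`` the pigeonhole principle
    guarantees completeness: at least one seed is mismatch-free.
    """
    k = index.k
    query = _as_bytes(flank)
    n_seeds = len(flank) // k
    if n_seeds < max_mismatches + 1:
        return _scan_all(index, query, max_mismatches)
    seen: set[tuple[str, int]] = set()
    hits: list[tuple[str, int, int]] = []
    for s in range(n_seeds):
        offset = s * k
        for chrom, pos in index._forward_hits(flank[offset: offset + k]):
            start = pos - offset
            key = (chrom, start)
            if key in seen:
                continue
            seen.add(key)
            d = _verify(index.arrays[chrom], query, start, max_mismatches)
            if d >= 0:
                hits.append((chrom, start, d))
    return hits


def map_flank(
    flank: str,
    index: GenomeIndex,
    max_mismatches: int = 3,
    min_flank_len: int = 20,
    max_n: int = 2,
) -> MapResult:
    """Place a junction flank on the reference, allowing substitutions only.

    Searches both orientations for every location within ``max_mismatches``
    over the full flank length.  A single best-distance location is returned
    as a unique :class:`FlankAlignment`; two or more tied best locations
    yield ``multi_mapped`` and no alignment.  The reported ``position`` is
    the RB-junction base and ``strand`` the LUC-CDS strand (see module
    docstring for the conversion).
    """
    flank = flank.upper()
    if len(flank) < min_flank_len:
        return MapResult(None, "too_short")
    if sum(c not in _ACGT for c in flank) > max_n:
        return MapResult(None, "low_quality")
    L = len(flank)
    placements: list[tuple[str, int, int, str]] = []  # chrom, start, dist, route
    for route, oriented in (("fwd", flank), ("rc", revcomp(flank))):
        for chrom, start, d in _seeded_hits(index, oriented, max_mismatches):
            placements.append((chrom, start, d, route))
    if not placements:
        return MapResult(None, "unmapped")
    best = min(d for _, _, d, _ in placements)
    top = [p for p in placements if p[2] == best]
    if len(top) > 1:
        return MapResult(None, "multi_mapped")
    chrom, start, d, route = top[0]
    if route == "fwd":
        strand, position = "-", start
    else:
        strand, position = "+", start + L - 1
    return MapResult(
        FlankAlignment(chrom, position, strand, d, True, start=start, end=start + L),
        "unique",
    )


def extract_junctions(
    reads: Iterable[tuple[str, str]],
    template: TDnaTemplate,
    max_template_mismatch: int = 2,
    min_flank_len: int = 20,
) -> tuple[list[ExtractedJunction], dict[str, int]]:
    """Extract barcode/flank from an iterable of (read_id, sequence).

    Returns the successful extractions and a tally of outcomes by reason.
    """
    out: list[ExtractedJunction] = []
    tally: dict[str, int] = {}
    for read_id, seq in reads:
        junction, reason = extract_barcode_and_flank(
            read_id, seq, template, max_template_mismatch, min_flank_len
        )
        tally[reason] = tally.get(reason, 0) + 1
        if junction is not None:
            out.append(junction)
    return out, tally
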