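"""Insertion-site classification.

Two independent labels are attached to every called line:

* **insertion type** — where the reporter landed relative to annotated
  protein-coding genes, strand-aware: inside a gene on the same strand as
  the LUC CDS (``genic_sense``), inside a gene on the opposite strand only
  (``genic_as``), or outside all genes (``intergenic``).  The gene span is
  the full annotated gene feature, introns and UTRs included, and the test
  point is the single RB-junction base.

* **WT-overlap type** — the 2x2 combination of reporter transcription
  (level > 0) with wild-type transcription at the locus: type ``i``
  (both transcribed), ``ii`` (WT only), ``iii`` (reporter only — de novo
  activation), ``iv`` (neither).  WT overlap is strand-agnostic by default;
  a switch restricts it to same-strand regions.  FPKM of overlapping WT
  isoforms is summed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from intervaltree import IntervalTree

__all__ = [
    "Gene",
    "WtRegion",
    "GeneAnnotation",
    "WtTranscriptome",
    "classify_insertion_type",
    "classify_wt_overlap",
    "INSERTION_TYPES",
    "WT_TYPES",
]

INSERTION_TYPES = ("genic_sense", "genic_as", "intergenic")
WT_TYPES = ("i", "ii", "iii", "iv")


@dataclass(frozen=True)
class Gene:
    """A gene feature, 0-based half-open."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"


@dataclass(frozen=True)
class WtRegion:
    """A wild-type transcribed region with its expression level (FPKM)."""

    chromosome: str
    start: int
    end: int
    strand: str
    fpkm: float

    def __post_init__(self) -> None:
        if self.fpkm <= 0:
            raise ValueError("WT transcribed regions must carry fpkm > 0")
        if self.end <= self.start:
            raise ValueError("empty region interval")


class GeneAnnotation:
    """Interval lookup over protein-coding gene spans."""

    def __init__(self, genes: Iterable[Gene], chromosomes: Iterable[str] | None = None):
        self.genes = [g for g in genes if g.biotype == "protein_coding"]
        self._trees: dict[str, IntervalTree] = {}
        for name in chromosomes or ():
            self._trees[name] = IntervalTree()
        for g in self.genes:
            self._trees.setdefault(g.chromosome, IntervalTree())[g.start: g.end] = g

    def overlapping(self, chromosome: str, position: int) -> list[Gene]:
        if chromosome not in self._trees:
            raise KeyError(f"unknown chromosome {chromosome!r}")
        return [iv.data for iv in self._trees[chromosome][position]]

    def classify(self, chromosome: str, position: int, strand: str) -> str:
        genes = self.overlapping(chromosome, position)
        if not genes:
            return "intergenic"
        return "genic_sense" if any(g.strand == strand for g in genes) else "genic_as"


class WtTranscriptome:
    """Interval lookup over WT transcribed regions with summed FPKM."""

    def __init__(self, regions: Iterable[WtRegion]):
        self.regions = list(regions)
        self._trees: dict[str, IntervalTree] = {}
        for r in self.regions:
            self._trees.setdefault(r.chromosome, IntervalTree())[r.start: r.end] = r

    def overlapping(
        self, chromosome: str, position: int, strand: Optional[str] = None
    ) -> list[WtRegion]:
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        hits = [iv.data for iv in tree[position]]
        if strand is not None:
            hits = [r for r in hits if r.strand == strand]
        return hits


def classify_insertion_type(
    chromosome: str, position: int, strand: str, annotation: GeneAnnotation
) -> str:
    """Genic sense / genic antisense / intergenic for one RB-junction base."""
    return annotation.classify(chromosome, position, strand)


def classify_wt_overlap(
    chromosome: str,
    position: int,
    level: float,
    wt: WtTranscriptome,
    strand: Optional[str] = None,
    strand_aware: bool = False,
) -> tuple[str, Optional[float]]:
    """WT-overlap type (i-iv) and summed FPKM at the junction base.

    ``strand_aware=True`` restricts the WT-transcribed test to regions on
    ``strand``; the default treats any overlapping transcription as
    WT-transcribed.
    """
    hits = wt.overlapping(chromosome, position, strand if strand_aware else None)
    wt_transcribed = bool(hits)
    fpkm = sum(r.fpkm for r in hits) if hits else None
    luc_transcribed = level > 0
    if wt_transcribed:
        return ("i" if luc_transcribed else "ii"), fpkm
    return ("iii" if luc_transcribed else "iv"), fpkm
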