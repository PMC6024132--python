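"""Positional class codes, TE overlap and catalog-level descriptive statistics.

Class codes follow the intergenic/sense/antisense trichotomy used for
assembled lncRNA candidates: ``o`` for >= 1 bp of exonic overlap with a
known transcript on the same strand, ``x`` for exonic overlap only on the
opposite strand, ``u`` otherwise.  Overlap is exon-level by default (a
candidate inside an intron of a known gene is ``u``); span-level overlap is
available behind ``span_level=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

from hexalnc.models import GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

VENN_REGIONS = ("A_only", "BC_only", "ABC_only", "A_BC", "A_ABC", "BC_ABC", "A_BC_ABC")


class KnownExonIndex:
    """Interval index over the exons (or spans) of known transcripts."""

    def __init__(self, known: Iterable[TranscriptModel], span_level: bool = False):
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        self.span_level = span_level
        for t in known:
            pieces = [t.span] if span_level else t.exons
            for e in pieces:
                self._trees.setdefault((e.chrom, e.strand), IntervalTree()).addi(e.start, e.end)
        self.chroms = {c for c, _ in self._trees}

    def overlaps(self, interval: GenomicInterval, strand: str) -> bool:
        tree = self._trees.get((interval.chrom, strand))
        return bool(tree and tree.overlap(interval.start, interval.end))


def assign_class_code(
    candidate: TranscriptModel,
    known: Iterable[TranscriptModel] | KnownExonIndex,
    span_level: bool = False,
) -> str:
    """Classify a candidate relative to known transcripts: o > x > u.

    A candidate on a chromosome absent from the known annotation is ``u``
    (logged, not an error: novel scaffolds are expected in assemblies).
    """
    index = known if isinstance(known, KnownExonIndex) else KnownExonIndex(known, span_level)
    pieces = [candidate.span] if index.span_level else candidate.exons
    if candidate.chrom not in index.chroms:
        logger.info("candidate %s on chromosome %s absent from known annotation: classed u",
                    candidate.transcript_id, candidate.chrom)
        return "u"
    same = opposite = False
    other_strand = "-" if candidate.strand == "+" else "+"
    for e in pieces:
        if index.overlaps(e, candidate.strand):
            same = True
            break
        if index.overlaps(e, other_strand):
            opposite = True
    if same:
        return "o"
    if opposite:
        return "x"
    return "u"


class TransposonIndex:
    """Strandless interval index over transposon-element intervals."""

    def __init__(self, tes: Iterable[GenomicInterval]):
        self._trees: Dict[str, IntervalTree] = {}
        for te in tes:
            self._trees.setdefault(te.chrom, IntervalTree()).addi(te.start, te.end)

    def overlaps(self, t: TranscriptModel) -> bool:
        tree = self._trees.get(t.chrom)
        if tree is None:
            return False
        return any(tree.overlap(e.start, e.end) for e in t.exons)


def overlaps_transposon(
    t: TranscriptModel, tes: Iterable[GenomicInterval] | TransposonIndex
) -> bool:
    """True iff >= 1 bp of any exon intersects any TE interval (strandless)."""
    index = tes if isinstance(tes, TransposonIndex) else TransposonIndex(tes)
    return index.overlaps(t)


@dataclass
class CatalogStats:
    length_fraction_200_1000: float
    length_fraction_gt_1000: float
    exon_fraction_le_1: float
    te_overlap_count: int
    presence_partition: Dict[str, int]

    @property
    def total_expressed(self) -> int:
        return sum(self.presence_partition.values())


def presence_partition(present: Mapping[str, Sequence[str]]) -> Dict[str, int]:
    """Counts for the 7 regions of the 3-set Venn over samples A/BC/ABC."""
    a, bc, abc = (set(present[s]) for s in ("A", "BC", "ABC"))
    return {
        "A_only": len(a - bc - abc),
        "BC_only": len(bc - a - abc),
        "ABC_only": len(abc - a - bc),
        "A_BC": len((a & bc) - abc),
        "A_ABC": len((a & abc) - bc),
        "BC_ABC": len((bc & abc) - a),
        "A_BC_ABC": len(a & bc & abc),
    }


def catalog_statistics(
    transcripts: Sequence[TranscriptModel],
    fpkm: pd.DataFrame,
    presence_threshold: float = 0.0,
    tes: Optional[Iterable[GenomicInterval] | TransposonIndex] = None,
) -> CatalogStats:
    """Length/exon distributions, TE overlap count and presence Venn.

    ``fpkm`` is indexed by transcript_id with columns A/BC/ABC; presence in
    a sample means FPKM strictly above ``presence_threshold`` (default 0:
    the Venn reflects detection, not abundance).  Transcripts shorter than
    200 nt violate the post-filter catalog invariant and raise.
    """
    if not transcripts:
        raise ValueError("empty catalog")
    lengths = [t.length for t in transcripts]
    short = [t.transcript_id for t in transcripts if t.length < 200]
    if short:
        raise ValueError(f"post-filter catalog contains transcripts < 200 nt: {short[:5]}")
    n = len(transcripts)
    n_mid = sum(1 for L in lengths if 200 <= L <= 1000)
    te_index = (
        tes if isinstance(tes, TransposonIndex) else TransposonIndex(tes) if tes is not None else None
    )
    te_count = sum(1 for t in transcripts if te_index.overlaps(t)) if te_index else 0

    ids = [t.transcript_id for t in transcripts]
    sub = fpkm.loc[fpkm.index.intersection(ids)]
    present = {s: sub.index[sub[s] > presence_threshold].tolist() for s in ("A", "BC", "ABC")}
    return CatalogStats(
        length_fraction_200_1000=n_mid / n,
        length_fraction_gt_1000=(n - n_mid) / n,
        exon_fraction_le_1=sum(1 for t in transcripts if t.exon_count <= 1) / n,
        te_overlap_count=te_count,
        presence_partition=presence_partition(present),
    )
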