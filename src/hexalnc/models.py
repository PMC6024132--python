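"""Genomic data types: intervals and transcript models.

Coordinates are 0-based, half-open throughout the package; GTF I/O converts
to/from the 1-based inclusive convention at the file boundary
(:mod:`hexalnc.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>= 1 bp intersection on the same chromosome (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """A genomic transcript: ordered exons on one chromosome/strand.

    ``length`` is the sum of exon lengths (the mature transcript length);
    ``sequence`` when present is the spliced, strand-oriented sequence and
    must match ``length``.  ``biotype`` distinguishes annotated coding
    transcripts (``coding_known``) from assembly candidates and confirmed
    lncRNAs; ``class_code`` is the positional class relative to known genes
    (u = intergenic, o = sense exonic overlap, x = antisense exonic
    overlap).
    """

    transcript_id: str
    exons: Sequence[GenomicInterval]
    gene_id: Optional[str] = None
    sequence: Optional[str] = None
    biotype: str = "candidate"  # coding_known | candidate | lncRNA
    class_code: Optional[str] = None  # u | o | x | known
    read_coverage: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"{self.transcript_id}: exons span multiple chromosomes/strands")
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        self.exons = tuple(exons)
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} != exon total {self.length}"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> GenomicInterval:
        """Genomic footprint from the first exon start to the last exon end."""
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)
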