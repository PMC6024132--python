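"""Readers and writers for the standard formats the pipeline consumes.

GTF is parsed with :mod:`gffutils`; FASTA with Biopython; BED/TSV with
pandas.  Internal coordinates are 0-based half-open, GTF is written/read as
1-based inclusive, BED as 0-based half-open (the formats' own conventions).
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from hexalnc.models import GenomicInterval, TranscriptModel

_GTF_SOURCE = "hexalnc"


def _canonical_order(transcripts: Iterable[TranscriptModel]) -> List[TranscriptModel]:
    return sorted(transcripts, key=lambda t: (t.chrom, t.span.start, t.span.end, t.transcript_id))


def write_gtf(transcripts: Iterable[TranscriptModel], path: str) -> None:
    """Write transcript + exon features; attributes carry the model fields.

    Transcripts are emitted in canonical (chrom, start, id) order so that
    identical inputs always produce byte-identical files.
    """
    lines = []
    for t in _canonical_order(transcripts):
        attrs = [f'gene_id "{t.gene_id or t.transcript_id}"', f'transcript_id "{t.transcript_id}"']
        attrs.append(f'biotype "{t.biotype}"')
        if t.class_code is not None:
            attrs.append(f'class_code "{t.class_code}"')
        if t.read_coverage is not None:
            attrs.append(f'cov "{t.read_coverage!r}"')
        attr_s = "; ".join(attrs) + ";"
        span = t.span
        lines.append(
            "\t".join(
                [t.chrom, _GTF_SOURCE, "transcript", str(span.start + 1), str(span.end), ".", t.strand, ".", attr_s]
            )
        )
        for e in t.exons:
            lines.append(
                "\t".join(
                    [t.chrom, _GTF_SOURCE, "exon", str(e.start + 1), str(e.end), ".", t.strand, ".", attr_s]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_gtf(path: str, sequences: Optional[Dict[str, str]] = None) -> List[TranscriptModel]:
    """Read transcript models from a GTF file.

    ``sequences`` (transcript_id -> spliced sequence), e.g. from
    :func:`read_fasta`, is attached when given.
    """
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    out: List[TranscriptModel] = []
    for feat in db.features_of_type("transcript"):
        tid = feat.attributes["transcript_id"][0]
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
            for e in db.children(feat, featuretype="exon")
        ]
        cov = feat.attributes.get("cov")
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=feat.attributes.get("gene_id", [None])[0],
                exons=exons,
                sequence=(sequences or {}).get(tid),
                biotype=feat.attributes.get("biotype", ["candidate"])[0],
                class_code=feat.attributes.get("class_code", [None])[0],
                read_coverage=float(cov[0]) if cov else None,
            )
        )
    return _canonical_order(out)


def write_fasta(records: Dict[str, str], path: str, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in sorted(records.items())]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_bed(intervals: Sequence[GenomicInterval], path: str, names: Optional[Sequence[str]] = None) -> None:
    rows = []
    for i, iv in enumerate(intervals):
        name = names[i] if names is not None else f"feature_{i}"
        rows.append((iv.chrom, iv.start, iv.end, name))
    rows.sort()
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path: str) -> List[GenomicInterval]:
    if os.path.getsize(path) == 0:
        return []
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [GenomicInterval(str(r[0]), int(r[1]), int(r[2])) for r in df.itertuples(index=False)]


def write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
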