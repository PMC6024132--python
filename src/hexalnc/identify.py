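"""Three-criterion lncRNA identification with a pluggable coding-potential scorer.

The three filters, applied in the fixed order length -> coverage -> coding:

1. transcript length >= 200 nt (inclusive boundary);
2. read coverage >= 3 (mean per-base depth; "less than 3 excluded");
3. noncoding by BOTH scores: cpc-like < -1 AND cnci-like < 0.

The coding-potential stage accepts either a precomputed score table (e.g.
real CPC/CNCI output) or the builtin heuristic, which shares the threshold
semantics of those tools: ``cpc_like = -(1 - 2*f) * c`` where ``f`` is the
longest-ORF fraction of the transcript and ``c`` a calibration constant,
and ``cnci_like`` a codon-usage log-odds over the longest ORF (positive
for ORFs drawn from the biased "coding" codon usage, negative in
expectation for random sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from hexalnc.models import TranscriptModel
from hexalnc.seqs import DNA_ALPHABET, STOP_CODONS, to_dna, validate_alphabet

DEFAULT_MIN_LENGTH = 200
DEFAULT_MIN_COVERAGE = 3.0
DEFAULT_CPC_THRESHOLD = -1.0
DEFAULT_CNCI_THRESHOLD = 0.0
CPC_CALIBRATION = 2.0
MIN_ORF_NT = 30  # ATG..stop spans below this are ignored by the scorer

# Codon-usage model for the cnci-like log-odds: "coding-preferred" codons
# (third base G or C, a common plant bias proxy) get 3x weight.  Stops are
# never drawn when simulating ORFs but contribute to the normalization of
# the uniform background like any other codon.
_BASES = "ACGT"
ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]
_weights = np.array([3.0 if c[2] in "GC" else 1.0 for c in SENSE_CODONS])
CODING_CODON_P = dict(zip(SENSE_CODONS, _weights / _weights.sum()))
_UNIFORM_P = 1.0 / len(SENSE_CODONS)
CODON_LOG_ODDS = {c: float(np.log2(p / _UNIFORM_P)) for c, p in CODING_CODON_P.items()}


@dataclass
class CodingPotentialScore:
    transcript_id: str
    cpc_like: float
    cnci_like: float
    source: str = "builtin_heuristic"  # or external_table

    def is_noncoding(
        self,
        cpc_threshold: float = DEFAULT_CPC_THRESHOLD,
        cnci_threshold: float = DEFAULT_CNCI_THRESHOLD,
    ) -> bool:
        return self.cpc_like < cpc_threshold and self.cnci_like < cnci_threshold


@dataclass
class FilterReport:
    input_count: int = 0
    removed_short: int = 0
    removed_low_coverage: int = 0
    removed_coding: int = 0
    retained_ids: List[str] = field(default_factory=list)

    def validate(self) -> None:
        total = self.removed_short + self.removed_low_coverage + self.removed_coding
        if self.input_count != len(self.retained_ids) + total:
            raise AssertionError("FilterReport counts do not partition the input")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["input", "removed_short", "removed_low_coverage", "removed_coding", "retained"],
                "count": [
                    self.input_count,
                    self.removed_short,
                    self.removed_low_coverage,
                    self.removed_coding,
                    len(self.retained_ids),
                ],
            }
        )


def longest_orf(seq: str) -> Tuple[int, int]:
    """Longest ATG..stop open reading frame on the given strand.

    Returns ``(start, length_nt)`` (length includes the stop codon), or
    ``(-1, 0)`` if no ORF of at least MIN_ORF_NT exists.  Only the
    transcript's own strand is scanned: assembled transcripts are oriented.
    """
    s = to_dna(seq)
    n = len(s)
    best = (-1, 0)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = s[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                length = i + 3 - start
                if length >= MIN_ORF_NT and length > best[1]:
                    best = (start, length)
                start = None
    return best


def score_coding_potential(t: TranscriptModel) -> CodingPotentialScore:
    """Builtin heuristic scorer (see module docstring for the contract)."""
    if t.sequence is None:
        raise ValueError(f"{t.transcript_id}: sequence required for the builtin scorer")
    seq = to_dna(t.sequence)
    validate_alphabet(seq, DNA_ALPHABET, f"{t.transcript_id} sequence")
    start, orf_len = longest_orf(seq)
    orf_fraction = orf_len / len(seq) if len(seq) else 0.0
    cpc_like = -(1.0 - 2.0 * orf_fraction) * CPC_CALIBRATION
    if orf_len == 0:
        cnci_like = -1.0
    else:
        codons = [seq[i : i + 3] for i in range(start, start + orf_len - 3, 3)]
        cnci_like = float(sum(CODON_LOG_ODDS.get(c, 0.0) for c in codons))
    return CodingPotentialScore(t.transcript_id, cpc_like, cnci_like)


def read_score_table(path_or_df) -> Dict[str, CodingPotentialScore]:
    """External-score pathway: TSV columns transcript_id, cpc, cnci."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.transcript_id)] = CodingPotentialScore(
            str(row.transcript_id), float(row.cpc), float(row.cnci), source="external_table"
        )
    return out


def length_filter(t: TranscriptModel, min_length: int = DEFAULT_MIN_LENGTH) -> bool:
    """Keep iff length >= min_length (200 nt boundary is inclusive)."""
    return t.length >= min_length


def coverage_filter(t: TranscriptModel, min_coverage: float = DEFAULT_MIN_COVERAGE) -> bool:
    """Keep iff read coverage >= min_coverage (coverage exactly 3 is kept)."""
    if t.read_coverage is None:
        raise ValueError(f"{t.transcript_id}: read_coverage missing")
    return t.read_coverage >= min_coverage


def identify_lncrnas(
    candidates: Sequence[TranscriptModel],
    scores: Optional[Dict[str, CodingPotentialScore]] = None,
    min_length: int = DEFAULT_MIN_LENGTH,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    cpc_threshold: float = DEFAULT_CPC_THRESHOLD,
    cnci_threshold: float = DEFAULT_CNCI_THRESHOLD,
) -> Tuple[List[TranscriptModel], FilterReport]:
    """Apply the three filters; a transcript is attributed to the first one it fails.

    ``scores`` maps transcript_id -> CodingPotentialScore (external table);
    candidates absent from it are scored with the builtin heuristic.
    """
    ids = [t.transcript_id for t in candidates]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicated transcript_id(s): {dupes[:5]}")
    report = FilterReport(input_count=len(candidates))
    retained: List[TranscriptModel] = []
    for t in candidates:
        if not length_filter(t, min_length):
            report.removed_short += 1
            continue
        if not coverage_filter(t, min_coverage):
            report.removed_low_coverage += 1
            continue
        score = (scores or {}).get(t.transcript_id) or score_coding_potential(t)
        if not score.is_noncoding(cpc_threshold, cnci_threshold):
            report.removed_coding += 1
            continue
        kept = TranscriptModel(
            transcript_id=t.transcript_id,
            exons=t.exons,
            gene_id=t.gene_id,
            sequence=t.sequence,
            biotype="lncRNA",
            class_code=t.class_code,
            read_coverage=t.read_coverage,
        )
        retained.append(kept)
        report.retained_ids.append(t.transcript_id)
    report.validate()
    return retained, report
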