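"""Small sequence helpers shared across modules.

All genomic sequences are handled in the DNA alphabet internally; the miRNA
interaction layer converts to RNA on ingest (see :mod:`hexalnc.mirna`).
"""

from __future__ import annotations

_DNA_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_RNA_COMPLEMENT = str.maketrans("ACGUacgu", "UGCAugca")

DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")

STOP_CODONS = ("TAA", "TAG", "TGA")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def validate_alphabet(seq: str, alphabet: frozenset, what: str = "sequence") -> None:
    bad = set(seq.upper()) - alphabet
    if bad:
        raise ValueError(f"{what} contains non-{''.join(sorted(alphabet))} characters: {sorted(bad)}")
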