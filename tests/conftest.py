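"""Shared fixtures: one default synthetic bundle per session plus oracles."""

from __future__ import annotations

import numpy as np
import pytest

from hexalnc import simulate as sim
from hexalnc.models import GenomicInterval, TranscriptModel


@pytest.fixture(scope="session")
def default_bundle() -> sim.Bundle:
    """The default truth-labelled bundle (seed 7), shared across tests."""
    return sim.generate_bundle(sim.SimulationConfig())


@pytest.fixture(scope="session")
def bundle_dir(default_bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    sim.write_bundle(default_bundle, str(d))
    return d


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)


def make_transcript(
    tid: str,
    chrom: str = "chr1",
    exons=((0, 1000),),
    strand: str = "+",
    sequence=None,
    biotype: str = "candidate",
    coverage: float = 10.0,
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        sequence=sequence,
        biotype=biotype,
        read_coverage=coverage,
    )


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation paths they check)


def oracle_class_code(candidate: TranscriptModel, known) -> str:
    """Per-base exon overlap scan."""
    same = opposite = False
    for k in known:
        for ke in k.exons:
            for ce in candidate.exons:
                if ce.chrom != ke.chrom:
                    continue
                if any(ke.start <= p < ke.end for p in range(ce.start, ce.end)):
                    if k.strand == candidate.strand:
                        same = True
                    else:
                        opposite = True
    return "o" if same else ("x" if opposite else "u")


def oracle_te_overlap(t: TranscriptModel, tes) -> bool:
    for te in tes:
        for e in t.exons:
            if e.chrom == te.chrom and e.start < te.end and te.start < e.end:
                return True
    return False


def oracle_smith_waterman(a: str, b: str, match=1.0, mismatch=-2.0, gap=-2.5) -> float:
    """Plain O(nm) local-alignment DP."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, H[i - 1, j] + gap, H[i, j - 1] + gap)
            best = max(best, H[i, j])
    return best


def oracle_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum nested pairing by direct recursion over substrings."""
    pairs = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
    from functools import lru_cache

    s = seq.upper().replace("T", "U")

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        best = rec(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if (s[i], s[k]) in pairs:
                best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(s) - 1)
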