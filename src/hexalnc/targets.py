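"""Cis/trans lncRNA-mRNA target prediction and interaction networks.

Cis pairs: a differentially expressed lncRNA and a differentially expressed
mRNA from the same hybrid-vs-parent comparison, less than 100 kb apart
(genomic span separation; 0 when overlapping).  "Co-expressed" is
operationalized as both members being significantly DE with a defined
direction in that comparison -- with three samples a correlation over three
points is not meaningful, though a correlation mode (|r| >= 0.9 over the
three FPKM values) is available.

Trans pairs: stage 1 aligns the lncRNA locally against the reverse
complement of each mRNA (match +1, mismatch -2, gap -2.5), converts the raw
score to an E-value with ungapped Karlin-Altschul statistics, and keeps
hits with E <= 1e-5 and identity >= 95% over the aligned region; stage 2
computes a nearest-neighbor stacking energy for the matched duplex window
and keeps pairs at or below the energy threshold (-30 by default).
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from scipy.optimize import brentq

from hexalnc.models import TranscriptModel
from hexalnc.seqs import revcomp_dna, to_dna

logger = logging.getLogger(__name__)

DEFAULT_MAX_DISTANCE = 100_000
DEFAULT_PROMOTER_WINDOW = 2_000
DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_IDENTITY_MIN = 0.95
DEFAULT_ENERGY_MAX = -30.0

MATCH_SCORE = 1.0
MISMATCH_SCORE = -2.0
GAP_SCORE = -2.5
KA_K = 0.1  # Karlin-Altschul K, ungapped default for this scoring scheme


@dataclass
class TargetPair:
    lncrna_id: str
    mrna_id: str
    mode: str  # cis | trans
    distance: int = 0
    positional_relation: str = "n/a"  # upstream | downstream | containing_locus | promoter_overlap | n/a
    identity: float = float("nan")
    alignment_evalue: float = float("nan")
    duplex_energy: float = float("nan")
    concordance: str = "n/a"  # same_trend | opposite_trend


def _concordance(dir_a: Optional[str], dir_b: Optional[str]) -> str:
    if dir_a in ("up", "down") and dir_b in ("up", "down"):
        return "same_trend" if dir_a == dir_b else "opposite_trend"
    return "n/a"


# ---------------------------------------------------------------------------
# cis pairing


def span_gap(a: TranscriptModel, b: TranscriptModel) -> Optional[int]:
    """bp between genomic spans on the same chromosome; 0 if overlapping."""
    if a.chrom != b.chrom:
        return None
    sa, sb = a.span, b.span
    if sa.start < sb.end and sb.start < sa.end:
        return 0
    return sb.start - sa.end if sb.start >= sa.end else sa.start - sb.end


def positional_relation(
    lnc: TranscriptModel, mrna: TranscriptModel, promoter_window: int = DEFAULT_PROMOTER_WINDOW
) -> str:
    """Position of the lncRNA relative to its target gene (strand-aware).

    containing_locus when the genomic spans overlap; promoter_overlap when
    the lncRNA intersects the promoter window (``promoter_window`` bp
    upstream of the mRNA TSS); otherwise upstream/downstream of the gene.
    """
    sl, sm = lnc.span, mrna.span
    if sl.start < sm.end and sm.start < sl.end:
        return "containing_locus"
    if mrna.strand == "+":
        prom = (max(0, sm.start - promoter_window), sm.start)
    else:
        prom = (sm.end, sm.end + promoter_window)
    if sl.start < prom[1] and prom[0] < sl.end:
        return "promoter_overlap"
    lnc_is_left = sl.end <= sm.start
    if mrna.strand == "+":
        return "upstream" if lnc_is_left else "downstream"
    return "downstream" if lnc_is_left else "upstream"


def find_cis_pairs(
    de_lncrnas: Sequence[TranscriptModel],
    de_mrnas: Sequence[TranscriptModel],
    directions: Mapping[str, str],
    max_distance: int = DEFAULT_MAX_DISTANCE,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
    fpkm: Optional[pd.DataFrame] = None,
    min_abs_correlation: float = 0.9,
) -> List[TargetPair]:
    """All (DE lncRNA, DE mRNA) pairs < ``max_distance`` apart on one chromosome.

    Callers pass DE sets from a single comparison; ``directions`` maps
    transcript_id -> up/down for concordance.  When ``fpkm`` is given the
    correlation co-expression mode is applied on top of the distance rule.
    """
    by_chrom: Dict[str, List[Tuple[int, TranscriptModel]]] = {}
    for m in de_mrnas:
        by_chrom.setdefault(m.chrom, []).append((m.span.start, m))
    max_span = {c: max(len(m.span) for _, m in lst) for c, lst in by_chrom.items()}
    for lst in by_chrom.values():
        lst.sort(key=lambda x: (x[0], x[1].transcript_id))
    pairs: List[TargetPair] = []
    for lnc in de_lncrnas:
        cands = by_chrom.get(lnc.chrom, [])
        starts = [s for s, _ in cands]
        lo = bisect_left(starts, lnc.span.start - max_distance - max_span.get(lnc.chrom, 0))
        hi = bisect_right(starts, lnc.span.end + max_distance)
        for _, m in cands[lo:hi]:
            if m.transcript_id == lnc.transcript_id:
                continue
            gap = span_gap(lnc, m)
            if gap is None or gap >= max_distance:
                continue
            if fpkm is not None:
                v = fpkm.loc[[lnc.transcript_id, m.transcript_id]].to_numpy(dtype=float)
                with np.errstate(invalid="ignore"):
                    r = np.corrcoef(v[0], v[1])[0, 1]
                if not np.isfinite(r) or abs(r) < min_abs_correlation:
                    continue
            pairs.append(
                TargetPair(
                    lncrna_id=lnc.transcript_id,
                    mrna_id=m.transcript_id,
                    mode="cis",
                    distance=gap,
                    positional_relation=positional_relation(lnc, m, promoter_window),
                    concordance=_concordance(
                        directions.get(lnc.transcript_id), directions.get(m.transcript_id)
                    ),
                )
            )
    pairs.sort(key=lambda p: (p.lncrna_id, p.mrna_id))
    return pairs


# ---------------------------------------------------------------------------
# trans pairing


def karlin_altschul_lambda(
    match: float = MATCH_SCORE, mismatch: float = MISMATCH_SCORE, p_match: float = 0.25
) -> float:
    """Ungapped lambda for an i.i.d. uniform-composition scoring scheme."""

    def f(lam: float) -> float:
        return p_match * np.exp(lam * match) + (1 - p_match) * np.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-6, 10.0))


_KA_LAMBDA = karlin_altschul_lambda()


def alignment_evalue(score: float, m: int, n: int) -> float:
    """E = K * m * n * exp(-lambda * S)."""
    return float(KA_K * m * n * np.exp(-_KA_LAMBDA * score))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_SCORE
    aligner.extend_gap_score = GAP_SCORE
    return aligner


def _aligned_strings(alignment) -> Tuple[str, str]:
    """Gapped aligned strings for the local alignment region."""
    a_seq, b_seq = str(alignment.query), str(alignment.target)
    coords = alignment.coordinates  # rows: target, query in Bio.Align
    b_parts: List[str] = []
    a_parts: List[str] = []
    for c in range(coords.shape[1] - 1):
        b0, b1 = int(coords[0, c]), int(coords[0, c + 1])
        a0, a1 = int(coords[1, c]), int(coords[1, c + 1])
        da, db = a1 - a0, b1 - b0
        if da and db:
            a_parts.append(a_seq[a0:a1])
            b_parts.append(b_seq[b0:b1])
        elif da:
            a_parts.append(a_seq[a0:a1])
            b_parts.append("-" * da)
        elif db:
            a_parts.append("-" * db)
            b_parts.append(b_seq[b0:b1])
    return "".join(a_parts), "".join(b_parts)


# Nearest-neighbor stacking free energies (kcal/mol-like units) for
# antiparallel RNA duplex steps 5'-p1 p2-3' over 3'-q1 q2-5', keyed by the
# two base pairs (top+bottom).  Watson-Crick steps follow the standard
# nearest-neighbor ordering; any step involving a G:U pair gets a single
# mild value.
_WC_STACKS = {
    ("AU", "AU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CG", "UA"): -2.08,
    ("CG", "AU"): -2.11,
    ("GC", "UA"): -2.24,
    ("GC", "AU"): -2.35,
    ("CG", "GC"): -2.36,
    ("GC", "GC"): -3.26,
    ("GC", "CG"): -3.42,
    ("CG", "CG"): -2.36,
    ("UA", "UA"): -0.93,
    ("AU", "GC"): -2.24,
    ("AU", "CG"): -2.08,
    ("UA", "GC"): -2.35,
    ("UA", "CG"): -2.11,
}
GU_STACK_ENERGY = -1.0
MISMATCH_GAP_PENALTY = 1.0

_PAIRS_WC = {"AU", "UA", "GC", "CG"}
_PAIRS_GU = {"GU", "UG"}


def _stack_term(p1: str, p2: str) -> float:
    if p1 in _PAIRS_GU or p2 in _PAIRS_GU:
        return GU_STACK_ENERGY
    # complete the symmetric table: a step equals its rotated counterpart
    if (p1, p2) in _WC_STACKS:
        return _WC_STACKS[(p1, p2)]
    rot = (p2[::-1], p1[::-1])
    return _WC_STACKS[rot]


def stack_energy_table() -> Dict[Tuple[str, str], float]:
    """The full built-in stacking table (all WC x WC steps + G:U rule)."""
    out: Dict[Tuple[str, str], float] = {}
    for p1 in _PAIRS_WC | _PAIRS_GU:
        for p2 in _PAIRS_WC | _PAIRS_GU:
            out[(p1, p2)] = _stack_term(p1, p2)
    return out


def duplex_energy(
    seq_a_window: str,
    seq_b_window: str,
    penalty: float = MISMATCH_GAP_PENALTY,
) -> float:
    """Stacking energy of an aligned duplex; more negative = more stable.

    ``seq_a_window`` is the lncRNA strand 5'->3'; ``seq_b_window`` the
    opposing strand read 3'->5', aligned column-by-column (gaps as '-').
    Consecutive complementary columns (WC or G:U) contribute the stacking
    term for that step; every mismatch or gap column adds ``penalty``.
    """
    if not seq_a_window or len(seq_a_window) != len(seq_b_window):
        raise ValueError("windows must be non-empty and equal length")
    top = seq_a_window.upper().replace("T", "U")
    bottom = seq_b_window.upper().replace("T", "U")
    pair_strings: List[Optional[str]] = []
    for x, y in zip(top, bottom):
        p = x + y
        pair_strings.append(p if p in (_PAIRS_WC | _PAIRS_GU) else None)
    energy = 0.0
    for p1, p2 in zip(pair_strings, pair_strings[1:]):
        if p1 is not None and p2 is not None:
            energy += _stack_term(p1, p2)
    energy += penalty * sum(1 for p in pair_strings if p is None)
    return round(energy, 6)


def find_trans_pairs(
    lncrna_seqs: Mapping[str, str],
    mrna_seqs: Mapping[str, str],
    directions: Optional[Mapping[str, str]] = None,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    identity_min: float = DEFAULT_IDENTITY_MIN,
    energy_max: float = DEFAULT_ENERGY_MAX,
) -> List[TargetPair]:
    """Complementarity-based (trans) pairs between DE lncRNAs and DE mRNAs."""
    directions = directions or {}
    aligner = _make_aligner()
    pairs: List[TargetPair] = []
    for lid in sorted(lncrna_seqs):
        lseq = to_dna(lncrna_seqs[lid])
        if not lseq:
            raise ValueError(f"sequence absent for {lid}")
        for mid in sorted(mrna_seqs):
            if mid == lid:
                continue
            mseq = to_dna(mrna_seqs[mid])
            if not mseq:
                raise ValueError(f"sequence absent for {mid}")
            target = revcomp_dna(mseq)
            score = float(aligner.score(target, lseq))
            evalue = alignment_evalue(score, len(lseq), len(mseq))
            if evalue > evalue_max:
                continue
            aln = aligner.align(target, lseq)[0]
            a_str, b_str = _aligned_strings(aln)  # lncRNA, revcomp(mRNA)
            ncols = len(a_str)
            matches = sum(1 for x, y in zip(a_str, b_str) if x == y and x != "-")
            identity = matches / ncols if ncols else 0.0
            if identity < identity_min:
                continue
            # b_str is in revcomp(mRNA) coordinates; its charwise complement
            # is the mRNA strand read 3'->5', aligned column-for-column.
            comp = str.maketrans("ACGT-", "TGCA-")
            bottom = b_str.translate(comp)
            energy = duplex_energy(a_str, bottom)
            if energy > energy_max:
                continue
            pairs.append(
                TargetPair(
                    lncrna_id=lid,
                    mrna_id=mid,
                    mode="trans",
                    identity=round(identity, 4),
                    alignment_evalue=evalue,
                    duplex_energy=energy,
                    concordance=_concordance(directions.get(lid), directions.get(mid)),
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# networks


@dataclass
class InteractionNetwork:
    graph: nx.Graph

    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    @property
    def same_trend_fraction(self) -> float:
        m = self.edge_count
        if m == 0:
            return float("nan")
        same = sum(1 for _, _, d in self.graph.edges(data=True) if d.get("concordance") == "same_trend")
        return same / m

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "lncrna_id": d["lncrna_id"],
                "mrna_id": d["mrna_id"],
                "mode": d.get("mode", ""),
                "concordance": d.get("concordance", "n/a"),
            }
            for _, _, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["lncrna_id", "mrna_id", "mode", "concordance"]).sort_values(
            ["lncrna_id", "mrna_id"], ignore_index=True
        )

    def node_frame(self) -> pd.DataFrame:
        rows = [
            {"id": n, "kind": d.get("kind", ""), "direction": d.get("direction", "")}
            for n, d in self.graph.nodes(data=True)
        ]
        return pd.DataFrame(rows, columns=["id", "kind", "direction"]).sort_values("id", ignore_index=True)

    def write_graphml(self, path: str) -> None:
        nx.write_graphml(self.graph, path)


def build_network(
    pairs: Sequence[TargetPair], de_directions: Mapping[str, str]
) -> InteractionNetwork:
    """Deduplicated bipartite lncRNA-mRNA graph with direction-concordance stats."""
    g = nx.Graph()
    for p in pairs:
        if p.lncrna_id == p.mrna_id:
            continue
        g.add_node(p.lncrna_id, kind="lncRNA", direction=de_directions.get(p.lncrna_id, ""))
        g.add_node(p.mrna_id, kind="mRNA", direction=de_directions.get(p.mrna_id, ""))
        conc = p.concordance
        if conc == "n/a":
            conc = _concordance(de_directions.get(p.lncrna_id), de_directions.get(p.mrna_id))
        g.add_edge(
            p.lncrna_id,
            p.mrna_id,
            lncrna_id=p.lncrna_id,
            mrna_id=p.mrna_id,
            mode=p.mode,
            concordance=conc,
        )
    return InteractionNetwork(g)


def key_object_subnetwork(network: InteractionNetwork, min_degree: int = 2) -> InteractionNetwork:
    """Subnetwork induced by lncRNAs of degree >= min_degree plus their partners."""
    g = network.graph
    keys = [n for n, d in g.nodes(data=True) if d.get("kind") == "lncRNA" and g.degree(n) >= min_degree]
    nodes = set(keys)
    for k in keys:
        nodes.update(g.neighbors(k))
    return InteractionNetwork(g.subgraph(nodes).copy())


# ---------------------------------------------------------------------------
# GO tallies


def go_term_tally(
    target_gene_ids: Iterable[str], annotation: pd.DataFrame
) -> Tuple[pd.DataFrame, int]:
    """Per-ontology term counts over target genes (tally, not a test).

    ``annotation`` has columns gene_id, ontology, term (the WEGO-style
    two-column gene_id/term form is accepted, ontology then "unknown").
    Returns (tally frame with count and percent of annotated targets,
    number of targets with no annotation).  Malformed rows are skipped and
    counted in the log.
    """
    targets = sorted(set(target_gene_ids))
    cols = list(annotation.columns)
    if "ontology" not in cols:
        annotation = annotation.copy()
        annotation["ontology"] = "unknown"
    bad = annotation["gene_id"].isna() | annotation["term"].isna()
    if bad.any():
        logger.warning("go_term_tally: skipped %d malformed annotation rows", int(bad.sum()))
        annotation = annotation[~bad]
    sub = annotation[annotation["gene_id"].isin(targets)]
    annotated_genes = set(sub["gene_id"])
    n_annotated = len(annotated_genes)
    unannotated = len(targets) - n_annotated
    tally = (
        sub.groupby(["ontology", "term"])["gene_id"].nunique().rename("count").reset_index()
    )
    tally["gene_percent"] = (
        tally["count"] * 100.0 / n_annotated if n_annotated else 0.0
    )
    tally = tally.sort_values(["ontology", "term"], ignore_index=True)
    return tally, unannotated
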