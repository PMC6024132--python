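"""miRNA target-mimicry scoring and hairpin precursor detection on lncRNAs.

Target scoring slides the miRNA along the lncRNA in the antisense register
and sums per-position costs: Watson-Crick match 0, G:U wobble 0.5,
mismatch 1.0, gap 1.0, with costs doubled inside the essential region
(miRNA positions 2-17, 5'->3').  At most one gap is allowed and only after
miRNA position 17.  Sites with penalty <= 2.5 are reported.  The structural
constraints (gap count/placement, essential region, threshold) mirror the
plant small-RNA target-prediction convention; the cost weights are
configurable.

Precursor detection replaces thermodynamic folding with base-pair
maximization (Nussinov dynamic programming over Watson-Crick + G:U pairs,
minimum loop 3) plus a stem-occupancy criterion: the mature miRNA must sit
in one arm of a hairpin, pairing most of its bases to a compact opposing
arm.  An externally computed dot-bracket structure can be supplied instead
of the builtin folder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from hexalnc.seqs import RNA_ALPHABET, to_rna, validate_alphabet

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_WC = {(0, 3), (3, 0), (2, 1), (1, 2)}  # A:U, U:A, G:C, C:G
_WOBBLE = {(2, 3), (3, 2)}  # G:U, U:G
MIRNA_MIN_LEN, MIRNA_MAX_LEN = 19, 24


@dataclass(frozen=True)
class TargetScoringParams:
    penalty_threshold: float = 2.5
    max_gaps: int = 1
    essential_start: int = 2  # 1-based miRNA position, inclusive
    essential_end: int = 17
    gap_permitted_after: int = 17  # gaps only at miRNA positions > this
    wobble_cost: float = 0.5
    mismatch_cost: float = 1.0
    gap_cost: float = 1.0
    essential_multiplier: float = 2.0


DEFAULT_PARAMS = TargetScoringParams()


@dataclass
class MirnaTargetHit:
    mirna_id: str
    lncrna_id: str
    site_start: int  # 0-based position of the site's 5' end on the lncRNA
    site_length: int
    penalty_score: float
    gap_count: int
    alignment: Tuple[str, str, str]  # miRNA 5'->3', match line, site 3'->5'


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[b] for b in seq), dtype=np.int8, count=len(seq))


def _position_cost_matrix(mirna: str, params: TargetScoringParams) -> np.ndarray:
    """cost[i, b]: cost of aligning miRNA position i (0-based) to target base b."""
    L = len(mirna)
    cost = np.empty((L, 4))
    for i, m in enumerate(mirna):
        mult = (
            params.essential_multiplier
            if params.essential_start <= i + 1 <= params.essential_end
            else 1.0
        )
        for b in range(4):
            key = (_CODE[m], b)
            if key in _WC:
                c = 0.0
            elif key in _WOBBLE:
                c = params.wobble_cost
            else:
                c = params.mismatch_cost
            cost[i, b] = c * mult
    return cost


def _variant_layouts(L: int, params: TargetScoringParams):
    """Alignment variants: site length, per-miRNA-position target offsets, gaps.

    Offsets are relative to the site start (5' end on the lncRNA).  ``None``
    marks an unpaired miRNA position (miRNA bulge).  ``extra_site`` is the
    site offset of an unpaired target base (target bulge), if any.
    """
    variants = []
    # ungapped
    variants.append(("ungapped", L, [L - p for p in range(1, L + 1)], None, 0))
    if params.max_gaps >= 1:
        for g in range(params.gap_permitted_after + 1, L + 1):  # miRNA bulge at position g
            offsets: List[Optional[int]] = []
            r = 0
            for p in range(1, L + 1):
                if p == g:
                    offsets.append(None)
                else:
                    offsets.append(L - 2 - r)
                    r += 1
            variants.append((f"mir_bulge_{g}", L - 1, offsets, None, 1))
        for g in range(params.gap_permitted_after, L):  # target bulge after miRNA position g
            offsets = [(L + 1 - p) if p <= g else (L - p) for p in range(1, L + 1)]
            variants.append((f"site_bulge_{g}", L + 1, offsets, L - g, 1))
    return variants


def score_mirna_target(
    mirna_seq: str,
    lncrna_seq: str,
    params: TargetScoringParams = DEFAULT_PARAMS,
    mirna_id: str = "",
    lncrna_id: str = "",
) -> List[MirnaTargetHit]:
    """All sites on the lncRNA with penalty <= the threshold (best variant per start)."""
    mir = to_rna(mirna_seq)
    lnc = to_rna(lncrna_seq)
    validate_alphabet(mir, RNA_ALPHABET, "miRNA")
    validate_alphabet(lnc, RNA_ALPHABET, "lncRNA")
    L = len(mir)
    if not (MIRNA_MIN_LEN <= L <= MIRNA_MAX_LEN):
        raise ValueError(f"miRNA length {L} outside [{MIRNA_MIN_LEN}, {MIRNA_MAX_LEN}]")
    n = len(lnc)
    cost = _position_cost_matrix(mir, params)
    x = _encode(lnc)
    best: Dict[int, Tuple[float, str, int, int]] = {}  # t0 -> (penalty, variant, site_len, gaps)
    for name, site_len, offsets, _extra, gaps in _variant_layouts(L, params):
        n_starts = n - site_len + 1
        if n_starts <= 0:
            continue
        pen = np.full(n_starts, gaps * params.gap_cost)
        for i, off in enumerate(offsets):
            if off is None:
                continue
            pen += cost[i, x[off : off + n_starts]]
        for t0 in np.nonzero(pen <= params.penalty_threshold + 1e-9)[0]:
            p = float(pen[t0])
            cur = best.get(int(t0))
            if cur is None or p < cur[0] - 1e-12:
                best[int(t0)] = (p, name, site_len, gaps)
    hits = []
    for t0 in sorted(best):
        p, name, site_len, gaps = best[t0]
        aln = _build_alignment(mir, lnc[t0 : t0 + site_len], name, params)
        hits.append(
            MirnaTargetHit(
                mirna_id=mirna_id,
                lncrna_id=lncrna_id,
                site_start=t0,
                site_length=site_len,
                penalty_score=round(p, 6),
                gap_count=gaps,
                alignment=aln,
            )
        )
    return hits


def _pair_symbol(m: str, t: str) -> str:
    key = (_CODE[m], _CODE[t])
    if key in _WC:
        return "|"
    if key in _WOBBLE:
        return ":"
    return " "


def _build_alignment(
    mir: str, site: str, variant: str, params: TargetScoringParams
) -> Tuple[str, str, str]:
    """Alignment triple: miRNA 5'->3' on top, site shown 3'->5' below."""
    rsite = site[::-1]  # site read 3'->5', aligned left-to-right with the miRNA
    L = len(mir)
    if variant == "ungapped":
        top, bottom = mir, rsite
    elif variant.startswith("mir_bulge_"):
        g = int(variant.rsplit("_", 1)[1])  # 1-based miRNA position left unpaired
        top = mir
        bottom = rsite[: g - 1] + "-" + rsite[g - 1 :]
    else:  # site_bulge_g: unpaired site base between miRNA positions g and g+1
        g = int(variant.rsplit("_", 1)[1])
        top = mir[:g] + "-" + mir[g:]
        bottom = rsite
    match = "".join(
        " " if "-" in (m, t) else _pair_symbol(m, t) for m, t in zip(top, bottom)
    )
    return top, match, bottom


def penalty_from_alignment(
    alignment: Tuple[str, str, str], params: TargetScoringParams = DEFAULT_PARAMS
) -> float:
    """Recompute a hit's penalty from its stored alignment triple."""
    top, _match, bottom = alignment
    penalty = 0.0
    pos = 0  # 1-based miRNA position counter
    for m, t in zip(top, bottom):
        if m != "-":
            pos += 1
        if m == "-" or t == "-":
            penalty += params.gap_cost
            continue
        key = (_CODE[m], _CODE[t])
        if key in _WC:
            c = 0.0
        elif key in _WOBBLE:
            c = params.wobble_cost
        else:
            c = params.mismatch_cost
        if params.essential_start <= pos <= params.essential_end:
            c *= params.essential_multiplier
        penalty += c
    return round(penalty, 6)


# ---------------------------------------------------------------------------
# Hairpin folding


def _pairable_matrix(codes: np.ndarray) -> np.ndarray:
    ok = np.zeros((4, 4), dtype=bool)
    for a, b in _WC | _WOBBLE:
        ok[a, b] = True
    return ok[codes[:, None], codes[None, :]]


def nussinov_fold(seq: str, min_loop: int = 3) -> Tuple[str, int]:
    """Maximum base-pair nested fold (WC + G:U), deterministic traceback.

    Ties are broken by pairing the leftmost base with its leftmost optimal
    partner.  Returns the dot-bracket string and the pair count.
    """
    s = to_rna(seq)
    validate_alphabet(s, RNA_ALPHABET)
    n = len(s)
    if n == 0:
        return "", 0
    codes = _encode(s)
    P = _pairable_matrix(codes)
    # M padded so that M[a, b] = 0 whenever a > b (empty subsequence)
    M = np.zeros((n + 1, n + 1), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1, j]  # i unpaired
            ks = np.nonzero(P[i, i + min_loop + 1 : j + 1])[0]
            if ks.size:
                ks = ks + i + min_loop + 1
                vals = M[i + 1, ks - 1] + M[ks + 1, j] + 1
                v = int(vals.max())
                if v > best:
                    best = v
            M[i, j] = best
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        while i < j:
            target = M[i, j]
            if target == 0:
                break
            paired = False
            for k in range(i + min_loop + 1, j + 1):
                if P[i, k] and M[i + 1, k - 1] + M[k + 1, j] + 1 == target:
                    structure[i], structure[k] = "(", ")"
                    stack.append((k + 1, j))
                    i, j = i + 1, k - 1
                    paired = True
                    break
            if not paired:
                i += 1
    return "".join(structure), int(M[0, n - 1])


def pairs_from_dotbracket(structure: str) -> Dict[int, int]:
    """Partner map (both directions) from a balanced dot-bracket string."""
    stack: List[int] = []
    partners: Dict[int, int] = {}
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            partners[i] = j
            partners[j] = i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return partners


@dataclass
class PrecursorCall:
    lncrna_id: str
    mirna_id: str
    window: Tuple[int, int]  # folded window on the lncRNA, half-open
    structure: str  # dot-bracket of the window
    paired_mirna_fraction: float
    is_precursor: bool


def call_precursor(
    lncrna_seq: str,
    mirna_seq: str,
    window_pad: int = 150,
    stem_min_paired: float = 16 / 21,
    min_loop: int = 3,
    lncrna_id: str = "",
    mirna_id: str = "",
    fold: Optional[Callable[[str], Tuple[str, int]]] = None,
    arm_span_slack: int = 8,
    min_helix_run: int = 12,
) -> PrecursorCall:
    """Does the lncRNA harbour the mature miRNA inside a hairpin stem?

    Requires a verbatim occurrence of the miRNA (T/U-normalized); the
    surrounding window (+- ``window_pad``) is folded and the call is
    positive iff (a) at least ``stem_min_paired`` of the miRNA bases pair
    into a compact opposing arm (partners on one side of the miRNA, within
    a window of miRNA length + ``arm_span_slack``) and (b) the stem
    contains one uninterrupted helix of >= ``min_helix_run`` consecutive
    miRNA bases (a hairpin stem is a long contiguous duplex; fragmented
    pairing in a maximum-pairing fold is not).  ``fold`` may supply an
    external structure predictor returning (dot-bracket, pairs).
    """
    lnc = to_rna(lncrna_seq)
    mir = to_rna(mirna_seq)
    L = len(mir)
    idx = lnc.find(mir)
    if idx < 0:
        return PrecursorCall(lncrna_id, mirna_id, (0, 0), "", 0.0, False)
    w0 = max(0, idx - window_pad)
    w1 = min(len(lnc), idx + L + window_pad)
    window_seq = lnc[w0:w1]
    folder = fold if fold is not None else (lambda s: nussinov_fold(s, min_loop=min_loop))
    structure, _npairs = folder(window_seq)
    partners = pairs_from_dotbracket(structure)
    s = idx - w0
    e = s + L
    left = sorted(partners[i] for i in range(s, e) if i in partners and partners[i] < s)
    right = sorted(partners[i] for i in range(s, e) if i in partners and partners[i] >= e)
    # stem support = largest set of partners on one side of the miRNA that
    # fits in a compact opposing-arm window
    width = L + arm_span_slack
    best = 0
    for arm in (left, right):
        lo = 0
        for hi in range(len(arm)):
            while arm[hi] - arm[lo] + 1 > width:
                lo += 1
            best = max(best, hi - lo + 1)
    fraction = best / L
    run = best_run = 0
    prev = None
    for i in range(s, e):
        p = partners.get(i)
        if p is not None and p not in range(s, e) and (prev is None or p == prev - 1):
            run += 1
        else:
            run = 1 if (p is not None and not s <= p < e) else 0
        best_run = max(best_run, run)
        prev = p
    return PrecursorCall(
        lncrna_id=lncrna_id,
        mirna_id=mirna_id,
        window=(w0, w1),
        structure=structure,
        paired_mirna_fraction=fraction,
        is_precursor=fraction >= stem_min_paired and best_run >= min_helix_run,
    )
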