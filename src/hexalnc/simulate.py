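"""Truth-labelled synthetic data with the structure the analysis assumes.

The generator emulates the inputs of the real study at desk scale: a small
multi-chromosome genome with multi-exon coding genes, planted lncRNA
candidates of the three positional classes (u/o/x) plus coding
contaminants and low-coverage transcripts, negative-binomial fragment
counts for samples A (paternal parent), BC (maternal parent) and ABC
(hybrid) with planted differential / nonadditive / parental-bias
structure, transposon intervals, miRNA target sites and stem-loop
precursors, and a GO map -- all recorded in truth tables.

Layout is deterministic given the config (including the seed): every gene
owns a genomic block with dedicated zones for overlapping (o/x) and
intergenic (u) candidates, which keeps planted class codes unambiguous and
keeps sequence edits of one transcript from touching another.

Classification margins are enforced at generation time: true lncRNAs are
sequence-scrubbed until the builtin coding-potential heuristic scores them
clearly noncoding, and contaminants carry ORFs covering >= 50% of their
length, so that planted identification labels are sharply recoverable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from hexalnc import io as hio
from hexalnc.expression import DEFAULT_EPSILON, ExpressionTable
from hexalnc.identify import (
    CODING_CODON_P,
    SENSE_CODONS,
    longest_orf,
    score_coding_potential,
)
from hexalnc.models import GenomicInterval, TranscriptModel
from hexalnc.seqs import revcomp_dna, to_dna

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)  # code complement

SAMPLES = ("A", "BC", "ABC")


class CapacityError(ValueError):
    """Requested features do not fit on the configured chromosomes."""


def _default_class_mix() -> Dict[str, float]:
    return {"u": 0.6, "o": 0.2, "x": 0.2}


def _default_library_sizes() -> Dict[str, float]:
    return {"A": 10_000_000.0, "BC": 9_000_000.0, "ABC": 11_000_000.0}


def _default_presence_mix() -> Dict[str, float]:
    # Venn structure over A/BC/ABC: most transcripts detected everywhere,
    # hybrid sharing more with the paternal parent (A), as in the study system.
    return {
        "A_BC_ABC": 0.55,
        "A_ABC": 0.12,
        "BC_ABC": 0.08,
        "A_BC": 0.06,
        "A": 0.07,
        "BC": 0.05,
        "ABC": 0.07,
    }


@dataclass
class SimulationConfig:
    seed: int = 7
    n_chromosomes: int = 3
    chrom_length: int = 400_000
    n_coding_genes: int = 60
    n_lncrna_candidates: int = 150
    class_mix: Dict[str, float] = field(default_factory=_default_class_mix)
    frac_coding_contaminants: float = 0.15
    frac_low_coverage: float = 0.10
    library_sizes: Dict[str, float] = field(default_factory=_default_library_sizes)
    de_fraction: float = 0.23
    de_log2fc: float = 3.0
    nonadditive_fraction: float = 0.12
    nonadditive_log2_deviation: float = 3.0
    nb_dispersion: float = 0.05
    n_mirnas: int = 8
    frac_lncrna_mirna_targets: float = 0.10
    frac_lncrna_precursors: float = 0.05
    frac_lncrna_te_overlap: float = 0.40
    base_fpkm_range: Tuple[float, float] = (5.0, 60.0)
    presence_mix: Dict[str, float] = field(default_factory=_default_presence_mix)

    def validate(self) -> None:
        props = {
            "frac_coding_contaminants": self.frac_coding_contaminants,
            "frac_low_coverage": self.frac_low_coverage,
            "de_fraction": self.de_fraction,
            "nonadditive_fraction": self.nonadditive_fraction,
            "frac_lncrna_mirna_targets": self.frac_lncrna_mirna_targets,
            "frac_lncrna_precursors": self.frac_lncrna_precursors,
            "frac_lncrna_te_overlap": self.frac_lncrna_te_overlap,
        }
        for name, v in props.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if set(self.class_mix) != {"u", "o", "x"}:
            raise ValueError("class_mix keys must be u, o, x")
        if abs(sum(self.presence_mix.values()) - 1.0) > 1e-9:
            raise ValueError("presence_mix must sum to 1")
        if any(v <= 0 for v in self.library_sizes.values()):
            raise ValueError("library sizes must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["base_fpkm_range"] = list(self.base_fpkm_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["base_fpkm_range"] = tuple(d["base_fpkm_range"])
        return cls(**d)


@dataclass
class TruthLabels:
    """Per-transcript and per-interaction ground truth for the bundle."""

    transcripts: pd.DataFrame  # id, biotype, class_code, is_lncrna, flags
    expression: Optional[pd.DataFrame] = None  # planted means + derived labels
    mirna: Optional[pd.DataFrame] = None  # planted miRNA interactions


@dataclass
class AnnotationResult:
    transcripts: List[TranscriptModel]
    te_intervals: List[GenomicInterval]
    truth: TruthLabels
    _genome: Dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    _protected: Dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def genome(self) -> Dict[str, str]:
        return {c: arr.tobytes().decode() for c, arr in sorted(self._genome.items())}

    def transcript(self, tid: str) -> TranscriptModel:
        return next(t for t in self.transcripts if t.transcript_id == tid)


# ---------------------------------------------------------------------------
# genome/transcript plumbing


def _tx_positions(t: TranscriptModel) -> np.ndarray:
    """Genome positions in transcript 5'->3' order."""
    if t.strand == "+":
        return np.concatenate([np.arange(e.start, e.end) for e in t.exons])
    return np.concatenate([np.arange(e.end - 1, e.start - 1, -1) for e in reversed(t.exons)])


def _extract_seq(t: TranscriptModel, genome: Dict[str, np.ndarray]) -> str:
    pos = _tx_positions(t)
    codes = np.array([_CODE[b] for b in genome[t.chrom][pos]], dtype=np.uint8)
    if t.strand == "-":
        codes = _COMP[codes]
    return _BASES[codes].tobytes().decode()

def _write_seq(t: TranscriptModel, genome: Dict[str, np.ndarray], offset: int, sub: str) -> None:
    """Write ``sub`` into the transcript at ``offset`` (transcript coords)."""
    pos = _tx_positions(t)[offset : offset + len(sub)]
    codes = np.array([_CODE[b] for b in sub.encode()], dtype=np.uint8)
    if t.strand == "-":
        codes = _COMP[codes]
    genome[t.chrom][pos] = _BASES[codes]


def _random_orf(rng: np.random.Generator, orf_len: int) -> str:
    """ATG + codons from the biased coding usage + a stop; length = orf_len."""
    n_codons = orf_len // 3 - 2
    codons = rng.choice(SENSE_CODONS, size=n_codons, p=list(CODING_CODON_P.values()))
    stop = rng.choice(["TAA", "TAG", "TGA"])
    return "ATG" + "".join(codons) + stop


# ---------------------------------------------------------------------------
# annotation generation


def generate_annotation(config: SimulationConfig) -> AnnotationResult:
    """Place coding genes and lncRNA candidates; return models + truth labels."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome = {c: rng.choice(_BASES, size=config.chrom_length) for c in chroms}

    mix = config.class_mix
    counts = rng.multinomial(config.n_lncrna_candidates, [mix["u"], mix["o"], mix["x"]])
    n_u, n_o, n_x = (int(v) for v in counts)
    if n_u > 2 * config.n_coding_genes or n_o > config.n_coding_genes or n_x > config.n_coding_genes:
        raise CapacityError(
            f"cannot host {n_u}/{n_o}/{n_x} u/o/x candidates with "
            f"{config.n_coding_genes} coding genes (2 u, 1 o, 1 x per gene block)"
        )

    OX_ZONE, U_SLOT, GAP = 900, 1300, 200
    cursors = {c: 500 for c in chroms}
    transcripts: List[TranscriptModel] = []
    u_slots: List[Tuple[str, int]] = []
    o_hosts: List[TranscriptModel] = []  # genes with a free first-exon overlap slot
    x_hosts: List[TranscriptModel] = []
    gap_regions: List[Tuple[str, int]] = []

    for gi in range(config.n_coding_genes):
        chrom = chroms[gi % len(chroms)]
        n_exons = int(rng.integers(2, 6))
        exon_lens = rng.integers(150, 501, n_exons)
        if exon_lens.sum() < 600:
            exon_lens[0] += 600 - exon_lens.sum()
        intron_lens = rng.integers(100, 401, n_exons - 1)
        strand = str(rng.choice(["+", "-"]))
        span = int(exon_lens.sum() + intron_lens.sum())
        block = OX_ZONE + span + OX_ZONE + 2 * U_SLOT + GAP
        start = cursors[chrom] + OX_ZONE
        if start + span + OX_ZONE + 2 * U_SLOT + GAP > config.chrom_length:
            raise CapacityError(
                f"{chrom} too short for gene {gi}: need {block} bp past {cursors[chrom]}"
            )
        exons = []
        pos = start
        for k in range(n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[k]), strand))
            pos += int(exon_lens[k]) + (int(intron_lens[k]) if k < n_exons - 1 else 0)
        gene = TranscriptModel(
            transcript_id=f"mrna{gi:04d}",
            gene_id=f"gene{gi:04d}",
            exons=exons,
            biotype="coding_known",
            class_code="known",
            read_coverage=round(float(rng.uniform(10, 100)), 3),
        )
        transcripts.append(gene)
        # plant the coding ORF (>= 300 bp, ~65% of the transcript)
        L = gene.length
        orf_len = max(300, 3 * int(0.65 * L / 3))
        orf_len = min(orf_len, 3 * ((L - 60) // 3))
        orf_start = int(rng.integers(20, L - orf_len - 20))
        _write_seq(gene, genome, orf_start, _random_orf(rng, orf_len))

        u_base = start + span + OX_ZONE
        u_slots.append((chrom, u_base))
        u_slots.append((chrom, u_base + U_SLOT))
        o_hosts.append(gene)
        x_hosts.append(gene)
        gap_regions.append((chrom, u_base + 2 * U_SLOT))
        cursors[chrom] = u_base + 2 * U_SLOT + GAP

    # mark coding exon bases: protected from candidate sequence edits
    protected = {c: np.zeros(config.chrom_length, dtype=bool) for c in chroms}
    coding_cov = {c: np.zeros(config.chrom_length, dtype=bool) for c in chroms}
    for g in transcripts:
        for e in g.exons:
            protected[e.chrom][e.start : e.end] = True
            coding_cov[e.chrom][e.start : e.end] = True

    labels = ["u"] * n_u + ["o"] * n_o + ["x"] * n_x
    rng.shuffle(labels)
    iu = io_ = ix = 0
    candidates: List[TranscriptModel] = []
    for ci, cls in enumerate(labels):
        tid = f"cand{ci:04d}"
        if cls == "u":
            chrom, slot = u_slots[iu]
            iu += 1
            if rng.random() < 0.7:
                length = int(rng.integers(300, 1201))
                exons = [GenomicInterval(chrom, slot + 10, slot + 10 + length, str(rng.choice(["+", "-"])))]
            else:
                l1, l2 = (int(v) for v in rng.integers(150, 451, 2))
                intr = int(rng.integers(80, 251))
                strand = str(rng.choice(["+", "-"]))
                exons = [
                    GenomicInterval(chrom, slot + 10, slot + 10 + l1, strand),
                    GenomicInterval(chrom, slot + 10 + l1 + intr, slot + 10 + l1 + intr + l2, strand),
                ]
        elif cls == "o":
            gene = o_hosts[io_]
            io_ += 1
            exon = gene.exons[0]
            # overlap < 30 bp: no complete ORF can hide inside the protected
            # (shared-with-coding-exon) region, so scrubbing always has a slot
            overlap = int(rng.integers(20, 30))
            length = int(rng.integers(300, 801))
            end = exon.start + overlap
            exons = [GenomicInterval(exon.chrom, end - length, end, gene.strand)]
        else:  # x
            gene = x_hosts[ix]
            ix += 1
            exon = gene.exons[-1]
            overlap = int(rng.integers(20, 30))
            start = exon.end - overlap
            strand = "-" if gene.strand == "+" else "+"
            exons = [GenomicInterval(exon.chrom, start, start + int(rng.integers(300, 801)), strand)]
        candidates.append(
            TranscriptModel(transcript_id=tid, gene_id=tid, exons=exons, biotype="candidate", class_code=cls)
        )

    # contaminants (long planted ORFs) live on intergenic candidates so the
    # planted ORF never overwrites a coding gene's exonic sequence
    u_ids = [t.transcript_id for t in candidates if t.class_code == "u"]
    n_cont = int(round(config.frac_coding_contaminants * config.n_lncrna_candidates))
    if n_cont > len(u_ids):
        raise CapacityError("not enough intergenic candidates to host coding contaminants")
    cont_ids = set(rng.choice(u_ids, size=n_cont, replace=False)) if n_cont else set()
    rest = [t.transcript_id for t in candidates if t.transcript_id not in cont_ids]
    n_low = int(round(config.frac_low_coverage * config.n_lncrna_candidates))
    low_ids = set(rng.choice(rest, size=min(n_low, len(rest)), replace=False)) if n_low else set()

    for t in candidates:
        if t.transcript_id in low_ids:
            t.read_coverage = round(float(rng.uniform(0.5, 2.5)), 3)
        else:
            t.read_coverage = round(float(rng.uniform(5.0, 50.0)), 3)
        if t.transcript_id in cont_ids:
            L = t.length
            orf_len = 3 * int(0.6 * L / 3)
            _write_seq(t, genome, (L - orf_len) // 2, _random_orf(rng, orf_len))

    # scrub true lncRNAs to sharp noncoding margins
    for t in candidates:
        if t.transcript_id not in cont_ids:
            _scrub_noncoding(t, genome, protected, rng)

    # transposon intervals: planted overlaps on a subset of true lncRNAs + decoys
    true_ids = [t.transcript_id for t in candidates if t.transcript_id not in cont_ids and t.transcript_id not in low_ids]
    n_te = int(round(config.frac_lncrna_te_overlap * len(true_ids)))
    te_ids = set(rng.choice(true_ids, size=n_te, replace=False)) if n_te else set()
    tes: List[GenomicInterval] = []
    for t in candidates:
        if t.transcript_id in te_ids:
            e = t.exons[0]
            s = e.start + len(e) // 3
            tes.append(GenomicInterval(e.chrom, s, s + 80))
    for chrom, gpos in gap_regions[::6]:
        tes.append(GenomicInterval(chrom, gpos + 10, gpos + 90))

    all_tx = transcripts + candidates
    for t in all_tx:
        t.sequence = _extract_seq(t, genome)

    truth_rows = []
    for t in all_tx:
        is_cand = t.biotype == "candidate"
        truth_rows.append(
            {
                "transcript_id": t.transcript_id,
                "biotype": t.biotype,
                "class_code": t.class_code,
                "is_contaminant": t.transcript_id in cont_ids,
                "is_low_coverage": t.transcript_id in low_ids,
                "is_lncrna": is_cand
                and t.transcript_id not in cont_ids
                and t.transcript_id not in low_ids,
                "te_overlap": t.transcript_id in te_ids,
                "length": t.length,
            }
        )
    truth = TruthLabels(transcripts=pd.DataFrame(truth_rows).set_index("transcript_id"))
    return AnnotationResult(
        transcripts=all_tx,
        te_intervals=tes,
        truth=truth,
        _genome=genome,
        _protected={c: coding_cov[c] for c in chroms},
    )


def _scrub_noncoding(
    t: TranscriptModel,
    genome: Dict[str, np.ndarray],
    protected: Dict[str, np.ndarray],
    rng: np.random.Generator,
    cpc_margin: float = -1.2,
    cnci_margin: float = -0.3,
    extra_protected: Optional[Sequence[Tuple[int, int]]] = None,
) -> None:
    """Break ORFs until the heuristic scores the transcript clearly noncoding.

    Only unprotected bases (outside coding exons and planted windows) are
    rewritten, so shared sequence is never disturbed.
    """
    pos = _tx_positions(t)
    prot = protected[t.chrom][pos].copy()
    for s, e in extra_protected or []:
        prot[s:e] = True
    for it in range(400):
        seq = _extract_seq(t, genome)
        probe = TranscriptModel(
            transcript_id=t.transcript_id, exons=t.exons, sequence=seq, biotype=t.biotype
        )
        sc = score_coding_potential(probe)
        if sc.cpc_like <= cpc_margin and sc.cnci_like <= cnci_margin:
            t.sequence = seq
            return
        start, orf_len = longest_orf(seq)
        if orf_len == 0:
            raise RuntimeError(f"{t.transcript_id}: margins unreachable without an ORF")
        slots = [
            cs
            for cs in range(start + 3, start + orf_len - 3, 3)
            if not prot[cs : cs + 3].any()
        ]
        if not slots:
            # no interior codon is writable (ORF barely overhangs a planted
            # window): destroy the start codon through any unprotected base
            free = [p for p in range(start, start + 3) if not prot[p]]
            if not free:
                raise CapacityError(f"{t.transcript_id}: ORF fully protected, cannot scrub")
            p = free[0]
            seq_now = _extract_seq(t, genome)
            _write_seq(t, genome, p, "C" if seq_now[p] != "C" else "G")
            continue
        if it < 50:
            cs = min(slots, key=lambda c: abs(c - (start + orf_len // 2)))
            _write_seq(t, genome, cs, "TAA")
        else:  # break potential rewrite cycles with a random patch
            cs = int(rng.choice(slots))
            patch = "".join(rng.choice(list("ACGT"), size=9))
            _write_seq(t, genome, cs, patch[: max(3, min(9, orf_len - (cs - start) - 3))])
    raise RuntimeError(f"{t.transcript_id}: could not reach noncoding margins")


# ---------------------------------------------------------------------------
# expression planting and counts

_DE_PATTERNS = (
    ("up_both", 0.35),
    ("down_both", 0.10),
    ("mid_bc_high", 0.05),
    ("mid_a_high", 0.10),
    ("up_vs_bc", 0.30),
    ("up_vs_a", 0.10),
)
_REPRESSION_MIX = (("paternal_higher", 0.35), ("maternal_higher", 0.45), ("parental_equal", 0.20))
_NONADD_DOWN_FRACTION = 0.52  # matches the observed predominance of repression


def _exact_allocation(
    names: Sequence[str], probs: Sequence[float], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Largest-remainder allocation of n items to classes, randomly interleaved.

    Planted proportions are hit exactly (up to rounding), so truth-driven
    counts are not at the mercy of multinomial noise at toy sample sizes.
    """
    target = np.asarray(probs, dtype=float) * n
    base = np.floor(target).astype(int)
    rem = n - int(base.sum())
    order = np.argsort(-(target - base))
    base[order[:rem]] += 1
    labels = np.repeat(list(names), base)
    rng.shuffle(labels)
    return labels


def plant_expression(
    config: SimulationConfig,
    transcript_ids: Sequence[str],
    rng: Optional[np.random.Generator] = None,
    all_present: bool = False,
) -> pd.DataFrame:
    """Planted per-sample mean FPKM plus derived truth labels.

    ``all_present=True`` forces every transcript into the shared-presence
    class (used for calibration/recovery runs where presence-driven
    structure would confound planted fractions).
    """
    rng = rng if rng is not None else np.random.default_rng([config.seed, 1])
    n = len(transcript_ids)
    lo, hi = config.base_fpkm_range
    base = 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=n)
    if all_present:
        patterns = np.array(["A_BC_ABC"] * n)
    else:
        keys = list(config.presence_mix)
        patterns = _exact_allocation(keys, [config.presence_mix[k] for k in keys], n, rng)
    tokens = [set(p.split("_")) for p in patterns]
    mean = {s: np.where([s in tk for tk in tokens], base, 0.0) for s in SAMPLES}

    all_present_idx = np.array([i for i, tk in enumerate(tokens) if tk == {"A", "BC", "ABC"}])
    F = 2.0 ** config.de_log2fc
    D = 2.0 ** config.nonadditive_log2_deviation

    n_de = int(round(config.de_fraction * n))
    de_idx = (
        rng.choice(all_present_idx, size=min(n_de, len(all_present_idx)), replace=False)
        if n_de
        else np.array([], dtype=int)
    )
    pat_names = [p for p, _ in _DE_PATTERNS]
    pat_probs = [w for _, w in _DE_PATTERNS]
    de_pattern = _exact_allocation(pat_names, pat_probs, len(de_idx), rng)
    for i, pat in zip(de_idx, de_pattern):
        if pat == "up_both":
            mean["ABC"][i] *= F
        elif pat == "down_both":
            mean["ABC"][i] /= F
        elif pat == "mid_bc_high":
            mean["BC"][i] *= F
            mean["A"][i] /= F
        elif pat == "mid_a_high":
            mean["A"][i] *= F
            mean["BC"][i] /= F
        elif pat == "up_vs_bc":
            mean["BC"][i] /= F
        elif pat == "up_vs_a":
            mean["A"][i] /= F

    remaining = np.setdiff1d(all_present_idx, de_idx)
    n_na = int(round(config.nonadditive_fraction * n))
    na_idx = rng.choice(remaining, size=min(n_na, len(remaining)), replace=False) if n_na else np.array([], dtype=int)
    na_kinds = [f"down_{r}" for r, _ in _REPRESSION_MIX] + ["up"]
    na_probs = [_NONADD_DOWN_FRACTION * w for _, w in _REPRESSION_MIX] + [
        1.0 - _NONADD_DOWN_FRACTION
    ]
    na_assign = _exact_allocation(na_kinds, na_probs, len(na_idx), rng)
    for i, kind in zip(na_idx, na_assign):
        if kind.startswith("down_"):
            rep = kind[5:]
            if rep == "paternal_higher":
                mean["A"][i] *= F
            elif rep == "maternal_higher":
                mean["BC"][i] *= F
            mpv = (mean["A"][i] + mean["BC"][i]) / 2.0
            mean["ABC"][i] = mpv / D
        else:
            mean["ABC"][i] = (mean["A"][i] + mean["BC"][i]) / 2.0 * D

    eps = DEFAULT_EPSILON
    df = pd.DataFrame(
        {
            "transcript_id": transcript_ids,
            "mean_A": mean["A"],
            "mean_BC": mean["BC"],
            "mean_ABC": mean["ABC"],
        }
    ).set_index("transcript_id")
    for s in SAMPLES:
        df[f"present_{s}"] = df[f"mean_{s}"] >= 0.1

    def _status(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        lr = np.log2((num + eps) / (den + eps))
        return np.where(lr >= 1, "up", np.where(lr <= -1, "down", "null"))

    df["de_ABC_vs_A"] = _status(df["mean_ABC"].to_numpy(), df["mean_A"].to_numpy())
    df["de_ABC_vs_BC"] = _status(df["mean_ABC"].to_numpy(), df["mean_BC"].to_numpy())
    df["de_BC_vs_A"] = _status(df["mean_BC"].to_numpy(), df["mean_A"].to_numpy())
    mpv = (df["mean_A"].to_numpy() + df["mean_BC"].to_numpy()) / 2.0
    dev = np.log2((df["mean_ABC"].to_numpy() + eps) / (mpv + eps))
    df["additivity"] = np.where(dev >= 1, "nonadditive_up", np.where(dev <= -1, "nonadditive_down", "additive"))
    df["repression_category"] = np.where(
        df["additivity"] == "nonadditive_down",
        np.where(
            df["de_BC_vs_A"] == "down",
            "paternal_higher",
            np.where(df["de_BC_vs_A"] == "up", "maternal_higher", "parental_equal"),
        ),
        "n/a",
    )
    return df


def generate_counts(
    config: SimulationConfig,
    annotation: AnnotationResult,
    truth: Optional[TruthLabels] = None,
    rng: Optional[np.random.Generator] = None,
) -> ExpressionTable:
    """Draw NB fragment counts from the planted means (Poisson at dispersion 0)."""
    truth = truth if truth is not None else annotation.truth
    rng = rng if rng is not None else np.random.default_rng([config.seed, 2])
    ids = [t.transcript_id for t in annotation.transcripts]
    lengths = {t.transcript_id: t.length for t in annotation.transcripts}
    if truth.expression is None:
        truth.expression = plant_expression(config, ids)
    expr = truth.expression
    counts = draw_counts(
        expr[["mean_A", "mean_BC", "mean_ABC"]].rename(
            columns={f"mean_{s}": s for s in SAMPLES}
        ),
        lengths,
        config.library_sizes,
        config.nb_dispersion,
        rng,
    )
    return ExpressionTable(counts=counts, library_sizes=dict(config.library_sizes), lengths=lengths)


def draw_counts(
    mean_fpkm: pd.DataFrame,
    lengths: Mapping[str, int],
    library_sizes: Mapping[str, float],
    dispersion: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """NB(mean, dispersion) counts with Var = mu + alpha * mu^2."""
    L = np.array([lengths[t] for t in mean_fpkm.index], dtype=float)
    out = {}
    for s in mean_fpkm.columns:
        mu = mean_fpkm[s].to_numpy(dtype=float) * L * float(library_sizes[s]) / 1e9
        if dispersion == 0:
            out[s] = rng.poisson(mu)
        else:
            r = 1.0 / dispersion
            p = r / (r + mu)
            draws = np.zeros(len(mu), dtype=np.int64)
            nz = mu > 0
            draws[nz] = rng.negative_binomial(r, p[nz])
            out[s] = draws
    return pd.DataFrame(out, index=mean_fpkm.index)


# ---------------------------------------------------------------------------
# miRNA planting

_PLANTED_PENALTIES = (0.0, 0.5, 2.5)
HAIRPIN_LOOP_LEN = 8


# Stops at offsets 0, 4 and 8 cover all three reading frames: any ORF
# entering the cassette terminates inside it.
_STOP_CASSETTE = "TAATTAATTAA"


def _contains_internal_orf(seq: str, min_orf: int = 30) -> bool:
    """Any complete ATG..stop span of >= min_orf nt fully inside ``seq``?"""
    stops = {"TAA", "TAG", "TGA"}
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in stops:
                if i + 3 - start >= min_orf:
                    return True
                start = None
    return False


def _hairpin_insert(mir: str, rng: np.random.Generator) -> str:
    """miRNA + loop + reverse complement + all-frame stop cassette.

    The written block becomes a protected window the noncoding scrub may
    not rewrite, so it must not harbour a complete ORF itself (the loop is
    regenerated until none exists) and the trailing stop cassette
    guarantees that any reading frame entering the window terminates
    inside it rather than running on into scrub-protected territory.
    """
    for _ in range(200):
        loop = "".join(rng.choice(list("ACGT"), size=HAIRPIN_LOOP_LEN))
        insert = mir + loop + revcomp_dna(mir) + _STOP_CASSETTE
        if not _contains_internal_orf(insert):
            return insert
    raise CapacityError("could not build an ORF-free hairpin insert")


def _random_mirna(rng: np.random.Generator, length: int = 21) -> str:
    """Random miRNA (DNA alphabet) with a G or T in positions 18..21.

    The tail G/T guarantees a non-essential position where a G:U wobble can
    be planted.
    """
    while True:
        s = "".join(rng.choice(list("ACGT"), size=length))
        if any(b in "GT" for b in s[17:21]):
            return s


def plant_mirna_set(
    config: SimulationConfig, annotation: AnnotationResult, rng: Optional[np.random.Generator] = None
) -> Dict[str, str]:
    """Plant miRNA target sites (penalties 0 / 0.5 / 2.5) and stem-loop precursors.

    Returns the miRNA sequences (DNA alphabet) and appends the planted
    interactions to ``annotation.truth.mirna``.  Host lncRNAs are
    intergenic true lncRNAs; each hosts at most one planted feature.
    """
    rng = rng if rng is not None else np.random.default_rng([config.seed, 3])
    genome = annotation._genome
    truth_t = annotation.truth.transcripts
    hosts = [
        annotation.transcript(tid)
        for tid in truth_t.index[truth_t["is_lncrna"] & (truth_t["class_code"] == "u")]
    ]
    mirnas = {f"mir{j:03d}": _random_mirna(rng) for j in range(config.n_mirnas)}
    mir_ids = sorted(mirnas)

    n_true = int(truth_t["is_lncrna"].sum())
    n_targets = int(round(config.frac_lncrna_mirna_targets * n_true))
    n_prec = int(round(config.frac_lncrna_precursors * n_true))
    if n_targets + n_prec > len(hosts):
        raise CapacityError("not enough intergenic lncRNAs to host miRNA features")
    chosen = rng.choice(len(hosts), size=n_targets + n_prec, replace=False)
    target_hosts = [hosts[i] for i in chosen[:n_targets]]
    prec_hosts = [hosts[i] for i in chosen[n_targets:]]

    rows = []
    for k, host in enumerate(target_hosts):
        mir_id = mir_ids[k % len(mir_ids)]
        mir = mirnas[mir_id]
        penalty = _PLANTED_PENALTIES[k % len(_PLANTED_PENALTIES)]
        site = list(revcomp_dna(mir))
        L = len(mir)
        if penalty >= 0.5:
            # wobble at a non-essential tail position (1-based p in 18..21)
            p = next(i + 1 for i in range(17, min(21, L)) if mir[i] in "GT")
            site[L - p] = "T" if mir[p - 1] == "G" else "G"
        if penalty >= 2.5:
            site[L - 9] = mir[8]  # same-base mismatch at essential position 9
        site_s = "".join(site)
        off = int(rng.integers(20, host.length - len(site_s) - 20))
        _write_seq(host, genome, off, site_s)
        _rescrub_host(host, genome, annotation, rng, [(off, off + len(site_s))])
        rows.append(
            {
                "mirna_id": mir_id,
                "lncrna_id": host.transcript_id,
                "kind": "target",
                "planted_penalty": penalty,
                "position": off,
            }
        )

    for k, host in enumerate(prec_hosts):
        mir_id = mir_ids[(k + n_targets) % len(mir_ids)]
        mir = mirnas[mir_id]
        insert = _hairpin_insert(mir, rng)
        if host.length < len(insert) + 40:
            raise CapacityError(
                f"{host.transcript_id} too short ({host.length} nt) for hairpin insert"
            )
        off = int(rng.integers(20, host.length - len(insert) - 20))
        _write_seq(host, genome, off, insert)
        _rescrub_host(host, genome, annotation, rng, [(off, off + len(insert))])
        rows.append(
            {
                "mirna_id": mir_id,
                "lncrna_id": host.transcript_id,
                "kind": "precursor",
                "planted_penalty": np.nan,
                "position": off,
            }
        )

    for t in annotation.transcripts:
        t.sequence = _extract_seq(t, genome)
    annotation.truth.mirna = pd.DataFrame(
        rows, columns=["mirna_id", "lncrna_id", "kind", "planted_penalty", "position"]
    )
    return mirnas


def _rescrub_host(
    host: TranscriptModel,
    genome: Dict[str, np.ndarray],
    annotation: AnnotationResult,
    rng: np.random.Generator,
    windows: Sequence[Tuple[int, int]],
) -> None:
    """Restore noncoding margins after planting, leaving planted windows intact."""
    _scrub_noncoding(host, genome, annotation._protected, rng, extra_protected=windows)


# ---------------------------------------------------------------------------
# GO annotation and sequence shuffles


GO_VOCABULARY = {
    "biological_process": [
        "metabolic process",
        "cellular process",
        "biological regulation",
        "pigmentation",
        "reproduction",
        "response to stimulus",
    ],
    "molecular_function": ["binding", "catalytic activity", "transporter activity"],
    "cellular_component": ["cell part", "organelle", "membrane"],
}


def generate_go_annotation(
    gene_ids: Sequence[str], rng: Optional[np.random.Generator] = None, seed: int = 7
) -> pd.DataFrame:
    """Toy gene -> (ontology, secondary term) map over a small plant-style vocabulary."""
    rng = rng if rng is not None else np.random.default_rng([seed, 4])
    rows = []
    for g in gene_ids:
        for ont, terms in GO_VOCABULARY.items():
            k = int(rng.integers(0, 3))
            if k:
                for term in rng.choice(terms, size=min(k, len(terms)), replace=False):
                    rows.append({"gene_id": g, "ontology": ont, "term": term})
    return pd.DataFrame(rows, columns=["gene_id", "ontology", "term"])


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle preserving dinucleotide composition."""
    s = to_dna(seq)
    if len(s) < 3:
        return s
    edges: Dict[str, List[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    terminal = s[-1]
    vertices = sorted(edges)
    for _ in range(1000):
        last = {}
        ok = True
        for v in vertices:
            if v == terminal and not edges[v]:
                continue
            last[v] = edges[v][int(rng.integers(len(edges[v])))]
        # every vertex must reach the terminal via last-edges
        for v in vertices:
            seen = set()
            cur = v
            while cur != terminal and cur in last and cur not in seen:
                seen.add(cur)
                cur = last[cur]
            if cur != terminal:
                ok = False
                break
        if ok:
            break
    else:
        return s
    pools = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last:
            rest.remove(last[v])
        rng.shuffle(rest)
        pools[v] = rest + ([last[v]] if v in last else [])
    out = [s[0]]
    cur = s[0]
    while pools.get(cur):
        nxt = pools[cur].pop(0)
        out.append(nxt)
        cur = nxt
    return "".join(out)


# ---------------------------------------------------------------------------
# bundle assembly and writing


@dataclass
class Bundle:
    config: SimulationConfig
    annotation: AnnotationResult
    mirnas: Dict[str, str]
    expression: ExpressionTable
    go_annotation: pd.DataFrame

    @property
    def truth(self) -> TruthLabels:
        return self.annotation.truth


def generate_bundle(config: SimulationConfig) -> Bundle:
    """Run all generator stages in their canonical order."""
    annotation = generate_annotation(config)
    mirnas = plant_mirna_set(config, annotation)
    expression = generate_counts(config, annotation)
    genes = sorted({t.gene_id for t in annotation.transcripts if t.biotype == "coding_known"})
    go = generate_go_annotation(genes, seed=config.seed)
    return Bundle(config, annotation, mirnas, expression, go)


def write_bundle(bundle: Bundle, outdir: str) -> Dict[str, str]:
    """Write the full fixture bundle; deterministic and byte-identical per config."""
    import os

    os.makedirs(outdir, exist_ok=True)
    p = {k: os.path.join(outdir, v) for k, v in {
        "config": "config.yaml",
        "gtf": "annotation.gtf",
        "genome": "genome.fa",
        "transcripts": "transcripts.fa",
        "te_bed": "te.bed",
        "counts": "counts.tsv",
        "library_sizes": "library_sizes.tsv",
        "mirnas": "mirnas.fa",
        "go": "go_annotation.tsv",
        "truth_transcripts": "truth_transcripts.tsv",
        "truth_expression": "truth_expression.tsv",
        "truth_mirna": "truth_mirna.tsv",
    }.items()}
    bundle.config.to_yaml(p["config"])
    hio.write_gtf(bundle.annotation.transcripts, p["gtf"])
    hio.write_fasta(bundle.annotation.genome, p["genome"])
    hio.write_fasta(
        {t.transcript_id: t.sequence for t in bundle.annotation.transcripts}, p["transcripts"]
    )
    hio.write_bed(
        bundle.annotation.te_intervals,
        p["te_bed"],
        names=[f"TE{i:04d}" for i in range(len(bundle.annotation.te_intervals))],
    )
    counts = bundle.expression.counts.rename(columns={s: f"count_{s}" for s in SAMPLES})
    counts.index.name = "transcript_id"
    hio.write_tsv(counts.sort_index(), p["counts"], index=True)
    libs = pd.DataFrame(
        {"sample": list(SAMPLES), "library_size": [bundle.expression.library_sizes[s] for s in SAMPLES]}
    )
    hio.write_tsv(libs, p["library_sizes"])
    hio.write_fasta(bundle.mirnas, p["mirnas"])
    hio.write_tsv(bundle.go_annotation, p["go"])
    truth = bundle.truth
    hio.write_tsv(truth.transcripts.sort_index(), p["truth_transcripts"], index=True)
    hio.write_tsv(truth.expression.sort_index(), p["truth_expression"], index=True)
    hio.write_tsv(truth.mirna, p["truth_mirna"])
    return p
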