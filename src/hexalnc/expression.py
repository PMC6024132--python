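"""FPKM quantification, differential expression and mid-parent-value analysis.

Samples are A (paternal parent, *B. rapa*), BC (maternal parent,
*B. carinata*) and ABC (the allohexaploid).  One pooled library per sample,
so differential calls use an exact conditional binomial test: conditioned
on the total fragment count of a transcript in the two libraries, the count
in library x is Binomial(n, lib_x/(lib_x+lib_y)) under the null of equal
concentration; this is the classic exact test for comparing two Poisson
counts with known exposure ratio.  Significance additionally requires
|log2FC| >= 1 (fold change of FPKM with a pseudo-FPKM floor).

Nonadditive expression compares the hybrid with the mid-parent value
MPV = (FPKM_A + FPKM_BC)/2 under the same machinery, testing the hybrid
count against the rounded mean of the library-size-rescaled parent counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

SAMPLES = ("A", "BC", "ABC")


@dataclass
class ExpressionTable:
    """Fragment counts and library sizes for the three samples.

    ``counts`` is indexed by transcript_id with columns A/BC/ABC;
    ``lengths`` are mature transcript lengths in bp.
    """

    counts: pd.DataFrame
    library_sizes: Dict[str, float]
    lengths: Dict[str, int]

    def __post_init__(self) -> None:
        if (self.counts < 0).any().any():
            raise ValueError("fragment counts must be nonnegative")
        for s, v in self.library_sizes.items():
            if v <= 0:
                raise ValueError(f"library size for {s} must be > 0")

    def fpkm(self) -> pd.DataFrame:
        return fpkm_table(self.counts, self.lengths, self.library_sizes)
COMPARISONS = ("ABC_vs_A", "ABC_vs_BC", "BC_vs_A")
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_LOG2FC = 1.0
DEFAULT_EPSILON = 0.01  # pseudo-FPKM floor: keeps fold changes of silent transcripts finite


def compute_fpkm(fragment_count: float, transcript_length_bp: int, library_size: float) -> float:
    """fragments per kilobase of exon per million mapped fragments."""
    if transcript_length_bp <= 0:
        raise ValueError("transcript length must be > 0")
    if library_size <= 0:
        raise ValueError("library size must be > 0")
    return fragment_count * 1e9 / (transcript_length_bp * library_size)


def fpkm_table(
    counts: pd.DataFrame, lengths: Mapping[str, int], library_sizes: Mapping[str, float]
) -> pd.DataFrame:
    """FPKM for a counts table indexed by transcript_id with sample columns."""
    L = np.array([lengths[t] for t in counts.index], dtype=float)
    out = {}
    for s in counts.columns:
        out[s] = counts[s].to_numpy(dtype=float) * 1e9 / (L * float(library_sizes[s]))
    return pd.DataFrame(out, index=counts.index)


@dataclass
class DifferentialResult:
    transcript_id: str
    comparison: str
    log2fc: float
    p_value: float
    significant: bool
    direction: str  # up | down | ns

    @property
    def is_de(self) -> bool:
        return self.significant


def _binomial_p(count_x: int, count_y: int, lib_x: float, lib_y: float) -> float:
    n = count_x + count_y
    if n == 0:
        return 1.0
    p0 = lib_x / (lib_x + lib_y)
    return float(stats.binomtest(count_x, n, p0).pvalue)


def differential_test(
    count_x: int,
    count_y: int,
    lib_x: float,
    lib_y: float,
    length: int,
    transcript_id: str = "",
    comparison: str = "",
    alpha: float = DEFAULT_ALPHA,
    min_log2fc: float = DEFAULT_MIN_LOG2FC,
    epsilon: float = DEFAULT_EPSILON,
) -> DifferentialResult:
    """Exact conditional binomial DE test of sample x vs sample y.

    log2fc = log2((fpkm_x + eps)/(fpkm_y + eps)); significant iff
    |log2fc| >= min_log2fc AND p < alpha (the fold-change/p conjunction).
    """
    if count_x < 0 or count_y < 0:
        raise ValueError("counts must be nonnegative")
    if count_x == 0 and count_y == 0:
        return DifferentialResult(transcript_id, comparison, 0.0, 1.0, False, "ns")
    fx = compute_fpkm(count_x, length, lib_x)
    fy = compute_fpkm(count_y, length, lib_y)
    log2fc = float(np.log2((fx + epsilon) / (fy + epsilon)))
    p = _binomial_p(count_x, count_y, lib_x, lib_y)
    significant = abs(log2fc) >= min_log2fc and p < alpha
    direction = "ns" if not significant else ("up" if log2fc > 0 else "down")
    return DifferentialResult(transcript_id, comparison, log2fc, p, significant, direction)


def differential_table(
    counts: pd.DataFrame,
    lengths: Mapping[str, int],
    library_sizes: Mapping[str, float],
    comparisons: Sequence[str] = COMPARISONS,
    alpha: float = DEFAULT_ALPHA,
    min_log2fc: float = DEFAULT_MIN_LOG2FC,
    epsilon: float = DEFAULT_EPSILON,
    fdr: bool = False,
) -> pd.DataFrame:
    """DE results for every transcript x comparison, long format.

    ``fdr=True`` replaces the raw-p criterion with Benjamini-Hochberg
    adjusted p per comparison (off by default: the analysis convention here
    is raw p < alpha).
    """
    rows = []
    for comp in comparisons:
        x, y = comp.split("_vs_")
        for tid in counts.index:
            r = differential_test(
                int(counts.at[tid, x]),
                int(counts.at[tid, y]),
                float(library_sizes[x]),
                float(library_sizes[y]),
                int(lengths[tid]),
                transcript_id=tid,
                comparison=comp,
                alpha=alpha,
                min_log2fc=min_log2fc,
                epsilon=epsilon,
            )
            rows.append(
                (tid, comp, r.log2fc, r.p_value, r.significant, r.direction)
            )
    df = pd.DataFrame(rows, columns=["transcript_id", "comparison", "log2fc", "p_value", "significant", "direction"])
    if fdr:
        for comp in comparisons:
            mask = df["comparison"] == comp
            p = df.loc[mask, "p_value"].to_numpy()
            q = _bh_adjust(p)
            sig = (np.abs(df.loc[mask, "log2fc"].to_numpy()) >= min_log2fc) & (q < alpha)
            df.loc[mask, "significant"] = sig
            df.loc[mask, "direction"] = np.where(
                ~sig, "ns", np.where(df.loc[mask, "log2fc"].to_numpy() > 0, "up", "down")
            )
    return df


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class AdditivityCall:
    transcript_id: str
    mpv: float
    log2_dev: float
    p_value: float
    mode: str  # additive | nonadditive
    direction: str  # up | down | n/a
    repression_category: str = "n/a"  # paternal_higher | maternal_higher | parental_equal | n/a
    pattern_cluster: str = "unassigned"


def classify_additivity(
    count_a: int,
    count_bc: int,
    count_abc: int,
    library_sizes: Mapping[str, float],
    length: int,
    transcript_id: str = "",
    alpha: float = DEFAULT_ALPHA,
    min_log2fc: float = DEFAULT_MIN_LOG2FC,
    epsilon: float = DEFAULT_EPSILON,
) -> AdditivityCall:
    """Hybrid vs mid-parent value: nonadditive iff |log2 dev| >= 1 and p < alpha.

    The p-value comes from the conditional binomial test of the hybrid
    count against a pseudo-parent sample: parent counts rescaled to the
    mean parental library size, averaged and rounded, tested at that
    library size.
    """
    lib_a, lib_bc, lib_abc = (float(library_sizes[s]) for s in SAMPLES)
    fa = compute_fpkm(count_a, length, lib_a)
    fbc = compute_fpkm(count_bc, length, lib_bc)
    fabc = compute_fpkm(count_abc, length, lib_abc)
    mpv = (fa + fbc) / 2.0
    log2_dev = float(np.log2((fabc + epsilon) / (mpv + epsilon)))
    pseudo_lib = (lib_a + lib_bc) / 2.0
    pseudo_count = int(round((count_a * pseudo_lib / lib_a + count_bc * pseudo_lib / lib_bc) / 2.0))
    if count_abc == 0 and pseudo_count == 0:
        p = 1.0
    else:
        p = _binomial_p(count_abc, pseudo_count, lib_abc, pseudo_lib)
    nonadd = abs(log2_dev) >= min_log2fc and p < alpha
    return AdditivityCall(
        transcript_id=transcript_id,
        mpv=mpv,
        log2_dev=log2_dev,
        p_value=p,
        mode="nonadditive" if nonadd else "additive",
        direction=("up" if log2_dev > 0 else "down") if nonadd else "n/a",
    )


def classify_repressed_category(
    call: AdditivityCall, de_bc_vs_a: DifferentialResult
) -> str:
    """Category of a repressed (nonadditive-down) transcript by its parents.

    BC_vs_A significant down (A higher) -> paternal_higher; significant up
    -> maternal_higher; not significant -> parental_equal ("equally
    expressed" parents are operationalized as BC_vs_A nonsignificant).
    """
    if call.mode != "nonadditive" or call.direction != "down":
        raise ValueError("repression categories apply only to nonadditive-down calls")
    if not de_bc_vs_a.significant:
        return "parental_equal"
    return "maternal_higher" if de_bc_vs_a.direction == "up" else "paternal_higher"


def assign_pattern_cluster(
    de_abc_vs_a: DifferentialResult,
    de_abc_vs_bc: DifferentialResult,
    present_a: bool,
    present_bc: bool,
    present_abc: bool,
) -> str:
    """One of the six hybrid-vs-parents expression-pattern clusters.

    Presence tests take precedence: 5 = expressed only in BC, 6 = only in
    A.  Then 1 = up vs both parents, 2 = down vs both, 3 = down vs BC and
    up vs A (BC > ABC > A), 4 = the mirror.  Everything else (including
    transcripts DE in just one comparison) is unassigned.
    """
    if present_bc and not present_a and not present_abc:
        return "5"
    if present_a and not present_bc and not present_abc:
        return "6"
    da, dbc = de_abc_vs_a.direction, de_abc_vs_bc.direction
    if da == "up" and dbc == "up":
        return "1"
    if da == "down" and dbc == "down":
        return "2"
    if da == "up" and dbc == "down":
        return "3"
    if da == "down" and dbc == "up":
        return "4"
    return "unassigned"


def additivity_table(
    counts: pd.DataFrame,
    lengths: Mapping[str, int],
    library_sizes: Mapping[str, float],
    de: pd.DataFrame,
    presence_threshold: float = 0.0,
    alpha: float = DEFAULT_ALPHA,
    min_log2fc: float = DEFAULT_MIN_LOG2FC,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Additivity calls + repression categories + pattern clusters, one row per transcript."""
    fpkm = fpkm_table(counts, lengths, library_sizes)
    de_idx = {(r.transcript_id, r.comparison): r for r in _iter_results(de)}
    rows = []
    for tid in counts.index:
        call = classify_additivity(
            int(counts.at[tid, "A"]),
            int(counts.at[tid, "BC"]),
            int(counts.at[tid, "ABC"]),
            library_sizes,
            int(lengths[tid]),
            transcript_id=tid,
            alpha=alpha,
            min_log2fc=min_log2fc,
            epsilon=epsilon,
        )
        if call.mode == "nonadditive" and call.direction == "down":
            call.repression_category = classify_repressed_category(call, de_idx[(tid, "BC_vs_A")])
        da, dbc = de_idx[(tid, "ABC_vs_A")], de_idx[(tid, "ABC_vs_BC")]
        if da.significant or dbc.significant:
            call.pattern_cluster = assign_pattern_cluster(
                da,
                dbc,
                fpkm.at[tid, "A"] > presence_threshold,
                fpkm.at[tid, "BC"] > presence_threshold,
                fpkm.at[tid, "ABC"] > presence_threshold,
            )
        rows.append(
            (
                tid,
                call.mpv,
                call.log2_dev,
                call.p_value,
                call.mode,
                call.direction,
                call.repression_category,
                call.pattern_cluster,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "mpv",
            "log2_dev",
            "p_value",
            "mode",
            "direction",
            "repression_category",
            "pattern_cluster",
        ],
    )


def _iter_results(de: pd.DataFrame) -> Iterable[DifferentialResult]:
    for r in de.itertuples(index=False):
        yield DifferentialResult(
            r.transcript_id, r.comparison, float(r.log2fc), float(r.p_value), bool(r.significant), r.direction
        )


@dataclass
class BiasSummary:
    per_comparison: pd.DataFrame  # n_de, n_up, n_down, total_abs_log2fc
    bias_verdict: str  # paternal_biased | maternal_biased | balanced


def parental_bias_summary(de: pd.DataFrame) -> BiasSummary:
    """Up/down counts and total |log2FC| per hybrid-parent comparison.

    Paternal-biased expression means the hybrid diverges more from the
    maternal parent: both n_de and the total |log2FC| are larger for
    ABC_vs_BC than for ABC_vs_A (mirrored for maternal; otherwise
    balanced).
    """
    rows = {}
    for comp in ("ABC_vs_A", "ABC_vs_BC"):
        sub = de[(de["comparison"] == comp) & de["significant"]]
        rows[comp] = {
            "n_de": len(sub),
            "n_up": int((sub["direction"] == "up").sum()),
            "n_down": int((sub["direction"] == "down").sum()),
            "total_abs_log2fc": float(sub["log2fc"].abs().sum()),
        }
    table = pd.DataFrame(rows).T
    a, bc = rows["ABC_vs_A"], rows["ABC_vs_BC"]
    if bc["n_de"] > a["n_de"] and bc["total_abs_log2fc"] > a["total_abs_log2fc"]:
        verdict = "paternal_biased"
    elif a["n_de"] > bc["n_de"] and a["total_abs_log2fc"] > bc["total_abs_log2fc"]:
        verdict = "maternal_biased"
    else:
        verdict = "balanced"
    return BiasSummary(per_comparison=table, bias_verdict=verdict)
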