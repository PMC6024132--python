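"""Stage orchestration: identify -> quantify -> diffexp -> additivity -> targets -> mirna -> report.

Each stage reads and writes files (no in-memory-only mode), so any stage
can be re-run in isolation or replaced by external tool output (e.g. real
CPC/CNCI scores via the score table).  The report aggregates every output
table into one JSON document whose counts equal the row counts of the
tables it summarizes, together with the thresholds used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from hexalnc import catalog as hcat
from hexalnc import expression as hexp
from hexalnc import identify as hid
from hexalnc import io as hio
from hexalnc import mirna as hmir
from hexalnc import targets as htar

logger = logging.getLogger(__name__)

SAMPLES = ("A", "BC", "ABC")
HYBRID_COMPARISONS = ("ABC_vs_A", "ABC_vs_BC")


@dataclass
class PipelineConfig:
    """All stage inputs, outputs and thresholds; defaults are the study's."""

    workdir: str = "."
    outdir: str = "results"
    annotation_gtf: str = "annotation.gtf"
    transcripts_fasta: str = "transcripts.fa"
    te_bed: str = "te.bed"
    counts_tsv: str = "counts.tsv"
    library_sizes_tsv: str = "library_sizes.tsv"
    mirna_fasta: str = "mirnas.fa"
    go_tsv: str = "go_annotation.tsv"
    scores_tsv: Optional[str] = None
    min_length: int = 200
    min_coverage: float = 3.0
    cpc_threshold: float = -1.0
    cnci_threshold: float = 0.0
    min_log2fc: float = 1.0
    alpha: float = 0.05
    mpv_min_log2fc: float = 1.0
    max_cis_distance: int = 100_000
    promoter_window: int = 2_000
    evalue_max: float = 1e-5
    identity_min: float = 0.95
    energy_max: float = -30.0
    penalty_threshold: float = 2.5
    window_pad: int = 150
    epsilon: float = 0.01
    presence_threshold: float = 0.0
    fdr: bool = False
    coexpression_mode: str = "direction"  # direction | correlation
    seed: int = 7

    def path(self, name: str) -> str:
        return os.path.join(self.workdir, name)

    def out(self, name: str) -> str:
        d = os.path.join(self.workdir, self.outdir)
        os.makedirs(d, exist_ok=True)
        return os.path.join(d, name)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _require(cfg: PipelineConfig, *names: str) -> None:
    for n in names:
        p = cfg.path(getattr(cfg, n))
        if not os.path.exists(p):
            raise FileNotFoundError(f"required input {n} missing: {p}")


def _load_catalog(cfg: PipelineConfig):
    seqs = hio.read_fasta(cfg.path(cfg.transcripts_fasta))
    transcripts = hio.read_gtf(cfg.path(cfg.annotation_gtf), sequences=seqs)
    known = [t for t in transcripts if t.biotype == "coding_known"]
    candidates = [t for t in transcripts if t.biotype != "coding_known"]
    return transcripts, known, candidates


def _load_expression(cfg: PipelineConfig, lengths: Dict[str, int]) -> hexp.ExpressionTable:
    counts = hio.read_tsv(cfg.path(cfg.counts_tsv), index_col="transcript_id")
    counts = counts.rename(columns={f"count_{s}": s for s in SAMPLES})[list(SAMPLES)]
    libs_df = hio.read_tsv(cfg.path(cfg.library_sizes_tsv))
    libs = dict(zip(libs_df["sample"], libs_df["library_size"].astype(float)))
    return hexp.ExpressionTable(counts=counts, library_sizes=libs, lengths=lengths)


def stage_identify(cfg: PipelineConfig) -> hid.FilterReport:
    """lncRNA identification + positional class codes for the retained set."""
    _require(cfg, "annotation_gtf", "transcripts_fasta")
    transcripts, known, candidates = _load_catalog(cfg)
    scores = hid.read_score_table(cfg.path(cfg.scores_tsv)) if cfg.scores_tsv else None
    lncrnas, report = hid.identify_lncrnas(
        candidates,
        scores=scores,
        min_length=cfg.min_length,
        min_coverage=cfg.min_coverage,
        cpc_threshold=cfg.cpc_threshold,
        cnci_threshold=cfg.cnci_threshold,
    )
    index = hcat.KnownExonIndex(known)
    for t in lncrnas:
        t.class_code = hcat.assign_class_code(t, index)
    hio.write_gtf(lncrnas, cfg.out("lncrna.gtf"))
    hio.write_fasta({t.transcript_id: t.sequence for t in lncrnas}, cfg.out("lncrna.fa"))
    hio.write_tsv(report.to_frame(), cfg.out("filter_report.tsv"))
    logger.info(
        "identify: %d candidates -> %d lncRNAs (short %d, low coverage %d, coding %d)",
        report.input_count,
        len(report.retained_ids),
        report.removed_short,
        report.removed_low_coverage,
        report.removed_coding,
    )
    return report


def stage_diffexp(cfg: PipelineConfig) -> pd.DataFrame:
    """FPKM + DE tests for all transcripts over the three comparisons."""
    _require(cfg, "annotation_gtf", "transcripts_fasta", "counts_tsv", "library_sizes_tsv")
    transcripts, _, _ = _load_catalog(cfg)
    lengths = {t.transcript_id: t.length for t in transcripts}
    expr = _load_expression(cfg, lengths)
    fpkm = expr.fpkm()
    fpkm.index.name = "transcript_id"
    hio.write_tsv(fpkm.sort_index().round(6), cfg.out("fpkm.tsv"), index=True)
    de = hexp.differential_table(
        expr.counts,
        lengths,
        expr.library_sizes,
        alpha=cfg.alpha,
        min_log2fc=cfg.min_log2fc,
        epsilon=cfg.epsilon,
        fdr=cfg.fdr,
    )
    hio.write_tsv(de.round({"log2fc": 6, "p_value": 10}), cfg.out("de.tsv"))
    return de


def stage_additivity(cfg: PipelineConfig) -> pd.DataFrame:
    """MPV comparison, repression categories and pattern clusters."""
    _require(cfg, "counts_tsv", "library_sizes_tsv")
    de = hio.read_tsv(cfg.out("de.tsv"))
    transcripts, _, _ = _load_catalog(cfg)
    lengths = {t.transcript_id: t.length for t in transcripts}
    expr = _load_expression(cfg, lengths)
    add = hexp.additivity_table(
        expr.counts,
        lengths,
        expr.library_sizes,
        de,
        presence_threshold=cfg.presence_threshold,
        alpha=cfg.alpha,
        min_log2fc=cfg.mpv_min_log2fc,
        epsilon=cfg.epsilon,
    )
    hio.write_tsv(add.round({"mpv": 6, "log2_dev": 6, "p_value": 10}), cfg.out("additivity.tsv"))
    return add


def _de_sets(cfg: PipelineConfig, de: pd.DataFrame, ids: List[str], comparison: str):
    sub = de[(de["comparison"] == comparison) & de["significant"] & de["transcript_id"].isin(ids)]
    return sub["transcript_id"].tolist(), dict(zip(sub["transcript_id"], sub["direction"]))


def stage_targets(cfg: PipelineConfig) -> Dict[str, dict]:
    """Cis/trans pairing, networks and GO tallies per hybrid-parent comparison."""
    _require(cfg, "annotation_gtf", "transcripts_fasta", "go_tsv")
    de = hio.read_tsv(cfg.out("de.tsv"))
    transcripts, known, _ = _load_catalog(cfg)
    lncrnas = hio.read_gtf(cfg.out("lncrna.gtf"), sequences=hio.read_fasta(cfg.out("lncrna.fa")))
    by_id = {t.transcript_id: t for t in transcripts + lncrnas}
    fpkm = (
        hio.read_tsv(cfg.out("fpkm.tsv"), index_col="transcript_id")
        if cfg.coexpression_mode == "correlation"
        else None
    )
    go = hio.read_tsv(cfg.path(cfg.go_tsv))
    stats: Dict[str, dict] = {}
    for comp in HYBRID_COMPARISONS:
        lnc_de, lnc_dirs = _de_sets(cfg, de, [t.transcript_id for t in lncrnas], comp)
        mrna_de, mrna_dirs = _de_sets(cfg, de, [t.transcript_id for t in known], comp)
        directions = {**lnc_dirs, **mrna_dirs}
        cis = htar.find_cis_pairs(
            [by_id[i] for i in lnc_de],
            [by_id[i] for i in mrna_de],
            directions,
            max_distance=cfg.max_cis_distance,
            promoter_window=cfg.promoter_window,
            fpkm=fpkm,
        )
        trans = htar.find_trans_pairs(
            {i: by_id[i].sequence for i in lnc_de},
            {i: by_id[i].sequence for i in mrna_de},
            directions,
            evalue_max=cfg.evalue_max,
            identity_min=cfg.identity_min,
            energy_max=cfg.energy_max,
        )
        pairs = cis + trans
        pair_rows = [dataclasses.asdict(p) for p in pairs]
        hio.write_tsv(
            pd.DataFrame(
                pair_rows,
                columns=[f.name for f in dataclasses.fields(htar.TargetPair)],
            ),
            cfg.out(f"pairs_{comp}.tsv"),
        )
        net = htar.build_network(pairs, directions)
        key = htar.key_object_subnetwork(net)
        hio.write_tsv(net.edge_frame(), cfg.out(f"network_edges_{comp}.tsv"))
        hio.write_tsv(net.node_frame(), cfg.out(f"network_nodes_{comp}.tsv"))
        net.write_graphml(cfg.out(f"network_{comp}.graphml"))
        target_genes = sorted({by_id[p.mrna_id].gene_id or p.mrna_id for p in pairs})
        tally, unannotated = htar.go_term_tally(target_genes, go)
        hio.write_tsv(tally.round({"gene_percent": 4}), cfg.out(f"go_tally_{comp}.tsv"))
        stats[comp] = {
            "n_cis_pairs": len(cis),
            "n_trans_pairs": len(trans),
            "n_pairs": len(pairs),
            "network_nodes": net.node_count,
            "network_edges": net.edge_count,
            "same_trend_fraction": None
            if net.edge_count == 0
            else round(net.same_trend_fraction, 6),
            "key_subnetwork_nodes": key.node_count,
            "key_subnetwork_edges": key.edge_count,
            "go_unannotated_targets": unannotated,
        }
    return stats


def stage_mirna(cfg: PipelineConfig) -> Dict[str, int]:
    """Target-mimicry scoring and precursor calls over the identified lncRNAs."""
    _require(cfg, "mirna_fasta")
    mirnas = hio.read_fasta(cfg.path(cfg.mirna_fasta))
    lnc_seqs = hio.read_fasta(cfg.out("lncrna.fa"))
    params = hmir.TargetScoringParams(penalty_threshold=cfg.penalty_threshold)
    hit_rows = []
    prec_rows = []
    for mid in sorted(mirnas):
        for lid in sorted(lnc_seqs):
            for h in hmir.score_mirna_target(
                mirnas[mid], lnc_seqs[lid], params, mirna_id=mid, lncrna_id=lid
            ):
                hit_rows.append(
                    {
                        "mirna_id": mid,
                        "lncrna_id": lid,
                        "site_start": h.site_start,
                        "penalty": h.penalty_score,
                        "gap_count": h.gap_count,
                        "mirna_line": h.alignment[0],
                        "match_line": h.alignment[1],
                        "site_line": h.alignment[2],
                    }
                )
            call = hmir.call_precursor(
                lnc_seqs[lid], mirnas[mid], window_pad=cfg.window_pad, lncrna_id=lid, mirna_id=mid
            )
            if call.is_precursor:
                prec_rows.append(
                    {
                        "lncrna_id": lid,
                        "mirna_id": mid,
                        "window_start": call.window[0],
                        "window_end": call.window[1],
                        "paired_mirna_fraction": round(call.paired_mirna_fraction, 6),
                        "structure": call.structure,
                    }
                )
    hits = pd.DataFrame(
        hit_rows,
        columns=["mirna_id", "lncrna_id", "site_start", "penalty", "gap_count", "mirna_line", "match_line", "site_line"],
    )
    precs = pd.DataFrame(
        prec_rows,
        columns=["lncrna_id", "mirna_id", "window_start", "window_end", "paired_mirna_fraction", "structure"],
    )
    hio.write_tsv(hits, cfg.out("mirna_hits.tsv"))
    hio.write_tsv(precs, cfg.out("mirna_precursors.tsv"))
    return {
        "n_hits": len(hits),
        "n_target_lncrnas": hits["lncrna_id"].nunique() if len(hits) else 0,
        "n_targeting_mirnas": hits["mirna_id"].nunique() if len(hits) else 0,
        "n_precursor_lncrnas": precs["lncrna_id"].nunique() if len(precs) else 0,
    }


def stage_report(cfg: PipelineConfig, target_stats=None, mirna_stats=None) -> dict:
    """One-shot JSON report aggregating all stage outputs."""
    transcripts, known, candidates = _load_catalog(cfg)
    lncrnas = hio.read_gtf(cfg.out("lncrna.gtf"))
    report_df = hio.read_tsv(cfg.out("filter_report.tsv"))
    fpkm = hio.read_tsv(cfg.out("fpkm.tsv"), index_col="transcript_id")
    de = hio.read_tsv(cfg.out("de.tsv"))
    add = hio.read_tsv(cfg.out("additivity.tsv"))
    tes = hio.read_bed(cfg.path(cfg.te_bed)) if os.path.exists(cfg.path(cfg.te_bed)) else []

    lnc_ids = [t.transcript_id for t in lncrnas]
    cat = hcat.catalog_statistics(
        lncrnas, fpkm, presence_threshold=cfg.presence_threshold, tes=tes
    )
    de_l = de[de["transcript_id"].isin(lnc_ids)]
    de_counts = {}
    for comp in de["comparison"].unique():
        sub = de_l[(de_l["comparison"] == comp) & de_l["significant"]]
        de_counts[comp] = {
            "n_de": len(sub),
            "n_up": int((sub["direction"] == "up").sum()),
            "n_down": int((sub["direction"] == "down").sum()),
            "total_abs_log2fc": round(float(sub["log2fc"].abs().sum()), 4),
        }
    de_union = (
        de_l[de_l["significant"] & de_l["comparison"].isin(HYBRID_COMPARISONS)]["transcript_id"].nunique()
    )
    bias = hexp.parental_bias_summary(de_l)
    add_l = add[add["transcript_id"].isin(lnc_ids)]
    nonadd = add_l[add_l["mode"] == "nonadditive"]
    n_down = int((nonadd["direction"] == "down").sum())
    rep_pct = {}
    for catname in ("paternal_higher", "maternal_higher", "parental_equal"):
        rep_pct[catname] = (
            round(100.0 * (nonadd["repression_category"] == catname).sum() / n_down, 4)
            if n_down
            else 0.0
        )
    clusters = add_l[add_l["pattern_cluster"] != "unassigned"]["pattern_cluster"].astype(str)
    report = {
        "thresholds": {
            "min_length": cfg.min_length,
            "min_coverage": cfg.min_coverage,
            "cpc_threshold": cfg.cpc_threshold,
            "cnci_threshold": cfg.cnci_threshold,
            "min_log2fc": cfg.min_log2fc,
            "alpha": cfg.alpha,
            "mpv_min_log2fc": cfg.mpv_min_log2fc,
            "max_cis_distance": cfg.max_cis_distance,
            "evalue_max": cfg.evalue_max,
            "identity_min": cfg.identity_min,
            "energy_max": cfg.energy_max,
            "penalty_threshold": cfg.penalty_threshold,
            "epsilon": cfg.epsilon,
            "presence_threshold": cfg.presence_threshold,
            "fdr": cfg.fdr,
        },
        "identification": {
            "input_candidates": int(report_df.set_index("stage").at["input", "count"]),
            "removed_short": int(report_df.set_index("stage").at["removed_short", "count"]),
            "removed_low_coverage": int(report_df.set_index("stage").at["removed_low_coverage", "count"]),
            "removed_coding": int(report_df.set_index("stage").at["removed_coding", "count"]),
            "n_lncrnas": len(lncrnas),
            "class_codes": {
                k: int(v)
                for k, v in sorted(pd.Series([t.class_code for t in lncrnas]).value_counts().items())
            },
        },
        "catalog": {
            "length_fraction_200_1000": round(cat.length_fraction_200_1000, 6),
            "length_fraction_gt_1000": round(cat.length_fraction_gt_1000, 6),
            "exon_fraction_le_1": round(cat.exon_fraction_le_1, 6),
            "te_overlap_count": cat.te_overlap_count,
            "presence_venn": cat.presence_partition,
            "n_expressed_per_sample": {
                s: int((fpkm.loc[fpkm.index.isin(lnc_ids), s] > cfg.presence_threshold).sum())
                for s in SAMPLES
            },
        },
        "differential_expression": {
            **de_counts,
            "n_de_union_hybrid_vs_parents": int(de_union),
            "bias_verdict": bias.bias_verdict,
        },
        "additivity": {
            "n_nonadditive": len(nonadd),
            "n_nonadditive_up": int((nonadd["direction"] == "up").sum()),
            "n_nonadditive_down": n_down,
            "repression_category_percent": rep_pct,
            "cluster_sizes": {str(k): int(v) for k, v in sorted(clusters.value_counts().items())},
        },
        "targets": target_stats or {},
        "mirna": mirna_stats or {},
    }
    with open(cfg.out("report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order and return the report dict."""
    stage_identify(cfg)
    stage_diffexp(cfg)
    stage_additivity(cfg)
    target_stats = stage_targets(cfg)
    mirna_stats = stage_mirna(cfg)
    return stage_report(cfg, target_stats=target_stats, mirna_stats=mirna_stats)
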