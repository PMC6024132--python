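"""Cis/trans pairing, duplex energies, networks and GO tallies."""

import numpy as np
import pandas as pd
import pytest

from hexalnc.seqs import revcomp_dna
from hexalnc.targets import (
    TargetPair,
    alignment_evalue,
    build_network,
    duplex_energy,
    find_cis_pairs,
    find_trans_pairs,
    go_term_tally,
    karlin_altschul_lambda,
    key_object_subnetwork,
    positional_relation,
    span_gap,
    stack_energy_table,
)

from conftest import make_transcript, oracle_smith_waterman


def _mrna(tid, exons, strand="+", chrom="chr1"):
    return make_transcript(tid, chrom=chrom, exons=exons, strand=strand, biotype="coding_known")


class TestCisPairs:
    def test_gap_under_100kb_pairs(self):
        lnc = make_transcript("l1", exons=[(0, 1000)])
        m = _mrna("m1", [(90_000, 95_000)])
        assert span_gap(lnc, m) == 89_000
        pairs = find_cis_pairs([lnc], [m], {"l1": "up", "m1": "up"})
        assert len(pairs) == 1 and pairs[0].distance == 89_000
        assert pairs[0].concordance == "same_trend"

    def test_distance_boundary_is_strict(self):
        lnc = make_transcript("l1", exons=[(0, 1000)])
        exactly = _mrna("m1", [(101_000, 102_000)])  # gap exactly 100,000
        assert find_cis_pairs([lnc], [exactly], {}) == []

    def test_different_chromosomes_never_pair(self):
        lnc = make_transcript("l1", chrom="chr1", exons=[(0, 1000)])
        m = _mrna("m1", [(500, 1500)], chrom="chr2")
        assert find_cis_pairs([lnc], [m], {}) == []

    def test_promoter_overlap_relation(self):
        # lncRNA inside the 2-kb window upstream of a + strand TSS
        m = _mrna("m1", [(10_000, 12_000)], strand="+")
        lnc = make_transcript("l1", exons=[(8_500, 9_500)])
        assert positional_relation(lnc, m) == "promoter_overlap"
        # for a - strand gene the promoter sits on the other side
        m2 = _mrna("m2", [(10_000, 12_000)], strand="-")
        lnc2 = make_transcript("l2", exons=[(12_500, 13_000)])
        assert positional_relation(lnc2, m2) == "promoter_overlap"

    def test_containing_locus_and_updownstream(self):
        m = _mrna("m1", [(10_000, 12_000)], strand="+")
        assert positional_relation(make_transcript("a", exons=[(11_000, 11_500)]), m) == "containing_locus"
        assert positional_relation(make_transcript("b", exons=[(1_000, 2_000)]), m) == "upstream"
        assert positional_relation(make_transcript("c", exons=[(20_000, 21_000)]), m) == "downstream"
        m_neg = _mrna("m2", [(10_000, 12_000)], strand="-")
        assert positional_relation(make_transcript("d", exons=[(1_000, 2_000)]), m_neg) == "downstream"

    def test_matches_all_pairs_bruteforce(self, rng):
        lncs, mrnas = [], []
        for i in range(60):
            c = f"chr{1 + i % 3}"
            s = int(rng.integers(0, 400_000))
            lncs.append(make_transcript(f"l{i}", chrom=c, exons=[(s, s + 500)]))
            s2 = int(rng.integers(0, 400_000))
            mrnas.append(_mrna(f"m{i}", [(s2, s2 + 2000)], chrom=f"chr{1 + (i + 1) % 3}"))
        dirs = {t.transcript_id: "up" for t in lncs + mrnas}
        got = {(p.lncrna_id, p.mrna_id) for p in find_cis_pairs(lncs, mrnas, dirs)}
        want = set()
        for l in lncs:
            for m in mrnas:
                g = span_gap(l, m)
                if g is not None and g < 100_000:
                    want.add((l.transcript_id, m.transcript_id))
        assert got == want


class TestTransPairs:
    def test_planted_revcomp_window_pairs(self, rng):
        lnc = "".join(rng.choice(list("ACGT"), size=60))
        mrna = (
            "".join(rng.choice(list("ACGT"), size=200))
            + revcomp_dna(lnc)
            + "".join(rng.choice(list("ACGT"), size=200))
        )
        pairs = find_trans_pairs({"l1": lnc}, {"m1": mrna}, {"l1": "up", "m1": "down"})
        assert len(pairs) == 1
        p = pairs[0]
        assert p.identity == 1.0
        assert p.alignment_evalue <= 1e-5
        assert p.duplex_energy <= -30
        assert p.concordance == "opposite_trend"

    def test_random_sequences_never_pair(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=500))
            b = "".join(rng.choice(list("ACGT"), size=500))
            assert find_trans_pairs({"l": a}, {"m": b}) == []

    def test_missing_sequence_raises(self):
        with pytest.raises(ValueError, match="l1"):
            find_trans_pairs({"l1": ""}, {"m1": "ACGT" * 100})

    def test_alignment_score_matches_smith_waterman_oracle(self, rng):
        from hexalnc.targets import _make_aligner

        aligner = _make_aligner()
        for _ in range(6):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(40, 200))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(40, 200))))
            assert aligner.score(a, b) == pytest.approx(oracle_smith_waterman(a, b))

    def test_karlin_altschul_lambda_solves_the_identity(self):
        lam = karlin_altschul_lambda()
        assert 0.25 * np.exp(lam) + 0.75 * np.exp(-2 * lam) == pytest.approx(1.0)
        # E-values decay with score and grow with search space
        assert alignment_evalue(30, 100, 100) < alignment_evalue(20, 100, 100)
        assert alignment_evalue(20, 1000, 1000) > alignment_evalue(20, 100, 100)


class TestDuplexEnergy:
    def test_fully_mismatched_windows_are_unstable(self):
        assert duplex_energy("AAAA", "AAAA") >= 0

    def test_gc_duplex_sums_nine_gc_stack_terms(self):
        top = "GCGCGCGCGC"
        bottom = "CGCGCGCGCG"  # complement read 3'->5'
        table = stack_energy_table()
        expected = sum(
            table[(top[i] + bottom[i], top[i + 1] + bottom[i + 1])] for i in range(9)
        )
        assert duplex_energy(top, bottom) == pytest.approx(expected)

    def test_internal_mismatch_destabilizes(self):
        top = "GCGCGCGCGC"
        bottom = "CGCGCGCGCG"
        broken = bottom[:4] + "A" + bottom[5:]
        assert duplex_energy(top, broken) > duplex_energy(top, bottom)

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            duplex_energy("", "")

    def test_gu_pairs_stack_mildly(self):
        # G:U-containing steps use the single wobble term
        e = duplex_energy("GG", "UC")  # G:U then G:C
        assert e == pytest.approx(-1.0)


class TestNetworks:
    def _pairs(self, spec):
        return [
            TargetPair(lncrna_id=l, mrna_id=m, mode="cis", concordance=c) for l, m, c in spec
        ]

    def test_node_and_edge_counts(self):
        net = build_network(
            self._pairs([("l1", "m1", "same_trend"), ("l1", "m2", "same_trend"), ("l2", "m1", "same_trend")]),
            {"l1": "up", "l2": "up", "m1": "up", "m2": "up"},
        )
        assert (net.node_count, net.edge_count) == (4, 3)
        assert net.same_trend_fraction == 1.0

    def test_planted_concordance_fraction(self):
        spec = [(f"l{i}", f"m{i}", "same_trend") for i in range(10)]
        spec += [(f"l{i}x", f"m{i}x", "opposite_trend") for i in range(2)]
        net = build_network(self._pairs(spec), {})
        assert net.same_trend_fraction == pytest.approx(10 / 12)

    def test_statistics_invariant_under_relabeling(self):
        spec = [("l1", "m1", "same_trend"), ("l2", "m1", "opposite_trend")]
        net1 = build_network(self._pairs(spec), {})
        relabeled = [("zz_" + l, "zz_" + m, c) for l, m, c in spec]
        net2 = build_network(self._pairs(relabeled), {})
        assert (net1.node_count, net1.edge_count, net1.same_trend_fraction) == (
            net2.node_count,
            net2.edge_count,
            net2.same_trend_fraction,
        )

    def test_key_subnetwork_star(self):
        net = build_network(
            self._pairs([("hub", "m1", "same_trend"), ("hub", "m2", "same_trend"), ("hub", "m3", "same_trend")]),
            {},
        )
        sub = key_object_subnetwork(net)
        assert sub.node_count == 4 and sub.edge_count == 3

    def test_all_degree_one_gives_empty_subnetwork(self):
        net = build_network(self._pairs([("l1", "m1", "same_trend"), ("l2", "m2", "same_trend")]), {})
        sub = key_object_subnetwork(net)
        assert sub.node_count == 0 and sub.edge_count == 0

    def test_key_subnetwork_matches_degree_filter_oracle(self, rng):
        spec = []
        for i in range(40):
            l = f"l{int(rng.integers(0, 12))}"
            m = f"m{int(rng.integers(0, 12))}"
            spec.append((l, m, "same_trend"))
        net = build_network(self._pairs(spec), {})
        sub = key_object_subnetwork(net, min_degree=2)
        g = net.graph
        keys = {n for n, d in g.nodes(data=True) if d["kind"] == "lncRNA" and g.degree(n) >= 2}
        want = set(keys)
        for k in keys:
            want |= set(g.neighbors(k))
        assert set(sub.graph.nodes) == want


class TestGoTally:
    def _ann(self):
        return pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g2", "g3"],
                "ontology": ["biological_process"] * 3 + ["molecular_function"],
                "term": ["metabolic process", "metabolic process", "binding", "binding"],
            }
        )

    def test_empty_target_set(self):
        tally, unannotated = go_term_tally([], self._ann())
        assert tally.empty and unannotated == 0

    def test_shared_term_counts_both_genes(self):
        tally, _ = go_term_tally(["g1", "g2"], self._ann())
        row = tally[tally["term"] == "metabolic process"].iloc[0]
        assert row["count"] == 2 and row["gene_percent"] == pytest.approx(100.0)

    def test_unannotated_targets_counted_separately(self):
        tally, unannotated = go_term_tally(["g1", "gX"], self._ann())
        assert unannotated == 1

    def test_counts_match_pandas_oracle_on_bundle(self, default_bundle):
        go = default_bundle.go_annotation
        genes = sorted(set(go["gene_id"]))[:20]
        tally, _ = go_term_tally(genes, go)
        oracle = (
            go[go["gene_id"].isin(genes)]
            .drop_duplicates()
            .groupby(["ontology", "term"])
            .size()
        )
        for _, r in tally.iterrows():
            assert oracle[(r["ontology"], r["term"])] == r["count"]

    def test_malformed_rows_are_skipped(self):
        ann = self._ann()
        ann.loc[len(ann)] = [None, "biological_process", "metabolic process"]
        tally, _ = go_term_tally(["g1"], ann)
        assert tally["count"].sum() == 1
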