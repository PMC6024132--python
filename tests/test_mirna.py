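"""Penalty scoring, Nussinov folding and precursor calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hexalnc.mirna import (
    TargetScoringParams,
    call_precursor,
    nussinov_fold,
    pairs_from_dotbracket,
    penalty_from_alignment,
    score_mirna_target,
)
from hexalnc.seqs import revcomp_rna

from conftest import oracle_max_pairs

MIR = "UGACCUGAAGCUCAAUGGACU"  # 21 nt, G at position 20


def _perfect_site(mir: str) -> str:
    return revcomp_rna(mir)


def _embed(site: str, rng, flank=40) -> str:
    left = "".join(rng.choice(list("ACGU"), size=flank))
    right = "".join(rng.choice(list("ACGU"), size=flank))
    return left + site + right


class TestTargetScoring:
    def test_perfect_complement_scores_zero(self, rng):
        lnc = _embed(_perfect_site(MIR), rng)
        hits = score_mirna_target(MIR, lnc)
        assert any(h.site_start == 40 and h.penalty_score == 0.0 for h in hits)

    def test_tail_wobble_costs_half(self, rng):
        site = list(_perfect_site(MIR))
        # G:U wobble at miRNA position 18 (outside the essential region)
        p = 18
        assert MIR[p - 1] == "G"
        site[len(MIR) - p] = "U"
        lnc = _embed("".join(site), rng)
        hits = [h for h in score_mirna_target(MIR, lnc) if h.site_start == 40]
        assert hits and hits[0].penalty_score == pytest.approx(0.5)

    def test_essential_mismatches_cost_double(self, rng):
        site = list(_perfect_site(MIR))
        for p in (5, 9):  # essential positions: mismatch cost 1.0 x 2
            site[len(MIR) - p] = MIR[p - 1]
        lnc = _embed("".join(site), rng)
        assert not [h for h in score_mirna_target(MIR, lnc) if h.site_start == 40]
        loose = TargetScoringParams(penalty_threshold=10.0)
        hits = [h for h in score_mirna_target(MIR, lnc, loose) if h.site_start == 40]
        assert hits and hits[0].penalty_score == pytest.approx(4.0)

    def test_mirna_length_bounds(self):
        with pytest.raises(ValueError):
            score_mirna_target("ACGU" * 3, "ACGU" * 30)

    def test_non_nucleotide_raises(self):
        with pytest.raises(ValueError):
            score_mirna_target(MIR, "N" * 100)

    def test_hits_stable_under_flank_extension(self, rng):
        core = _embed(_perfect_site(MIR), rng, flank=10)
        extended = "".join(rng.choice(list("ACGU"), size=50)) + core
        h1 = [h for h in score_mirna_target(MIR, core) if h.penalty_score == 0.0]
        h2 = [h for h in score_mirna_target(MIR, extended) if h.penalty_score == 0.0]
        assert len(h1) == len(h2) == 1
        assert h2[0].site_start == h1[0].site_start + 50

    def test_match_to_mismatch_never_lowers_penalty(self, rng):
        loose = TargetScoringParams(penalty_threshold=100.0)
        site = _perfect_site(MIR)
        lnc = _embed(site, rng)
        base = [h for h in score_mirna_target(MIR, lnc, loose) if h.site_start == 40][0]
        for pos in range(40, 40 + len(site), 4):
            mutated = lnc[:pos] + ("C" if lnc[pos] != "C" else "A") + lnc[pos + 1 :]
            hits = [h for h in score_mirna_target(MIR, mutated, loose) if h.site_start == 40]
            assert hits[0].penalty_score >= base.penalty_score

    def test_planted_bundle_sites_score_their_planted_penalties(self, default_bundle):
        tm = default_bundle.truth.mirna
        seqs = {t.transcript_id: t.sequence for t in default_bundle.annotation.transcripts}
        targets = tm[tm["kind"] == "target"]
        assert len(targets) > 0
        for r in targets.itertuples():
            hits = score_mirna_target(
                default_bundle.mirnas[r.mirna_id], seqs[r.lncrna_id], mirna_id=r.mirna_id
            )
            match = [h for h in hits if h.site_start == r.position]
            assert match, (r.lncrna_id, r.mirna_id)
            assert match[0].penalty_score == pytest.approx(r.planted_penalty)

    def test_alignment_triple_reconstructs_penalty(self, default_bundle):
        tm = default_bundle.truth.mirna
        seqs = {t.transcript_id: t.sequence for t in default_bundle.annotation.transcripts}
        for r in tm[tm["kind"] == "target"].itertuples():
            for h in score_mirna_target(default_bundle.mirnas[r.mirna_id], seqs[r.lncrna_id]):
                assert penalty_from_alignment(h.alignment) == pytest.approx(h.penalty_score)

    def test_gap_variants_respect_the_placement_rules(self, rng):
        loose = TargetScoringParams(penalty_threshold=100.0)
        lnc = _embed(_perfect_site(MIR), rng)
        for h in score_mirna_target(MIR, lnc, loose):
            assert h.gap_count <= 1
            # no gap column may touch miRNA positions 1..17
            top, _, bottom = h.alignment
            pos = 0
            for m, t in zip(top, bottom):
                if m != "-":
                    pos += 1
                if t == "-":  # unpaired miRNA base: only past position 17
                    assert pos > 17
                if m == "-":  # target bulge between miRNA positions pos and pos+1
                    assert pos >= 17


class TestNussinov:
    def test_unpairable_sequence(self):
        assert nussinov_fold("AAAAAAAA") == ("........", 0)

    def test_gc_hairpin(self):
        structure, n = nussinov_fold("GGGAAAACCC")
        assert n == 3
        assert structure == "(((....)))"

    def test_dotbracket_is_balanced_and_loops_are_legal(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(10, 40))))
            structure, n = nussinov_fold(seq)
            partners = pairs_from_dotbracket(structure)
            assert len(partners) == 2 * n
            for i, j in partners.items():
                if i < j:
                    assert j - i > 3  # min loop

    def test_matches_enumeration_oracle_on_short_sequences(self, rng):
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(4, 17))))
            _, n = nussinov_fold(seq)
            assert n == oracle_max_pairs(seq)

    @given(st.text(alphabet="ACGU", min_size=1, max_size=14))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_pair_count_equals_oracle_property(self, seq):
        _, n = nussinov_fold(seq)
        assert n == oracle_max_pairs(seq)

    def test_rejects_non_rna(self):
        with pytest.raises(ValueError):
            nussinov_fold("ACGX")


class TestPrecursor:
    def test_planted_insert_is_called_with_full_stem(self, rng):
        mir = MIR
        insert = mir + "A" * 8 + revcomp_rna(mir)
        host = _embed(insert, rng, flank=30)
        call = call_precursor(host, mir)
        assert call.is_precursor
        assert call.paired_mirna_fraction == 1.0

    def test_missing_occurrence_short_circuits(self):
        call = call_precursor("ACGU" * 100, MIR)
        assert not call.is_precursor and call.structure == ""

    def test_external_fold_hook(self, rng):
        mir = MIR
        insert = mir + "A" * 8 + revcomp_rna(mir)
        host = _embed(insert, rng, flank=5)

        def fake_fold(seq):
            return "." * len(seq), 0  # an external predictor that pairs nothing

        call = call_precursor(host, mir, fold=fake_fold)
        assert not call.is_precursor

    def test_bundle_precursors_recalled(self, default_bundle):
        tm = default_bundle.truth.mirna
        seqs = {t.transcript_id: t.sequence for t in default_bundle.annotation.transcripts}
        prec = tm[tm["kind"] == "precursor"]
        assert len(prec) > 0
        for r in prec.itertuples():
            call = call_precursor(seqs[r.lncrna_id], default_bundle.mirnas[r.mirna_id])
            assert call.is_precursor
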