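"""FPKM, the conditional binomial DE test, MPV classification, clusters and bias."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hexalnc.expression import (
    BiasSummary,
    DifferentialResult,
    assign_pattern_cluster,
    classify_additivity,
    classify_repressed_category,
    compute_fpkm,
    differential_table,
    differential_test,
    fpkm_table,
    parental_bias_summary,
)

LIB = 1e7
LIBS = {"A": LIB, "BC": LIB, "ABC": LIB}


def _binomial_two_sided_oracle(k: int, n: int, p: float) -> float:
    """Direct enumeration: sum of pmf over outcomes no more likely than k."""
    pmf = stats.binom.pmf(np.arange(n + 1), n, p)
    return float(pmf[pmf <= pmf[k] * (1 + 1e-9)].sum())


class TestFpkm:
    def test_closed_form_values(self):
        assert compute_fpkm(0, 1000, 1e7) == 0.0
        assert compute_fpkm(100, 1000, 1e7) == pytest.approx(10.0)

    @given(
        count=st.integers(1, 10_000),
        length=st.integers(200, 5000),
        lib=st.integers(10**6, 10**8),
        k=st.integers(2, 10),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, count, length, lib, k):
        assert compute_fpkm(count, length, lib) == pytest.approx(
            compute_fpkm(count * k, length, lib * k)
        )

    def test_zero_length_or_library_raise(self):
        with pytest.raises(ValueError):
            compute_fpkm(1, 0, 1e7)
        with pytest.raises(ValueError):
            compute_fpkm(1, 1000, 0)

    def test_table_matches_scalar_form(self):
        counts = pd.DataFrame({"A": [10, 0], "BC": [5, 7], "ABC": [1, 2]}, index=["t1", "t2"])
        lengths = {"t1": 500, "t2": 1500}
        out = fpkm_table(counts, lengths, LIBS)
        for t in counts.index:
            for s in counts.columns:
                assert out.at[t, s] == pytest.approx(compute_fpkm(counts.at[t, s], lengths[t], LIB))


class TestDifferentialTest:
    def test_symmetry_of_equal_counts(self):
        r = differential_test(50, 50, LIB, LIB, 1000)
        assert r.log2fc == 0.0 and not r.significant and r.direction == "ns"

    def test_eightfold_change_is_significant(self):
        r = differential_test(80, 10, LIB, LIB, 1000)
        assert r.log2fc == pytest.approx(3.0, abs=0.02)  # pseudo-FPKM floor shifts it slightly
        assert r.p_value == pytest.approx(_binomial_two_sided_oracle(80, 90, 0.5), rel=1e-6)
        assert r.significant and r.direction == "up"

    def test_small_fold_change_never_significant(self):
        r = differential_test(3, 2, LIB, LIB, 1000)
        assert abs(r.log2fc) < 1 and not r.significant

    def test_both_zero_counts(self):
        r = differential_test(0, 0, LIB, LIB, 1000)
        assert (r.log2fc, r.p_value, r.direction) == (0.0, 1.0, "ns")

    @given(x=st.integers(0, 500), y=st.integers(0, 500))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_antisymmetry_under_sample_swap(self, x, y):
        a = differential_test(x, y, LIB, 2 * LIB, 800)
        b = differential_test(y, x, 2 * LIB, LIB, 800)
        assert a.log2fc == pytest.approx(-b.log2fc)
        assert a.p_value == pytest.approx(b.p_value)

    def test_unequal_libraries_shift_the_null(self):
        # same counts, 3x library: concentration differs, p reflects exposure
        r = differential_test(300, 100, LIB, LIB / 3, 1000)
        assert not r.significant  # 300 vs 100 at 3:1 exposure is the null ratio


class TestAdditivity:
    def test_hybrid_at_mpv_is_additive(self):
        r = classify_additivity(100, 300, 200, LIBS, 1000)
        assert r.mode == "additive" and r.log2_dev == pytest.approx(0.0, abs=0.01)

    def test_fourfold_above_mpv_is_nonadditive_up(self):
        # FPKM A=10, BC=30, ABC=80 at length 1 kb, lib 1e7 -> counts 100/300/800
        r = classify_additivity(100, 300, 800, LIBS, 1000)
        assert r.mpv == pytest.approx(20.0)
        assert r.log2_dev == pytest.approx(2.0, abs=0.01)
        assert r.mode == "nonadditive" and r.direction == "up"

    def test_small_deviation_is_additive(self):
        r = classify_additivity(100, 300, 250, LIBS, 1000)  # 25 vs MPV 20
        assert abs(r.log2_dev) < 1 and r.mode == "additive"


class TestRepression:
    def _call(self, direction="down"):
        r = classify_additivity(800, 100, 40, LIBS, 1000)
        assert r.mode == "nonadditive" and r.direction == "down"
        return r

    def _de(self, direction, significant=True):
        return DifferentialResult("t", "BC_vs_A", -3.0 if direction == "down" else 3.0, 0.001, significant, direction if significant else "ns")

    def test_three_categories(self):
        call = self._call()
        assert classify_repressed_category(call, self._de("down")) == "paternal_higher"
        assert classify_repressed_category(call, self._de("up")) == "maternal_higher"
        assert classify_repressed_category(call, self._de("up", significant=False)) == "parental_equal"

    def test_rejects_non_repressed_calls(self):
        up = classify_additivity(100, 300, 800, LIBS, 1000)
        with pytest.raises(ValueError):
            classify_repressed_category(up, self._de("up"))


class TestPatternClusters:
    def _de(self, comp, direction):
        sig = direction in ("up", "down")
        return DifferentialResult("t", comp, {"up": 3.0, "down": -3.0}.get(direction, 0.0), 0.001 if sig else 0.9, sig, direction)

    @pytest.mark.parametrize(
        "dir_a,dir_bc,expected",
        [
            ("up", "up", "1"),
            ("down", "down", "2"),
            ("up", "down", "3"),
            ("down", "up", "4"),
            ("up", "ns", "unassigned"),
        ],
    )
    def test_direction_rule_table(self, dir_a, dir_bc, expected):
        got = assign_pattern_cluster(
            self._de("ABC_vs_A", dir_a), self._de("ABC_vs_BC", dir_bc), True, True, True
        )
        assert got == expected

    def test_presence_takes_precedence(self):
        # expressed only in BC -> cluster 5 regardless of test directions
        got = assign_pattern_cluster(self._de("ABC_vs_A", "ns"), self._de("ABC_vs_BC", "down"), False, True, False)
        assert got == "5"
        got = assign_pattern_cluster(self._de("ABC_vs_A", "down"), self._de("ABC_vs_BC", "ns"), True, False, False)
        assert got == "6"

    def test_intermediate_pattern_from_counts(self):
        # FPKM BC=100 > ABC=30 > A=1 with both comparisons significant -> cluster 3
        de_a = differential_test(300, 10, LIB, LIB, 1000, comparison="ABC_vs_A")
        de_bc = differential_test(300, 1000, LIB, LIB, 1000, comparison="ABC_vs_BC")
        assert de_a.direction == "up" and de_bc.direction == "down"
        assert assign_pattern_cluster(de_a, de_bc, True, True, True) == "3"


class TestBiasSummary:
    def _de_frame(self, rows):
        return pd.DataFrame(rows, columns=["transcript_id", "comparison", "log2fc", "p_value", "significant", "direction"])

    def test_identical_comparisons_are_balanced(self):
        rows = [(f"t{i}", c, 2.0, 0.01, True, "up") for i in range(5) for c in ("ABC_vs_A", "ABC_vs_BC")]
        assert parental_bias_summary(self._de_frame(rows)).bias_verdict == "balanced"

    def test_empty_de_sets(self):
        s = parental_bias_summary(self._de_frame([]))
        assert s.bias_verdict == "balanced"
        assert (s.per_comparison["total_abs_log2fc"] == 0).all()

    def test_larger_maternal_divergence_reads_paternal_biased(self):
        rows = [(f"t{i}", "ABC_vs_BC", 3.0, 0.001, True, "up") for i in range(8)]
        rows += [(f"t{i}", "ABC_vs_A", 2.0, 0.001, True, "up") for i in range(3)]
        assert parental_bias_summary(self._de_frame(rows)).bias_verdict == "paternal_biased"

    def test_planted_bundle_is_paternal_biased(self, default_bundle):
        b = default_bundle
        lnc = b.truth.transcripts.query("is_lncrna").index
        de = differential_table(
            b.expression.counts.loc[lnc],
            {k: v for k, v in b.expression.lengths.items()},
            b.expression.library_sizes,
        )
        assert parental_bias_summary(de).bias_verdict == "paternal_biased"
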