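import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tarpair.diffexpr import (
    DEThresholds,
    ac_test,
    bh_adjust,
    compare_overlap,
    log2_fold_change,
    run_de,
)
from tarpair.expression import compute_fpkm
from tarpair.formats import ValidationError

from conftest import make_counts, make_record


def ac_oracle(x, y, N1, N2):
    """Direct log-space summation of the exact-test mass function
    p(y'|x) = (N2/N1)^y' (x+y')! / (x! y'! (1+N2/N1)^(x+y'+1)),
    two-sided over both conditioning orientations."""

    def logpmf(k, n, r):
        return (k * math.log(r) + math.lgamma(n + k + 1) - math.lgamma(n + 1)
                - math.lgamma(k + 1) - (n + k + 1) * math.log1p(r))

    def lower(n, k, r):
        return sum(math.exp(logpmf(j, n, r)) for j in range(k + 1))

    r12, r21 = N2 / N1, N1 / N2
    tails = [
        lower(x, y, r12),
        1.0 - (lower(x, y - 1, r12) if y > 0 else 0.0),
        lower(y, x, r21),
        1.0 - (lower(y, x - 1, r21) if x > 0 else 0.0),
    ]
    return min(1.0, 2.0 * min(tails))


class TestAcTest:
    @pytest.mark.parametrize("N1,N2", [(1e6, 1e6), (1e6, 2.5e6)])
    def test_matches_summation_oracle_small_grid(self, N1, N2):
        for x in range(0, 61, 3):
            for y in range(0, 61 - x, 3):
                assert ac_test(x, y, N1, N2) == pytest.approx(
                    ac_oracle(x, y, N1, N2), abs=1e-9)

    def test_equal_counts_equal_libraries_not_significant(self):
        assert ac_test(0, 0, 1e6, 1e6) == pytest.approx(1.0)
        assert ac_test(100, 100, 1e6, 1e6) > 0.9

    def test_extreme_difference_tiny_p(self):
        assert ac_test(0, 50, 1e6, 1e6) < 1e-10

    @settings(derandomize=True, max_examples=200)
    @given(x=st.integers(0, 500), y=st.integers(0, 500),
           n1=st.integers(1, 10**7), n2=st.integers(1, 10**7))
    def test_symmetric_and_valid(self, x, y, n1, n2):
        p = ac_test(x, y, n1, n2)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(ac_test(y, x, n2, n1), rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ac_test(-1, 0, 1, 1)


class TestLog2FoldChange:
    @pytest.mark.parametrize("a,b,pseudo,expected", [
        (10, 10, 0, 0.0), (10, 20, 0, 1.0), (0, 0, 0.01, 0.0)])
    def test_examples(self, a, b, pseudo, expected):
        assert log2_fold_change(a, b, pseudo) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100)
    @given(a=st.floats(0, 1e6), b=st.floats(0, 1e6))
    def test_antisymmetric_under_swap(self, a, b):
        assert log2_fold_change(a, b, 0.01) == pytest.approx(
            -log2_fold_change(b, a, 0.01), abs=1e-9)

    def test_zero_means_without_pseudocount_rejected(self):
        with pytest.raises(ValidationError):
            log2_fold_change(0, 0, 0)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_hand_evaluated_step_up(self):
        # m=3: q(3)=0.03; q(2)=min(3*0.02/2, 0.03)=0.03; q(1)=min(3*0.01, 0.03)=0.03
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_and_never_below_p(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12) and np.all(q <= 1.0 + 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


def annotation_for(cm, length=1000):
    return [make_record(tid=t, start=1, end=length, exons=[(1, length)])
            for t in cm.transcript_ids]


class TestRunDe:
    def test_identical_groups_all_ns(self):
        cm = make_counts(np.full((5, 4), 50), library_size=10**6)
        expr = compute_fpkm(cm, annotation_for(cm))
        de = run_de(cm, expr, "A", "B")
        assert all(r.tier == "ns" and r.log2fc == 0 and r.direction == "none" for r in de)

    def test_single_extreme_transcript_is_the_only_significant(self):
        counts = np.full((10, 4), 50)
        counts[3, 2:] = 800
        cm = make_counts(counts, library_size=10**6)
        expr = compute_fpkm(cm, annotation_for(cm))
        de = run_de(cm, expr, "A", "B")
        sig = [r.transcript_id for r in de if r.tier == "significant"]
        assert sig == ["T3"]
        assert next(r for r in de if r.transcript_id == "T3").direction == "up"

    def test_swapping_groups_flips_direction_keeps_p(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(100, size=(20, 6))
        counts[0, 3:] *= 8
        cm = make_counts(counts, groups=("A", "A", "A", "B", "B", "B"),
                         library_size=10**6)
        expr = compute_fpkm(cm, annotation_for(cm))
        fwd = run_de(cm, expr, "A", "B")
        rev = run_de(cm, expr, "B", "A")
        for f, r in zip(fwd, rev):
            assert f.p_value == pytest.approx(r.p_value, rel=1e-12)
            assert f.log2fc == pytest.approx(-r.log2fc, abs=1e-9)

    def test_planted_fold_change_detected(self):
        # planted log2FC 3 at baseline 200 with 6+6 Poisson replicates
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            counts = rng.poisson(200, size=(50, 12))
            counts[0, 6:] = rng.poisson(200 * 8, size=6)
            cm = make_counts(counts, groups=("A",) * 6 + ("B",) * 6, library_size=10**6)
            expr = compute_fpkm(cm, annotation_for(cm))
            de = run_de(cm, expr, "A", "B")
            hits += de[0].tier == "significant"
        assert hits >= 9

    def test_empty_group_rejected(self):
        cm = make_counts(np.full((2, 2), 5), groups=("A", "A"), library_size=10)
        expr = compute_fpkm(cm, annotation_for(cm))
        with pytest.raises(ValidationError):
            run_de(cm, expr, "A", "B")

    def test_tier_invariants_hold(self, sim_counts, sim_annotation):
        expr = compute_fpkm(sim_counts, sim_annotation[0])
        th = DEThresholds()
        for r in run_de(sim_counts, expr, "control", "mutant", th):
            assert r.fdr >= r.p_value - 1e-12
            if r.tier == "significant":
                assert (r.fold_change >= th.fc_min or r.fold_change <= 1 / th.fc_min)
                assert r.fdr <= th.fdr_max
            if r.tier == "candidate":
                assert r.p_value < th.p_max and abs(r.log2fc) >= th.abs_log2fc_min


class TestCompareOverlap:
    def make(self, ids, tier="significant"):
        from tarpair.diffexpr import DEResult
        return [DEResult(t, 1, 2, 2, 1, 0.001, 0.001, tier, "up") for t in ids]

    def test_identical_lists(self):
        de = self.make(["a", "b"])
        assert compare_overlap(de, de) == (0, 2, 0)

    def test_disjoint_lists(self):
        assert compare_overlap(self.make(list("abc")), self.make(list("defg"))) == (3, 0, 4)

    def test_partial_overlap(self):
        assert compare_overlap(self.make(list("abc")), self.make(list("bcd"))) == (1, 2, 1)

    def test_tier_or_better_semantics(self):
        a = self.make(["a"], "significant") + self.make(["b"], "candidate")
        b = self.make(["a"], "candidate") + self.make(["b"], "ns")
        assert compare_overlap(a, b, tier="significant") == (1, 0, 0)
        assert compare_overlap(a, b, tier="candidate") == (1, 1, 0)
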