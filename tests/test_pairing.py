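import math

import numpy as np
import pytest
from scipy import stats

from tarpair.diffexpr import DEResult
from tarpair.expression import ExpressionMatrix
from tarpair.formats import ValidationError
from tarpair.pairing import (
    TargetPair,
    build_tarpairs,
    candidate_pairs,
    classify_cis_trans,
    correlate,
    read_energy_table,
    refine_tarpairs,
    span_distance,
)

from conftest import make_record


def expr_from(matrix, ids):
    matrix = np.asarray(matrix, float)
    samples = [f"s_{j}" for j in range(matrix.shape[1])]
    return ExpressionMatrix(
        transcript_ids=list(ids), sample_ids=samples, fpkm=matrix,
        effective_length={t: 1000 for t in ids},
        group_of={s: "g" for s in samples},
    )


class TestCorrelate:
    def test_identity(self):
        assert correlate([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx((1.0, 1.0))

    def test_reversal(self):
        assert correlate([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx((-1.0, -1.0))

    def test_monotone_nonlinear(self):
        pearson, spearman = correlate([1, 2, 3, 4], [1, 4, 9, 16])
        assert spearman == pytest.approx(1.0)
        assert pearson == pytest.approx(25 / math.sqrt(645))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            correlate([1, 1, 1], [1, 2, 3])


class TestCandidatePairs:
    def brute_force(self, expr, lnc_ids, mrna_ids, rho_min):
        out = []
        ef = expr.to_frame()
        for l in lnc_ids:
            for m in mrna_ids:
                p = stats.pearsonr(ef.loc[l], ef.loc[m]).statistic
                s = stats.spearmanr(ef.loc[l], ef.loc[m]).statistic
                if p >= rho_min and s >= rho_min:
                    out.append((l, m, p, s))
        return out

    def test_perfectly_tracking_pair_found(self):
        base = np.array([1.0, 5, 2, 8, 3, 9])
        expr = expr_from([base, base * 2], ["L0", "M0"])
        (hit,) = candidate_pairs(expr, ["L0"], ["M0"])
        assert hit[:2] == ("L0", "M0")
        assert hit[2] == pytest.approx(1.0) and hit[3] == pytest.approx(1.0)

    @pytest.mark.parametrize("rho_min", [0.3, 0.6])
    def test_equals_brute_force_double_loop(self, rho_min):
        rng = np.random.default_rng(12)
        mat = rng.poisson(20, size=(20, 6)).astype(float)
        mat += rng.normal(0, 0.01, mat.shape)  # break rank ties
        lnc_ids = [f"L{i}" for i in range(10)]
        mrna_ids = [f"M{i}" for i in range(10)]
        expr = expr_from(mat, lnc_ids + mrna_ids)
        got = candidate_pairs(expr, lnc_ids, mrna_ids, rho_min)
        expected = sorted(self.brute_force(expr, lnc_ids, mrna_ids, rho_min))
        assert [g[:2] for g in got] == [e[:2] for e in expected]
        for g, e in zip(got, expected):
            assert g[2] == pytest.approx(e[2], abs=1e-9)
            assert g[3] == pytest.approx(e[3], abs=1e-9)

    def test_impossible_threshold_empty(self):
        expr = expr_from(np.arange(8.0).reshape(2, 4), ["L0", "M0"])
        assert candidate_pairs(expr, ["L0"], ["M0"], rho_min=1.01) == []

    def test_overlapping_id_sets_rejected(self):
        expr = expr_from(np.arange(8.0).reshape(2, 4), ["X", "Y"])
        with pytest.raises(ValidationError):
            candidate_pairs(expr, ["X"], ["X"])


class TestClassifyCisTrans:
    def test_upstream_gap_within_window(self):
        mrna = make_record("M", start=5000, end=8000, strand="+")
        lnc = make_record("L", start=1000, end=2000)
        assert classify_cis_trans(lnc, mrna) == "cis"
        assert span_distance(lnc, mrna) == 3000

    def test_inclusive_boundary_at_exactly_10kb(self):
        mrna = make_record("M", start=50000, end=52000, strand="+")
        lnc = make_record("L", start=39000, end=40000)
        assert classify_cis_trans(lnc, mrna) == "cis"
        assert classify_cis_trans(make_record("L", start=39000, end=39999), mrna) == "rejected"

    def test_different_chromosome_with_energy_is_trans(self):
        mrna = make_record("M", chrom="chr1", start=5000, end=8000)
        lnc = make_record("L", chrom="chr2", start=5000, end=6000)
        assert classify_cis_trans(lnc, mrna, energy=-40, energy_max=-30) == "trans"
        assert classify_cis_trans(lnc, mrna, energy=-20, energy_max=-30) == "rejected"
        assert classify_cis_trans(lnc, mrna) == "rejected"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_equals_interval_oracle_over_placements(self, strand):
        # 200 kb toy chromosome, mRNA fixed mid-chromosome, lncRNA slid across
        mrna = make_record("M", start=100_000, end=102_000, strand=strand)
        up, down = 10_000, 20_000
        if strand == "+":
            lo, hi = mrna.start - up, mrna.end + down
        else:
            lo, hi = mrna.start - down, mrna.end + up
        for start in range(1, 200_000 - 999, 499):
            lnc = make_record("L", start=start, end=start + 999)
            expected = "cis" if (start <= hi and start + 999 >= lo) else "rejected"
            assert classify_cis_trans(lnc, mrna, up, down) == expected


class TestEnergyTable:
    def test_basic_and_duplicate_policy(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text(
            "lnc_id\tmrna_id\tenergy\nL1\tM1\t-40\nL2\tM2\t-35\nL1\tM1\t-10\n")
        table = read_energy_table(path)
        assert len(table) == 2
        assert table[("L1", "M1")] == -10.0  # last wins

    def test_positive_energy_accepted(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("lnc_id\tmrna_id\tenergy\nL1\tM1\t+5\n")
        assert read_energy_table(path)[("L1", "M1")] == 5.0

    def test_non_numeric_energy_rejected(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("lnc_id\tmrna_id\tenergy\nL1\tM1\tstrong\n")
        with pytest.raises(ValidationError):
            read_energy_table(path)


def de_result(tid, fold, tier="significant"):
    l2 = math.log2(fold)
    return DEResult(tid, 1.0, fold, fold, l2, 1e-6, 1e-5, tier,
                    "up" if l2 > 0 else ("down" if l2 < 0 else "none"))


def pair(l, m):
    return TargetPair(l, m, 0.9, 0.9, "cis", distance_bp=100)


class TestTarPairCascade:
    def test_ns_member_excluded(self):
        hits = build_tarpairs([pair("L1", "M1")],
                              [de_result("L1", 4.0)], [de_result("M1", 4.0, tier="ns")])
        assert hits == []

    def test_enumeration_of_two_fold_filter(self):
        pairs = [pair(f"L{i}", f"M{i}") for i in range(5)]
        lnc_folds = [4.0, 0.2, 3.0, 1.5, 2.0]
        mrna_folds = [2.5, 8.0, 1.2, 4.0, 0.5]
        de_l = [de_result(f"L{i}", f) for i, f in enumerate(lnc_folds)]
        de_m = [de_result(f"M{i}", f) for i, f in enumerate(mrna_folds)]
        hits = build_tarpairs(pairs, de_l, de_m, fold_min=2.0)
        assert [h.pair.lnc_id for h in hits] == ["L0", "L1", "L4"]
        assert hits[0].min_abs_fold == pytest.approx(2.5)

    def test_inverse_direction_annotated(self):
        hits = build_tarpairs([pair("L1", "M1")],
                              [de_result("L1", 4.0)], [de_result("M1", 0.25)])
        assert hits[0].congruence == "inverse"
        assert hits[0].min_abs_fold == pytest.approx(4.0)

    def test_refine_min_rule(self):
        de_l = [de_result("L1", 6.0), de_result("L2", 6.0)]
        de_m = [de_result("M1", 5.2), de_result("M2", 4.9)]
        hits = build_tarpairs([pair("L1", "M1"), pair("L2", "M2")], de_l, de_m)
        kept = refine_tarpairs(hits, fold_min=5.0)
        assert [h.pair.lnc_id for h in kept] == ["L1"]

    def test_refine_of_build2_equals_build5(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(1, 12))
            pairs = [pair(f"L{i}", f"M{i}") for i in range(n)]
            folds = np.exp(rng.normal(0, 2, size=(2, n)) * math.log(2))
            tiers = rng.choice(["significant", "candidate", "ns"], size=(2, n))
            de_l = [de_result(f"L{i}", folds[0, i], tiers[0, i]) for i in range(n)]
            de_m = [de_result(f"M{i}", folds[1, i], tiers[1, i]) for i in range(n)]
            a = refine_tarpairs(build_tarpairs(pairs, de_l, de_m, fold_min=2.0), 5.0)
            b = build_tarpairs(pairs, de_l, de_m, fold_min=5.0)
            assert [(h.pair.lnc_id, h.pair.mrna_id) for h in a] == [
                (h.pair.lnc_id, h.pair.mrna_id) for h in b]

    def test_id_collision_rejected(self):
        with pytest.raises(ValidationError):
            build_tarpairs([pair("X", "M1")], [de_result("X", 4.0)],
                           [de_result("X", 4.0)])


def test_planted_cis_pairs_always_classified_cis(sim_annotation):
    records, truth = sim_annotation
    by_id = {r.transcript_id: r for r in records}
    for lnc_id, mrna_id, mode in truth.planted_pairs:
        if mode == "cis":
            assert classify_cis_trans(by_id[lnc_id], by_id[mrna_id]) == "cis"
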