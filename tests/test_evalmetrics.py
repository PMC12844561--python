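import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import porecall as pc
from porecall.methcaller import MethCall
from porecall.evalmetrics import DEFAULT_ERROR_BINS, error_stratified_accuracy


class TestAlnStats:
    def test_perfect_alignment(self):
        st = pc.aln_stats("10M", nm=0)
        assert st.identity == 1.0 and st.error_rate == 0.0

    def test_hand_counted_mixed_alignment(self):
        st = pc.aln_stats("8M1I1D", nm=3)
        assert st.identity == pytest.approx(0.7)
        assert st.mismatch_rate == pytest.approx(0.1)
        assert st.insertion_rate == pytest.approx(0.1)
        assert st.deletion_rate == pytest.approx(0.1)

    def test_explicit_eq_x_ops_need_no_nm(self):
        st = pc.aln_stats("5=1X4=")
        assert st.identity == pytest.approx(0.9)
        assert st.mismatch_rate == pytest.approx(0.1)

    def test_components_sum_to_error_rate(self, rng):
        for _ in range(50):
            m, i, d, x = (int(v) for v in rng.integers(1, 20, size=4))
            cigar = f"{m}={x}X{i}I{d}D"
            st = pc.aln_stats(cigar)
            assert st.error_rate == pytest.approx(
                st.mismatch_rate + st.insertion_rate + st.deletion_rate,
                abs=1e-12,
            )
            assert st.identity + st.error_rate == pytest.approx(1.0, abs=1e-12)

    def test_malformed_nm_rejected(self):
        with pytest.raises(ValueError):
            pc.aln_stats("5M2I2D", nm=1)  # NM < indel bases

    def test_sam_file_parsing(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:ref\tLN:100\n"
            "r1\t0\tref\t1\t60\t8M1I1D\t*\t0\t0\tAAAAAAAAA\t*\tNM:i:3\n"
        )
        df = pc.evalmetrics.aln_stats_from_sam(sam) if hasattr(pc, "evalmetrics") \
            else None
        from porecall.evalmetrics import aln_stats_from_sam

        df = aln_stats_from_sam(sam)
        assert df.iloc[0].identity == pytest.approx(0.7)

    def test_identity_to_truth_via_edlib(self):
        st = pc.identity_to_truth("ACGTACGT", "ACGTACGT")
        assert st.identity == 1.0
        st = pc.identity_to_truth("ACGTACGT", "ACGAACGT")  # one mismatch
        assert st.identity == pytest.approx(7 / 8)


class TestRocPr:
    def test_perfect_separation(self):
        auc, aupr, _ = pc.roc_pr([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0 and aupr == 1.0

    def test_four_point_fixture_mann_whitney(self):
        auc, _, _ = pc.roc_pr([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1])
        assert auc == pytest.approx(0.75)

    def test_matches_concordant_pair_statistic(self, rng):
        """Trapezoidal ROC AUC equals the midrank Mann-Whitney statistic."""
        for _ in range(30):
            n = int(rng.integers(4, 21))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.uniform(0, 1, size=n), 1)  # force ties
            auc, _, _ = pc.roc_pr(labels, scores)
            pos = scores[labels == 1][:, None]
            neg = scores[labels == 0][None, :]
            mw = (pos > neg).mean() + 0.5 * (pos == neg).mean()
            assert auc == pytest.approx(mw, abs=1e-12)

    def test_constant_scores_give_half(self):
        auc, _, _ = pc.roc_pr([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pc.roc_pr([1, 1], [0.1, 0.2])


class TestPrf1:
    def test_hand_counted(self):
        labels = [1, 1, 1, 1, 0, 0]
        pred = [1, 1, 1, 0, 1, 0]  # TP=3 FP=1 FN=1
        assert pc.prf1(labels, pred) == (0.75, 0.75, 0.75)

    def test_perfect(self):
        assert pc.prf1([0, 1, 1], [0, 1, 1]) == (1.0, 1.0, 1.0)

    def test_no_predicted_positive_flagged(self):
        with pytest.raises(ValueError):
            pc.prf1([1, 0], [0, 0])


class TestPearson:
    def test_exact_lines(self):
        x = np.arange(10.0)
        assert pc.pearson(x, x).rho == pytest.approx(1.0)
        assert pc.pearson(x, -x).rho == pytest.approx(-1.0)

    def test_hand_example(self):
        res = pc.pearson([1, 2, 3], [1, 2, 4])
        assert res.rho == pytest.approx(0.98198051, abs=1e-7)
        assert res.n_sites == 3

    def test_matches_scipy_on_random_vectors(self, rng):
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            assert pc.pearson(x, y).rho == pytest.approx(
                sps.pearsonr(x, y).statistic, abs=1e-12
            )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pc.pearson([1, 1, 1], [1, 2, 3])


class TestAggregateSites:
    def _call(self, pm, pos=5, rid="r"):
        return MethCall(rid, pos, 1 - pm, pm, label=int(pm > 0.5),
                        ref="chr", ref_pos=pos)

    def test_hand_counted_frequency(self):
        calls = [self._call(p) for p in (0.9, 0.9, 0.1)]
        df = pc.aggregate_sites(calls)
        assert len(df) == 1
        assert df.iloc[0].coverage == 3
        assert df.iloc[0].frequency == pytest.approx(2 / 3)

    def test_exact_half_counts_as_unmethylated(self):
        df = pc.aggregate_sites([self._call(0.5)])
        assert df.iloc[0].frequency == 0.0

    def test_empty_calls_empty_table(self):
        assert pc.aggregate_sites([]).empty

    def test_min_coverage_drops_sites(self):
        calls = [self._call(0.9, pos=1)] + [self._call(0.9, pos=2)] * 3
        df = pc.aggregate_sites(calls, min_coverage=2)
        assert df.pos.tolist() == [2]


class TestDepthCurve:
    def _make_calls(self, rng, n_sites=60, depth=20):
        probs = {"c": {i: float(rng.uniform()) for i in range(n_sites)}}
        calls = []
        for pos, p in probs["c"].items():
            for r in range(depth):
                meth = rng.random() < p
                noisy = np.clip(p + rng.normal(0, .05), 0, 1)
                pm = 0.9 if meth else 0.1
                calls.append(MethCall(f"read{r}", pos, 1 - pm, pm,
                                      label=int(pm > .5), ref="c", ref_pos=pos))
        return probs, calls

    def test_full_depth_equals_unsubsampled(self, rng):
        probs, calls = self._make_calls(rng)
        bs = pc.simulate_bs_table(probs, depth=50, seed=1)
        full = pc.correlate_with_bs(pc.aggregate_sites(calls), bs).rho
        curve = pc.depth_correlation_curve(calls, bs, depths=[100], seed=0)
        assert curve[100] == pytest.approx(full, abs=1e-12)

    def test_curve_reproducible_for_fixed_seed(self, rng):
        probs, calls = self._make_calls(rng)
        bs = pc.simulate_bs_table(probs, depth=50, seed=1)
        a = pc.depth_correlation_curve(calls, bs, depths=[2, 5, 10], seed=7)
        b = pc.depth_correlation_curve(calls, bs, depths=[2, 5, 10], seed=7)
        assert a == b


class TestErrorStratifiedAccuracy:
    def test_all_correct_gives_ones(self):
        calls = [
            (MethCall(f"r{i}", 0, 0.1, 0.9, label=1), 1) for i in range(6)
        ]
        errs = {f"r{i}": 0.02 + 0.05 * i for i in range(6)}
        acc = error_stratified_accuracy(calls, errs)
        assert all(v == 1.0 for v in acc.values())

    def test_empty_bins_absent_not_zero(self):
        calls = [(MethCall("r0", 0, 0.1, 0.9, label=1), 1)]
        acc = error_stratified_accuracy(calls, {"r0": 0.02})
        assert list(acc.keys()) == [(0.0, 0.05)]

    def test_default_bins_match_figure_convention(self):
        assert DEFAULT_ERROR_BINS == (0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 1.0)

    def test_bins_left_closed_right_open(self):
        calls = [(MethCall("a", 0, 0.9, 0.1, label=0), 1),
                 (MethCall("b", 0, 0.1, 0.9, label=1), 1)]
        acc = error_stratified_accuracy(calls, {"a": 0.05, "b": 0.049})
        assert acc[(0.0, 0.05)] == 1.0  # only read b
        assert acc[(0.05, 0.1)] == 0.0  # read a falls in the next bin
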