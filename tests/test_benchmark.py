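import numpy as np
import pandas as pd
import pytest

from qmd import (
    QmdConfig,
    baseline_mwu,
    baseline_rac,
    confusion_metrics,
    mae,
    run_benchmark,
    run_qmd_rel,
    simulate_instance,
    synth_pool,
)
from qmd.benchmark import _filter_rel

FAST = QmdConfig(test="asymptotic")


class TestSynthPool:
    def test_zero_sparsity_is_dense(self):
        pool = synth_pool(30, 10, sparsity=0.0, seed=1)
        assert (pool.profiles.to_numpy() > 0).all()

    def test_columns_sum_to_one(self):
        pool = synth_pool(30, 10, sparsity=0.4, seed=2)
        np.testing.assert_allclose(pool.profiles.sum(axis=0), 1.0, atol=1e-9)

    def test_seed_reproducibility(self):
        p1 = synth_pool(25, 8, seed=7)
        p2 = synth_pool(25, 8, seed=7)
        pd.testing.assert_frame_equal(p1.profiles, p2.profiles)

    def test_occupancy_decreases_with_sparsity(self):
        occ = {}
        for sparsity in (0.1, 0.5):
            vals = [
                (synth_pool(40, 15, sparsity=sparsity, seed=s).profiles.to_numpy() > 0).mean()
                for s in range(20)
            ]
            occ[sparsity] = np.mean(vals)
        assert occ[0.5] < occ[0.1]

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            synth_pool(1, 10)
        with pytest.raises(ValueError):
            synth_pool(10, 10, sparsity=1.0)


class TestSimulateInstance:
    def test_no_perturbation_same_columns_is_exactly_null(self, dense_pool):
        idx = np.arange(5)
        inst = simulate_instance(
            dense_pool, seed=3, n_per_group=5, prop_da=0.0,
            sample_idx_T=idx, sample_idx_C=idx,
            psi_T=np.full(5, 1e10), psi_C=np.full(5, 1e10),
        )
        assert inst.true_delta_psi == 0.0
        assert np.allclose(inst.true_delta_M, 0.0)
        assert len(inst.perturbed_set) == 0

    def test_hand_computed_three_taxon_instance(self, dense_pool):
        pool = dense_pool
        idx = np.array([0, 1, 2])
        psi = np.full(3, 8.0)
        taxon = pool.profiles.index[0]
        inst = simulate_instance(
            pool, seed=4, n_per_group=3,
            perturbed_taxa=[taxon], effects=[2.0],
            sample_idx_T=idx, sample_idx_C=idx, psi_T=psi, psi_C=psi,
        )
        o = pool.profiles.to_numpy()[:, idx]
        # independent arithmetic: totals after multiplying taxon 0 by 2^2
        totals = 8.0 * (1.0 + 3.0 * o[0])
        expected_dpsi = float(np.mean(np.log2(totals)) - np.mean(np.log2(8.0 * np.ones(3))))
        assert inst.true_delta_psi == pytest.approx(expected_dpsi, abs=1e-12)
        # perturbed taxon: absolute abundance exactly 4x its control values
        assert inst.true_delta_M[taxon] == pytest.approx(2.0, abs=1e-12)
        other = pool.profiles.index[5]
        assert inst.true_delta_M[other] == pytest.approx(0.0, abs=1e-12)

    def test_unperturbed_taxa_keep_absolute_abundance(self, small_pool):
        inst = simulate_instance(small_pool, seed=5, n_per_group=8)
        unperturbed = [t for t in small_pool.profiles.index if t not in inst.perturbed_set]
        pd.testing.assert_frame_equal(
            inst.abs_abund.loc[unperturbed], inst.abs_abund_pre.loc[unperturbed]
        )

    def test_seed_reproducibility(self, small_pool):
        a = simulate_instance(small_pool, seed=6)
        b = simulate_instance(small_pool, seed=6)
        pd.testing.assert_frame_equal(a.rel.rel, b.rel.rel)
        assert a.true_delta_psi == b.true_delta_psi

    def test_relative_change_closure_on_dense_pool(self, dense_pool):
        # delta_M_i - delta_psi equals the per-taxon log2 relative change when
        # every taxon is detected in every sample
        inst = simulate_instance(dense_pool, seed=7, n_per_group=10)
        rel = inst.rel.rel.to_numpy()
        n = inst.n_per_group
        d = np.log2(rel[:, :n]).mean(axis=1) - np.log2(rel[:, n:]).mean(axis=1)
        np.testing.assert_allclose(
            inst.true_delta_M.to_numpy() - inst.true_delta_psi, d, atol=1e-9
        )

    def test_too_few_samples_rejected(self, small_pool):
        with pytest.raises(ValueError):
            simulate_instance(small_pool, seed=8, n_per_group=2)


class TestMae:
    def test_perfect_estimate_is_zero(self):
        t = pd.Series([1.0, -2.0], index=["a", "b"])
        assert mae(t, t) == 0.0

    def test_constant_offset(self):
        t = pd.Series([1.0, -2.0, 0.5], index=list("abc"))
        assert mae(t + 0.5, t) == pytest.approx(0.5)

    def test_matches_independent_arithmetic(self):
        rng = np.random.default_rng(9)
        est = pd.Series(rng.normal(size=20), index=[f"t{i}" for i in range(20)])
        truth = pd.Series(rng.normal(size=20), index=[f"t{i}" for i in range(20)])
        expected = sum(abs(a - b) for a, b in zip(est, truth)) / 20
        assert mae(est, truth) == pytest.approx(expected)

    def test_empty_overlap_errors(self):
        with pytest.raises(ValueError):
            mae(pd.Series([1.0], index=["a"]), pd.Series([1.0], index=["b"]))


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        m = confusion_metrics({"a"}, {"a"}, {"a", "b"})
        assert m.fnr == 0.0 and m.fpr == 0.0

    def test_two_false_positives(self):
        evaluated = {f"t{i}" for i in range(100)}
        truth = {f"t{i}" for i in range(10)}
        predicted = truth | {"t90", "t91"}
        m = confusion_metrics(predicted, truth, evaluated)
        assert m.fpr == pytest.approx(2 / 90)
        assert m.fnr == 0.0

    def test_matches_elementwise_tally(self):
        rng = np.random.default_rng(10)
        evaluated = [f"t{i}" for i in range(50)]
        truth = {t for t in evaluated if rng.random() < 0.3}
        predicted = {t for t in evaluated if rng.random() < 0.4}
        m = confusion_metrics(predicted, truth, evaluated)
        tp = sum(1 for t in evaluated if t in predicted and t in truth)
        fp = sum(1 for t in evaluated if t in predicted and t not in truth)
        fn = sum(1 for t in evaluated if t not in predicted and t in truth)
        tn = len(evaluated) - tp - fp - fn
        assert (m.tp, m.fp, m.fn, m.tn) == (tp, fp, fn, tn)

    def test_non_subset_errors(self):
        with pytest.raises(ValueError):
            confusion_metrics({"x"}, set(), {"a"})


class TestBaselines:
    def test_rac_equals_qmd_delta_m_when_shift_zero(self, dense_pool):
        inst = simulate_instance(dense_pool, seed=12, n_per_group=6, prop_da=0.0,
                                 sample_idx_T=np.arange(6), sample_idx_C=np.arange(6),
                                 psi_T=np.full(6, 1e10), psi_C=np.full(6, 1e10))
        result = run_qmd_rel(inst.rel, FAST)
        assert result.delta_psi_hat == 0.0
        rac = baseline_rac(inst.rel)
        np.testing.assert_allclose(
            rac.to_numpy(),
            result.taxa.set_index("taxon_id")["delta_M_log2"].reindex(rac.index).to_numpy(),
        )

    def test_identical_groups_give_zero_rac(self, dense_pool):
        idx = np.arange(4)
        inst = simulate_instance(dense_pool, seed=13, n_per_group=4, prop_da=0.0,
                                 sample_idx_T=idx, sample_idx_C=idx,
                                 psi_T=np.full(4, 1e10), psi_C=np.full(4, 1e10))
        assert np.allclose(baseline_rac(inst.rel), 0.0)

    def test_rac_pays_for_ignoring_total_change(self, small_pool):
        # when the total load shifts, RAC's error exceeds QMD's in most draws
        wins = 0
        n_seeds = 8
        for s in range(n_seeds):
            inst = simulate_instance(small_pool, seed=100 + s, n_per_group=25,
                                     prop_da=0.3)
            if abs(inst.true_delta_psi) < 1.0:
                n_seeds -= 1
                continue
            rel = _filter_rel(inst.rel, 5)
            result = run_qmd_rel(rel, FAST)
            est = result.taxa.set_index("taxon_id")["delta_M_log2"]
            if mae(est, inst.true_delta_M) < mae(baseline_rac(rel), inst.true_delta_M):
                wins += 1
        assert wins > n_seeds / 2

    def test_mwu_fpr_inflated_under_total_change(self, small_pool):
        # unshifted MWU calls unperturbed taxa significant when |delta_psi| is large
        fpr_mwu, fpr_qmd = [], []
        for s in range(5):
            inst = simulate_instance(small_pool, seed=200 + s, n_per_group=30,
                                     prop_da=0.25)
            if abs(inst.true_delta_psi) < 1.0:
                continue
            rel = _filter_rel(inst.rel, 5)
            cfg = QmdConfig(test="asymptotic")
            qmd_res = run_qmd_rel(rel, cfg)
            mwu_res = baseline_mwu(rel, cfg)

            def fpr_of(frame):
                testable = frame["testable"].fillna(False)
                ev = set(frame.loc[testable, "taxon_id"])
                pred = set(frame.loc[testable & (frame["p_value"] < 0.05), "taxon_id"])
                return confusion_metrics(pred, inst.perturbed_set & ev, ev).fpr

            fpr_qmd.append(fpr_of(qmd_res.taxa))
            fpr_mwu.append(fpr_of(mwu_res))
        assert np.median(fpr_mwu) > np.median(fpr_qmd)


class TestRunBenchmark:
    def test_single_instance_fixed_draws(self, small_pool):
        res = run_benchmark(small_pool, 1, seed=5, methods=("qmd", "rac"),
                            config=FAST, n_per_group=10, prop_da=0.2)
        assert len(res.metrics) == 2
        assert set(res.metrics["method"]) == {"qmd", "rac"}
        assert res.n_failed == 0

    def test_row_count_is_instances_times_methods(self, small_pool):
        res = run_benchmark(small_pool, 3, seed=6, methods=("qmd", "rac", "mwu"),
                            config=FAST)
        assert len(res.metrics) == 9

    def test_fdr_never_raises_fpr(self, small_pool):
        res = run_benchmark(small_pool, 6, seed=7, methods=("qmd", "qmd_fdr"),
                            config=FAST)
        wide = res.metrics.pivot(index="instance_id", columns="method", values="fpr")
        assert (wide["qmd_fdr"] <= wide["qmd"] + 1e-12).all()

    def test_parameter_recovery_low_da_fraction(self, small_pool):
        res = run_benchmark(small_pool, 50, seed=8, methods=("qmd",), config=FAST,
                            prop_range=(0.05, 0.2), n_range=(20, 100))
        q = res.metrics[res.metrics["method"] == "qmd"]
        err = (q["est_delta_psi"] - q["true_delta_psi"]).abs()
        assert err.median() <= 0.3

    def test_seed_determinism(self, small_pool):
        a = run_benchmark(small_pool, 2, seed=9, methods=("qmd",), config=FAST)
        b = run_benchmark(small_pool, 2, seed=9, methods=("qmd",), config=FAST)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)

    def test_invalid_arguments_rejected(self, small_pool):
        with pytest.raises(ValueError):
            run_benchmark(small_pool, 0, seed=1)
        with pytest.raises(ValueError):
            run_benchmark(small_pool, 1, seed=1, methods=("qmd", "ancom"))
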