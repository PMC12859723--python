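"""Nested cross-validation with calibrated ensembling.

Evaluation protocol: participants (never individual scans) are dealt into 5
outer test folds, stratified by ever-impaired status; within each outer
fold's training participants, 6 inner validation folds are formed the same
way. For each inner fold a submodel is trained on the other five, calibrated
on the held-out fold with isotonic regression, and the calibrated validation
scores are pooled to pick the F1-optimal decision threshold. Each outer test
scan receives the mean of the six calibrated probabilities and is thresholded
into a binary call. A leakage audit asserts that no scan is ever scored by a
model whose training or calibration data included its participant.

A robustness mode additionally keeps participants who were never impaired
during their THC session out of all training and validation sets, assigning
their scans exclusively to test folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (CalibrationError, ConfigurationError, DataError,
                         LeakageError, TrainingError)

# ---------------------------------------------------------------------------
# fold planning


@dataclass
class FoldPlan:
    outer: dict[str, int]  # participant -> outer fold (0-based)
    inner: dict[int, dict[str, int]]  # outer fold -> {participant -> inner fold}
    n_outer: int
    n_inner: int
    seed: int
    test_only: frozenset[str] = frozenset()  # robustness-mode participants


def _deal(rng: np.random.Generator, ids: list[str], n_folds: int,
          strata: dict[str, bool]) -> dict[str, int]:
    """Stratified round-robin deal keeping per-stratum counts within +/-1."""
    assign: dict[str, int] = {}
    offset = 0
    for value in (True, False):
        group = [p for p in ids if strata[p] == value]
        group = [group[i] for i in rng.permutation(len(group))]
        for j, p in enumerate(group):
            assign[p] = (j + offset) % n_folds
        offset += len(group)
    return assign


def make_fold_plan(participants: list[str], ever_impaired: dict[str, bool],
                   n_outer: int = 5, n_inner: int = 6, seed: int = 0,
                   test_only: set[str] | None = None) -> FoldPlan:
    """Participant-level stratified nested fold assignment."""
    test_only = set(test_only or ())
    eligible = [p for p in participants if p not in test_only]
    n_imp = sum(ever_impaired[p] for p in eligible)
    n_non = len(eligible) - n_imp
    # an empty never-impaired stratum is legitimate (robustness mode sends
    # all never-impaired participants to the test-only pool)
    if n_imp < n_outer or 0 < n_non < n_outer:
        raise ConfigurationError(
            f"need >= {n_outer} participants of each class for {n_outer} outer "
            f"folds; got {n_imp} ever-impaired / {n_non} never-impaired")
    rng = np.random.default_rng(seed)
    outer = _deal(rng, eligible, n_outer, ever_impaired)
    for j, p in enumerate(sorted(test_only)):
        outer[p] = j % n_outer
    inner: dict[int, dict[str, int]] = {}
    for f in range(n_outer):
        train = [p for p in eligible if outer[p] != f]
        inner[f] = _deal(rng, train, n_inner, ever_impaired)
    return FoldPlan(outer=outer, inner=inner, n_outer=n_outer, n_inner=n_inner,
                    seed=seed, test_only=frozenset(test_only))


# ---------------------------------------------------------------------------
# calibration, ensembling, thresholding


class IsotonicMap:
    """Nondecreasing step-function map raw score -> [0, 1] (PAVA fit);
    inputs outside the fitted range clamp to the end values."""

    def __init__(self, scores: np.ndarray, labels: np.ndarray):
        from sklearn.isotonic import IsotonicRegression

        scores = np.asarray(scores, float)
        labels = np.asarray(labels, float)
        if scores.size < 2:
            raise CalibrationError("isotonic calibration needs >= 2 points")
        if np.unique(labels).size < 2:
            raise CalibrationError("isotonic calibration needs both classes")
        self._iso = IsotonicRegression(y_min=0.0, y_max=1.0,
                                       out_of_bounds="clip")
        self._iso.fit(scores, labels)

    def __call__(self, scores: np.ndarray) -> np.ndarray:
        return self._iso.predict(np.asarray(scores, float))


def isotonic_calibrate(scores: np.ndarray, labels: np.ndarray) -> IsotonicMap:
    return IsotonicMap(scores, labels)


@dataclass
class CalibratedEnsemble:
    """k submodels with their isotonic maps and a shared decision threshold."""

    submodels: list
    calibrators: list[IsotonicMap]
    threshold: float = 0.5

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        probs = [cal(m.score(features))
                 for m, cal in zip(self.submodels, self.calibrators)]
        return np.mean(probs, axis=0)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.predict_proba(features) >= self.threshold


def ensemble_score(probabilities: np.ndarray) -> np.ndarray:
    """Arithmetic mean over the k calibrated submodel probabilities
    (axis 0 = submodels)."""
    p = np.asarray(probabilities, float)
    if p.ndim == 1:
        p = p[None, :]
    if p.shape[0] < 1:
        raise DataError("ensemble needs >= 1 submodel")
    return p.mean(axis=0)


def _f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def select_threshold(probabilities: np.ndarray,
                     labels: np.ndarray) -> tuple[float, float]:
    """F1-optimal decision threshold over all achievable cut points.

    Candidates are the midpoints between consecutive distinct sorted
    probabilities plus {0, 1}; prediction is probability >= threshold. Ties
    in F1 resolve to the smallest threshold. Returns (threshold, best F1).
    """
    p = np.asarray(probabilities, float)
    y = np.asarray(labels).astype(bool)
    if not (y.any() and (~y).any()):
        raise TrainingError("threshold selection needs both classes present")
    uniq = np.unique(p)
    candidates = np.concatenate([[0.0], (uniq[1:] + uniq[:-1]) / 2.0, [1.0]])
    best_t, best_f1 = 0.0, -1.0
    for t in candidates:
        pred = p >= t
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        fn = int((~pred & y).sum())
        f1 = _f1(tp, fp, fn)
        if f1 > best_f1 + 1e-15:
            best_t, best_f1 = float(t), f1
    return best_t, best_f1


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricSet:
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    accuracy: float | None = None
    false_positive_rate: float | None = None
    roc_auc: float | None = None
    n: int = 0
    undefined: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("precision", "recall", "f1", "accuracy",
                 "false_positive_rate", "roc_auc", "n")}


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def compute_metrics(labels: np.ndarray, predictions: np.ndarray | None = None,
                    scores: np.ndarray | None = None) -> MetricSet:
    """Confusion-matrix metrics plus trapezoidal ROC-AUC.

    Undefined denominators (no predicted positives, no true positives, one
    observed class) are reported as None with a reason, never silently as 0.
    The AUC equals the tie-corrected rank (Mann-Whitney) statistic.
    """
    y = np.asarray(labels).astype(bool)
    if y.size < 1:
        raise DataError("compute_metrics needs >= 1 labeled scan")
    ms = MetricSet(n=int(y.size))
    if predictions is None and scores is not None:
        predictions = np.asarray(scores, float) >= 0.5
    if predictions is not None:
        pred = np.asarray(predictions).astype(bool)
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        tn = int((~pred & ~y).sum())
        fn = int((~pred & y).sum())
        ms.accuracy = (tp + tn) / y.size
        if tp + fp:
            ms.precision = tp / (tp + fp)
        else:
            ms.undefined["precision"] = "no predicted positives"
        if tp + fn:
            ms.recall = tp / (tp + fn)
        else:
            ms.undefined["recall"] = "no true positives in sample"
        if ms.precision is not None and ms.recall is not None:
            ms.f1 = f1_from_precision_recall(ms.precision, ms.recall)
        elif 2 * tp + fp + fn:
            ms.f1 = _f1(tp, fp, fn)
        else:
            ms.undefined["f1"] = "no positives predicted or observed"
        if fp + tn:
            ms.false_positive_rate = fp / (fp + tn)
        else:
            ms.undefined["false_positive_rate"] = "no true negatives in sample"
    if scores is not None:
        if y.any() and (~y).any():
            from sklearn.metrics import roc_auc_score

            ms.roc_auc = float(roc_auc_score(y, np.asarray(scores, float)))
        else:
            ms.undefined["roc_auc"] = "labels contain a single class"
    elif "roc_auc" not in ms.undefined:
        ms.undefined["roc_auc"] = "no scores provided"
    return ms


# ---------------------------------------------------------------------------
# the nested CV engine


@dataclass
class NestedCVResult:
    scans: pd.DataFrame  # participant, fold, label, probability, prediction
    per_fold: list[MetricSet]
    pooled: MetricSet  # over concatenated out-of-fold predictions
    fold_mean: dict  # mean of per-fold metric values (defined folds only)
    ensembles: list[CalibratedEnsemble]
    audit: dict


def run_nested_cv(features: np.ndarray, labels: np.ndarray,
                  participants: np.ndarray, model_spec, plan: FoldPlan,
                  mode: str = "standard") -> NestedCVResult:
    """Run the full calibrated nested cross-validation protocol.

    ``features`` is the (n_scans, n_features) matrix from
    ``model_spec.extract_features`` (feature extraction is unsupervised, so
    it may be computed once for all scans); fitting, calibration, and
    thresholding happen strictly inside folds.
    """
    if mode not in ("standard", "robustness"):
        raise ConfigurationError(f"unknown mode '{mode}'")
    y = np.asarray(labels).astype(bool)
    pids = np.asarray(participants)
    if features.shape[0] != y.size or y.size != pids.size:
        raise DataError("features, labels, and participants must align")
    missing = set(pids) - set(plan.outer)
    if missing:
        raise DataError(f"participants missing from fold plan: {sorted(missing)[:5]}")

    prob = np.full(y.size, np.nan)
    pred = np.zeros(y.size, bool)
    fold_of = np.array([plan.outer[p] for p in pids])
    ensembles: list[CalibratedEnsemble] = []
    per_fold: list[MetricSet] = []
    audit = {"mode": mode, "folds": [], "violations": 0}

    for f in range(plan.n_outer):
        test_mask = fold_of == f
        inner_map = plan.inner[f]
        trainable = np.array([p in inner_map for p in pids])
        submodels, calibrators = [], []
        val_probs, val_labels = [], []
        train_pids_used: set[str] = set()
        for v in range(plan.n_inner):
            tr_mask = trainable & np.array(
                [inner_map.get(p, -1) not in (v, -1) for p in pids])
            va_mask = trainable & np.array(
                [inner_map.get(p, -1) == v for p in pids])
            if not va_mask.any() or np.unique(y[tr_mask]).size < 2:
                raise TrainingError(
                    f"inner fold {v} of outer fold {f} lacks data or classes")
            sub = model_spec.fit(features[tr_mask], y[tr_mask],
                                 seed=plan.seed * 1000 + f * 10 + v)
            try:
                cal = isotonic_calibrate(sub.score(features[va_mask]), y[va_mask])
            except CalibrationError:
                # single-class validation fold: calibrate on its own training
                # scores as a declared fallback (kept out of threshold pool)
                cal = isotonic_calibrate(sub.score(features[tr_mask]), y[tr_mask])
            else:
                val_probs.append(cal(sub.score(features[va_mask])))
                val_labels.append(y[va_mask])
            submodels.append(sub)
            calibrators.append(cal)
            train_pids_used |= set(pids[tr_mask]) | set(pids[va_mask])

        thr, _ = select_threshold(np.concatenate(val_probs),
                                  np.concatenate(val_labels))
        ens = CalibratedEnsemble(submodels=submodels, calibrators=calibrators,
                                 threshold=thr)
        ensembles.append(ens)

        leaked = sorted(set(pids[test_mask]) & train_pids_used)
        audit["folds"].append({"fold": f, "n_test": int(test_mask.sum()),
                               "threshold": thr, "leaked": leaked})
        if leaked:
            audit["violations"] += len(leaked)
            raise LeakageError(
                f"outer fold {f}: test participants {leaked[:5]} appeared in "
                "training/validation data")
        if mode == "robustness":
            contaminated = sorted(plan.test_only & train_pids_used)
            if contaminated:
                raise LeakageError(
                    f"robustness mode: never-impaired participants "
                    f"{contaminated[:5]} leaked into training")

        p_test = ens.predict_proba(features[test_mask])
        prob[test_mask] = p_test
        pred[test_mask] = p_test >= thr
        per_fold.append(compute_metrics(y[test_mask], pred[test_mask], p_test))

    pooled = compute_metrics(y, pred, prob)
    keys = ("precision", "recall", "f1", "accuracy", "false_positive_rate",
            "roc_auc")
    fold_mean = {k: (float(np.mean(vals)) if (vals := [getattr(m, k)
                 for m in per_fold if getattr(m, k) is not None]) else None)
                 for k in keys}
    scans = pd.DataFrame({"participant": pids, "fold": fold_of, "label": y,
                          "probability": prob, "prediction": pred})
    return NestedCVResult(scans=scans, per_fold=per_fold, pooled=pooled,
                          fold_mean=fold_mean, ensembles=ensembles, audit=audit)


def temporal_subset_eval(result: NestedCVResult,
                         scan_meta: pd.DataFrame) -> MetricSet:
    """Metrics restricted to inconsistently-impaired participants.

    Keeps scans from participants labeled impaired at exactly one of their
    post-THC timepoints (the group where impairment status changes within a
    session), then recomputes the metric set on their out-of-fold results.
    """
    from .synthgen import PREDOSE, THC

    meta = scan_meta.reset_index(drop=True)
    post = meta[(meta["arm"] == THC) & (meta["timepoint"] != PREDOSE)]
    n_imp = post.groupby("participant")["impaired_class"].sum()
    n_tp = post.groupby("participant")["impaired_class"].size()
    inconsistent = set(n_imp[(n_imp == 1) & (n_tp >= 2)].index)
    mask = meta["participant"].isin(inconsistent).to_numpy()
    if not mask.any():
        ms = MetricSet(n=0)
        ms.undefined = {k: "no inconsistently-impaired participants"
                        for k in ("precision", "recall", "f1", "accuracy",
                                  "false_positive_rate", "roc_auc")}
        return ms
    r = result.scans
    return compute_metrics(r["label"].to_numpy()[mask],
                           r["prediction"].to_numpy()[mask],
                           r["probability"].to_numpy()[mask])
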