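"""Statistical comparison and secondary analyses.

* ``paired_bootstrap`` — stratified paired bootstrap of two classifiers on
  their shared test scans: resamples preserve the impaired/not-impaired
  counts exactly, every metric is recomputed for both classifiers per
  resample, and the paired differences give percentile 95% CIs, bootstrap
  SEs, and one-sided p-values (proportion of differences <= 0, plus the
  mirrored proportion for metrics where smaller is better).
* ``condition_contrasts`` — within-subject condition contrasts (impairment
  probability, heart rate, DEQ) from complete-pair participant differences
  with cluster-bootstrap CIs.
* ``channel_importance`` — per-channel validation ROC-AUC with the kernel
  model trained on each oxygenated channel independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError
from .crossval import FoldPlan, compute_metrics

METRICS = ("roc_auc", "accuracy", "precision", "recall", "f1",
           "false_positive_rate")


@dataclass
class MetricComparison:
    metric: str
    observed_difference: float | None
    ci_low: float | None
    ci_high: float | None
    se: float | None
    p_value: float | None  # proportion of bootstrap differences <= 0
    p_value_mirrored: float | None  # proportion >= 0 (for smaller-is-better)
    n_resamples_used: int
    reason: str | None = None


@dataclass
class BootstrapComparison:
    metrics: dict[str, MetricComparison]
    n_shared_scans: int
    n_boot: int
    seed: int


def _metric_matrix(y: np.ndarray, pred: np.ndarray, scores: np.ndarray,
                   pos_draws: np.ndarray, neg_draws: np.ndarray) -> dict:
    """All six metrics for every bootstrap resample, vectorized.

    ``pos_draws``/``neg_draws`` hold resampled indices into the positive and
    negative scan pools; undefined values are NaN.
    """
    from scipy.stats import rankdata

    n_boot = pos_draws.shape[0]
    n_pos, n_neg = pos_draws.shape[1], neg_draws.shape[1]
    pp = pred[pos_draws]  # predictions on resampled positives
    pn = pred[neg_draws]
    tp = pp.sum(axis=1)
    fn = n_pos - tp
    fp = pn.sum(axis=1)
    tn = n_neg - fp

    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        recall = tp / n_pos
        f1 = np.where(2 * tp + fp + fn > 0, 2 * tp / (2 * tp + fp + fn), np.nan)
        accuracy = (tp + tn) / (n_pos + n_neg)
        fpr = fp / n_neg

    s = np.concatenate([scores[pos_draws], scores[neg_draws]], axis=1)
    ranks = rankdata(s, axis=1)
    auc = (ranks[:, :n_pos].sum(axis=1) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return {"roc_auc": auc, "accuracy": accuracy, "precision": precision,
            "recall": recall, "f1": f1, "false_positive_rate": fpr,
            "_n_boot": n_boot}


def paired_bootstrap(labels: np.ndarray, preds_a: np.ndarray,
                     scores_a: np.ndarray, preds_b: np.ndarray,
                     scores_b: np.ndarray, n_boot: int = 1000,
                     seed: int = 0) -> BootstrapComparison:
    """Stratified paired bootstrap comparison of classifiers A and B.

    Each resample draws, with replacement, exactly the original number of
    impaired and of not-impaired scans, so class proportions are preserved
    exactly. Resamples where a metric is undefined for either classifier are
    excluded for that metric and counted in ``n_resamples_used``.
    """
    y = np.asarray(labels).astype(bool)
    arrays = [np.asarray(a) for a in (preds_a, scores_a, preds_b, scores_b)]
    if any(a.shape != y.shape for a in arrays):
        raise DataError("all prediction/score vectors must align with labels")
    pa, sa, pb, sb = arrays
    if not (y.any() and (~y).any()):
        raise DataError("paired bootstrap needs both classes in the labels")

    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    rng = np.random.default_rng(seed)
    pos_draws = pos[rng.integers(0, pos.size, size=(n_boot, pos.size))]
    neg_draws = neg[rng.integers(0, neg.size, size=(n_boot, neg.size))]

    mat_a = _metric_matrix(y, pa.astype(bool), sa.astype(float),
                           pos_draws, neg_draws)
    mat_b = _metric_matrix(y, pb.astype(bool), sb.astype(float),
                           pos_draws, neg_draws)
    obs_a = compute_metrics(y, pa, sa)
    obs_b = compute_metrics(y, pb, sb)

    out: dict[str, MetricComparison] = {}
    for m in METRICS:
        diffs = mat_a[m] - mat_b[m]
        usable = diffs[~np.isnan(diffs)]
        va, vb = getattr(obs_a, m), getattr(obs_b, m)
        observed = None if va is None or vb is None else va - vb
        if usable.size == 0:
            out[m] = MetricComparison(
                metric=m, observed_difference=observed, ci_low=None,
                ci_high=None, se=None, p_value=None, p_value_mirrored=None,
                n_resamples_used=0,
                reason="metric undefined in every bootstrap resample")
            continue
        lo, hi = np.percentile(usable, [2.5, 97.5])
        out[m] = MetricComparison(
            metric=m, observed_difference=observed,
            ci_low=float(lo), ci_high=float(hi),
            se=float(usable.std(ddof=1)) if usable.size > 1 else 0.0,
            p_value=float((usable <= 0).mean()),
            p_value_mirrored=float((usable >= 0).mean()),
            n_resamples_used=int(usable.size))
    return BootstrapComparison(metrics=out, n_shared_scans=int(y.size),
                               n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# within-subject condition contrasts


@dataclass
class ContrastEstimate:
    outcome: str
    condition_a: str
    condition_b: str
    estimate: float | None
    ci_low: float | None
    ci_high: float | None
    n_participants: int
    reason: str | None = None


DEFAULT_CONTRAST_PAIRS = (
    ("THC-impaired", "THC-not-impaired"),
    ("THC-impaired", "placebo"),
    ("THC-impaired", "predose"),
    ("THC-not-impaired", "placebo"),
    ("placebo", "predose"),
)


def condition_contrasts(values: np.ndarray, participants: np.ndarray,
                        conditions: np.ndarray, outcome: str = "value",
                        pairs=DEFAULT_CONTRAST_PAIRS, n_boot: int = 2000,
                        seed: int = 0) -> list[ContrastEstimate]:
    """Random-intercept condition contrasts via complete-pair differencing.

    For each condition pair, every participant observed under both conditions
    contributes the difference of their condition means; the contrast is the
    across-participant mean of those differences (participant intercepts
    cancel exactly), with a percentile CI from a cluster bootstrap resampling
    participants. A pair observed in fewer than 2 participants is reported
    undefined-with-reason.
    """
    df = pd.DataFrame({"value": np.asarray(values, float),
                       "participant": np.asarray(participants),
                       "condition": np.asarray(conditions)})
    cell = df.groupby(["participant", "condition"])["value"].mean().unstack()
    rng = np.random.default_rng(seed)
    out = []
    for ca, cb in pairs:
        if ca not in cell.columns or cb not in cell.columns:
            out.append(ContrastEstimate(outcome, ca, cb, None, None, None, 0,
                                        reason="condition absent from data"))
            continue
        d = (cell[ca] - cell[cb]).dropna().to_numpy()
        if d.size < 2:
            out.append(ContrastEstimate(outcome, ca, cb,
                                        float(d.mean()) if d.size else None,
                                        None, None, int(d.size),
                                        reason="fewer than 2 participants "
                                               "observed in both conditions"))
            continue
        draws = d[rng.integers(0, d.size, size=(n_boot, d.size))].mean(axis=1)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        out.append(ContrastEstimate(outcome, ca, cb, float(d.mean()),
                                    float(lo), float(hi), int(d.size)))
    return out


def scan_conditions(scan_meta: pd.DataFrame) -> np.ndarray:
    """Map per-scan metadata to the four contrast conditions."""
    from .synthgen import PREDOSE, THC

    conds = []
    for _, row in scan_meta.iterrows():
        if row["timepoint"] == PREDOSE:
            conds.append("predose")
        elif row["arm"] != THC:
            conds.append("placebo")
        elif bool(row.get("impaired_class", False)):
            conds.append("THC-impaired")
        else:
            conds.append("THC-not-impaired")
    return np.asarray(conds)


# ---------------------------------------------------------------------------
# channel importance


def channel_importance(X: np.ndarray, labels: np.ndarray,
                       participants: np.ndarray, plan: FoldPlan,
                       sample_rate: float = 1.0, n_kernels: int = 200,
                       seed: int = 0, montage=None) -> pd.DataFrame:
    """Mean validation ROC-AUC per oxygenated channel, assessed independently.

    ``X`` is (n_scans, 2C, T) with the first C series the HbO channels. For
    each channel a kernel model (ridge head, no detachment for speed) is
    trained on the inner-fold complements and scored on each validation
    fold; the channel's importance is its mean validation AUC over all inner
    folds of all outer folds.
    """
    from .models import DetachKernelModel

    y = np.asarray(labels).astype(bool)
    pids = np.asarray(participants)
    C = X.shape[1] // 2
    spec = DetachKernelModel(n_kernels=n_kernels, seed=seed, detach=False)
    rows = []
    for c in range(C):
        feats = spec.extract_features(X[:, [c], :], sample_rate)
        aucs = []
        for f in range(plan.n_outer):
            inner_map = plan.inner[f]
            fold_idx = np.array([inner_map.get(p, -1) for p in pids])
            for v in range(plan.n_inner):
                tr = (fold_idx >= 0) & (fold_idx != v)
                va = fold_idx == v
                if np.unique(y[tr]).size < 2 or np.unique(y[va]).size < 2:
                    continue
                sub = spec.fit(feats[tr], y[tr], seed=seed)
                m = compute_metrics(y[va], scores=sub.score(feats[va]))
                if m.roc_auc is not None:
                    aucs.append(m.roc_auc)
        rows.append({"channel": c + 1,
                     "region": montage[c].region if montage else None,
                     "mean_validation_auc": float(np.mean(aucs)) if aucs else np.nan,
                     "n_folds": len(aucs)})
    return pd.DataFrame(rows)
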