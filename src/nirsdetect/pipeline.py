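"""End-to-end orchestration: simulate -> preprocess -> label -> classify.

``build_dataset`` streams scans through the preprocessing pipeline as they
are generated (memory stays flat at study scale) and stacks the band-passed,
decimated HbO/HbR series into a model-ready array. ``evaluate_cohort`` runs
the full calibrated nested cross-validation on such a dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crossval import NestedCVResult, make_fold_plan, run_nested_cv
from .labeling import label_cohort, training_class_assignment
from .signal import downsample, preprocess_scan
from .synthgen import Cohort, CohortConfig, generate_cohort


@dataclass
class ScanDataset:
    """Preprocessed scans ready for classification.

    ``X`` is (n_scans, 2C, T): the C oxyhemoglobin series stacked over the C
    deoxyhemoglobin series, band-passed and decimated to ``sample_rate``.
    """

    X: np.ndarray
    meta: pd.DataFrame  # participant, arm, timepoint, scan_type, scan_passed
    sample_rate: float
    montage: list
    n_excluded: int = 0
    labels: pd.DataFrame | None = None  # set by attach_labels


def build_dataset(config: CohortConfig, variance_fraction: float = 0.8,
                  band: tuple[float, float] = (0.01, 0.2),
                  model_rate: float = 1.0, screen: bool = True,
                  exclude_failing: bool = True) -> tuple[ScanDataset, Cohort]:
    """Generate a cohort and preprocess every scan into a model-ready array."""
    series, rows = [], []
    montage_ref = []

    def callback(scan):
        hemo = preprocess_scan(scan, variance_fraction=variance_fraction,
                               band=band, screen=screen)
        hemo = downsample(hemo, model_rate)
        if not montage_ref:
            montage_ref.append((hemo.montage, hemo.sample_rate))
        rows.append({"participant": scan.participant, "arm": scan.arm,
                     "timepoint": scan.timepoint, "scan_type": scan.scan_type,
                     "scan_passed": bool(hemo.meta.get("scan_passed", True))})
        series.append(np.concatenate([hemo.hbo.T, hemo.hbr.T]))

    cohort = generate_cohort(config, scan_callback=callback)
    meta = pd.DataFrame(rows)
    X = np.asarray(series)
    n_excluded = 0
    if exclude_failing and not meta["scan_passed"].all():
        keep = meta["scan_passed"].to_numpy()
        n_excluded = int((~keep).sum())
        X, meta = X[keep], meta[keep].reset_index(drop=True)
    montage, fs = montage_ref[0]
    return ScanDataset(X=X, meta=meta, sample_rate=fs, montage=montage,
                       n_excluded=n_excluded), cohort


def attach_labels(dataset: ScanDataset, cohort: Cohort,
                  sigma_hr: float = 10.0, sigma_deq: float = 30.0,
                  tau: float = 2.0) -> pd.DataFrame:
    """Label the cohort and attach the per-scan training class to the
    dataset metadata (adds impaired_class and class_subtype columns)."""
    labels = label_cohort(cohort, sigma_hr=sigma_hr, sigma_deq=sigma_deq,
                          tau=tau)
    dataset.meta = training_class_assignment(labels, dataset.meta)
    dataset.labels = labels
    return labels


def ever_impaired_map(meta: pd.DataFrame) -> dict[str, bool]:
    g = meta.groupby("participant")["impaired_class"].any()
    return {p: bool(v) for p, v in g.items()}


def evaluate_cohort(dataset: ScanDataset, model_spec, n_outer: int = 5,
                    n_inner: int = 6, seed: int = 0,
                    mode: str = "standard") -> NestedCVResult:
    """Fold-plan + nested CV on a labeled dataset (one scan type at a time)."""
    meta = dataset.meta
    if "impaired_class" not in meta.columns:
        raise ValueError("dataset has no labels; call attach_labels first")
    ever = ever_impaired_map(meta)
    test_only = None
    if mode == "robustness":
        from .synthgen import THC

        had_thc = set(meta.loc[meta["arm"] == THC, "participant"])
        test_only = {p for p, imp in ever.items()
                     if not imp and p in had_thc}
    plan = make_fold_plan(sorted(ever), ever, n_outer=n_outer,
                          n_inner=n_inner, seed=seed, test_only=test_only)
    features = model_spec.extract_features(dataset.X, dataset.sample_rate)
    return run_nested_cv(features, meta["impaired_class"].to_numpy(),
                         meta["participant"].to_numpy(), model_spec, plan,
                         mode=mode)


def scan_heart_rates(cohort: Cohort, meta: pd.DataFrame) -> np.ndarray:
    """Mean heart rate in the +/-20-minute window around each scan."""
    from .synthgen import SCAN_TIMES_MIN

    phys = cohort.physiology.sort_values(["participant", "arm"])
    phys = phys.set_index(["participant", "arm"])
    vals = []
    for _, r in meta.iterrows():
        sess = phys.loc[(r["participant"], r["arm"])]
        t = sess["time_min"].to_numpy(float)
        hr = sess["hr_bpm"].to_numpy(float)
        w = np.abs(t - SCAN_TIMES_MIN[r["timepoint"]]) <= 20.0
        vals.append(hr[w].mean())
    return np.asarray(vals)


def fst_scan_predictions(cohort: Cohort, meta: pd.DataFrame
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project the session-level field-sobriety outcome onto post-THC scans.

    Returns (mask over meta rows where the FST produced a prediction, binary
    predictions, ordinal 0-4 scores). The FST is administered once per THC
    session, so only post-dose THC scans have an FST comparator.
    """
    from .synthgen import PREDOSE, THC

    fst = cohort.fst.set_index("participant")
    mask = ((meta["arm"] == THC) & (meta["timepoint"] != PREDOSE)
            & meta["participant"].isin(fst.index)).to_numpy()
    rows = meta[mask]
    preds = fst.loc[rows["participant"], "fst_positive"].to_numpy(bool)
    scores = fst.loc[rows["participant"], "fst_score"].to_numpy(float)
    return mask, preds, scores
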