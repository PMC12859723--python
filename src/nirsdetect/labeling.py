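"""Ground-truth impairment labeling.

A post-dose scan counts as impaired only when three independent assessments
agree: both clinical raters call the participant impaired AND a composite
physiology/self-report algorithm fires. The algorithm combines the heart-rate
rise over the predose baseline with the "feel drug" DEQ item as a two-term
standardized score against a fixed threshold; its constants are configurable
and surfaced in the output. Pre-dose scans are never impaired.

For model training, the non-impaired class pools three scan types: post-
placebo scans, pre-dose scans, and post-THC scans without clear clinical
impairment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError, PipelineError
from .synthgen import Cohort, PREDOSE, THC


@dataclass(frozen=True)
class ImpairmentLabel:
    participant: str
    arm: str
    timepoint: str
    rater_a: bool
    rater_b: bool
    algorithm: bool

    @property
    def impaired(self) -> bool:
        return self.rater_a and self.rater_b and self.algorithm


def algorithm_flag(physiology: pd.DataFrame, scan_time_min: float,
                   sigma_hr: float = 10.0, sigma_deq: float = 30.0,
                   tau: float = 2.0) -> bool:
    """Composite physiological/psychological impairment call for one scan.

    delta-HR is the mean heart rate inside a +/-20-minute window around the
    scan minus the predose mean; DEQ_feel is the "feel drug" item at the grid
    point nearest the scan. The flag fires when
    delta_HR/sigma_hr + DEQ_feel/sigma_deq >= tau.
    """
    t = physiology["time_min"].to_numpy(float)
    hr = physiology["hr_bpm"].to_numpy(float)
    base_mask = t <= 0
    if not base_mask.any():
        raise DataError("no predose baseline measurements in physiology series")
    window = np.abs(t - scan_time_min) <= 20.0
    if not window.any():
        raise DataError(f"no physiology measurements within 20 min of "
                        f"t={scan_time_min} min")
    delta_hr = hr[window].mean() - hr[base_mask].mean()
    feel = float(physiology["deq1"].to_numpy(float)[np.argmin(np.abs(t - scan_time_min))])
    return bool(delta_hr / sigma_hr + feel / sigma_deq >= tau)


def conjunction_label(participant: str, arm: str, timepoint: str,
                      rater_a: bool, rater_b: bool,
                      algorithm: bool) -> ImpairmentLabel:
    """Two-step ground truth: both raters AND the algorithm must agree."""
    return ImpairmentLabel(participant=participant, arm=arm,
                           timepoint=timepoint, rater_a=bool(rater_a),
                           rater_b=bool(rater_b), algorithm=bool(algorithm))


def label_cohort(cohort: Cohort, sigma_hr: float = 10.0,
                 sigma_deq: float = 30.0, tau: float = 2.0) -> pd.DataFrame:
    """Impairment labels for every scheduled postdose (participant, arm,
    timepoint) in the cohort, from raters and physiology only (never the
    latent truth)."""
    from .synthgen import SCAN_TIMES_MIN

    phys = cohort.physiology
    rows = []
    for (pid, arm), sess_raters in cohort.raters.groupby(["participant", "arm"],
                                                         sort=False):
        sess_phys = phys[(phys["participant"] == pid) & (phys["arm"] == arm)]
        for _, r in sess_raters.iterrows():
            alg = algorithm_flag(sess_phys, SCAN_TIMES_MIN[r["timepoint"]],
                                 sigma_hr=sigma_hr, sigma_deq=sigma_deq, tau=tau)
            lab = conjunction_label(pid, arm, r["timepoint"],
                                    r["rater_a"], r["rater_b"], alg)
            rows.append((pid, arm, r["timepoint"], lab.rater_a, lab.rater_b,
                         lab.algorithm, lab.impaired))
    return pd.DataFrame(rows, columns=["participant", "arm", "timepoint",
                                       "rater_a", "rater_b", "algorithm",
                                       "impaired"])


def training_class_assignment(labels: pd.DataFrame,
                              scan_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-scan binary training class with non-impaired subtype bookkeeping.

    ``scan_meta`` needs columns participant/arm/timepoint (one row per scan).
    The impaired class is exactly the post-THC scans labeled impaired; the
    rest split into three audited subtypes: postplacebo, predose, and
    post-THC-not-impaired. Aborts when the impaired class is empty, since no
    classifier can be trained on a single class.
    """
    lab_idx = labels.set_index(["participant", "arm", "timepoint"])["impaired"]
    classes, subtypes = [], []
    for _, row in scan_meta.iterrows():
        key = (row["participant"], row["arm"], row["timepoint"])
        if row["timepoint"] == PREDOSE:
            classes.append(False)
            subtypes.append("predose")
            continue
        if key not in lab_idx.index:
            raise DataError(f"scan {key} has no impairment label")
        impaired = bool(lab_idx.loc[key]) and row["arm"] == THC
        classes.append(impaired)
        if impaired:
            subtypes.append("impaired")
        elif row["arm"] == THC:
            subtypes.append("post_thc_not_impaired")
        else:
            subtypes.append("postplacebo")
    out = scan_meta.copy()
    out["impaired_class"] = classes
    out["class_subtype"] = subtypes
    if not out["impaired_class"].any():
        raise PipelineError(
            "impaired class is empty: no post-THC scan met the two-step "
            "impairment criterion; the classification pipeline cannot proceed")
    return out
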