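"""Preprocess one raw fNIRS scan into hemoglobin concentration series.

Raw dual-wavelength intensities -> optical density -> PCA motion correction
-> 0.01-0.2 Hz zero-phase band-pass -> modified Beer-Lambert inversion to
oxy/deoxyhemoglobin (µM), with cardiac-band channel quality screening.
"""

import numpy as np

import nirsdetect as nd

config = nd.CohortConfig(n_participants=10, seed=3, scan_missing_rate=0.0)
cohort = nd.generate_cohort(config)
scan = cohort.scans[0]

print(f"scan: {scan.participant} {scan.arm} {scan.timepoint} "
      f"({scan.scan_type}), {scan.intensity.shape[0]} samples x "
      f"{scan.intensity.shape[1]} detector columns")

hemo = nd.preprocess_scan(scan)
print(f"channels passing cardiac-band quality screen: "
      f"{int(hemo.quality.sum())}/{len(hemo.quality)}")
print(f"HbO series: {hemo.hbo.shape}, sd per channel "
      f"{np.median(hemo.hbo.std(axis=0)):.3f} µM (median)")
print(f"HbR/HbO sd ratio: "
      f"{np.median(hemo.hbr.std(axis=0) / hemo.hbo.std(axis=0)):.2f}")
# After band-passing, the remaining variance is dominated by slow
# hemodynamics; HbR mirrors the HbO signal at roughly a third the amplitude.
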