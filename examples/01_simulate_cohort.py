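"""Simulate a small THC/placebo crossover cohort and write it to disk.

Each participant completes two sessions (THC and placebo, randomized order)
with a predose and two postdose fNIRS scans, serial heart-rate/DEQ
measurements, clinician impairment ratings, and one field sobriety test per
THC session. The printed counts show the latent impairment structure the
generator embedded.
"""

from pathlib import Path

import nirsdetect as nd
from nirsdetect import io

config = nd.CohortConfig(n_participants=20, scan_minutes=2, sample_rate=5,
                         scan_missing_rate=0.0, seed=7)
cohort = nd.generate_cohort(config)

outdir = Path("scratch/example_cohort")
io.write_cohort(cohort, outdir)

truth = cohort.truth()
post_thc = truth[truth["arm"] == "THC"]
print(f"scans written: {len(cohort.scans)} -> {outdir}")
print(f"post-THC scan slots: {len(post_thc)}, latently impaired: "
      f"{int(post_thc['impaired'].sum())}")
per = post_thc.groupby("participant")["impaired"].sum()
print(f"participants impaired at both timepoints: {(per == 2).sum()}, "
      f"at exactly one: {(per == 1).sum()}, never: {(per == 0).sum()}")
print(f"FST positive rate in THC sessions: "
      f"{cohort.fst['fst_positive'].mean():.2f}")
# Impairment only ever occurs after THC; the placebo arm is the built-in
# negative control for every downstream analysis.
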