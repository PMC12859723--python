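"""On-disk formats: long-format TSV scan files, a JSON cohort manifest, and
an optional SNIRF (HDF5) reader for real-device recordings."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError
from .signal import HemoSeries
from .synthgen import Cohort, RawScan, default_montage


def _scan_stem(scan: RawScan) -> str:
    return f"{scan.participant}_{scan.arm}_{scan.timepoint}_{scan.scan_type}"


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write the cohort as TSV scans + physiology/rater/truth tables and a
    JSON manifest tying them together."""
    outdir = Path(outdir)
    (outdir / "scans").mkdir(parents=True, exist_ok=True)
    index = []
    for scan in cohort.scans:
        stem = _scan_stem(scan)
        entry = {"participant": scan.participant, "arm": scan.arm,
                 "timepoint": scan.timepoint, "scan_type": scan.scan_type,
                 "sample_rate": scan.sample_rate,
                 "file": f"scans/{stem}.tsv" if scan.intensity is not None else None}
        if scan.intensity is not None:
            t = np.arange(scan.intensity.shape[0]) / scan.sample_rate
            df = pd.DataFrame(scan.intensity, columns=scan.columns)
            df.insert(0, "time_s", t)
            df.to_csv(outdir / "scans" / f"{stem}.tsv", sep="\t", index=False,
                      float_format="%.6g")
        index.append(entry)

    phys = cohort.physiology.rename(columns={"time_min": "time_min"})
    phys.to_csv(outdir / "physiology.tsv", sep="\t", index=False)
    cohort.raters.to_csv(outdir / "raters.tsv", sep="\t", index=False)
    cohort.fst.to_csv(outdir / "fst.tsv", sep="\t", index=False)
    cohort.truth().to_csv(outdir / "truth.tsv", sep="\t", index=False)

    cfg = dataclasses.asdict(cohort.config)
    cfg["extinction"] = {str(k): v for k, v in cfg["extinction"].items()}
    manifest = {"config": cfg, "n_scans": len(cohort.scans), "scans": index}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def read_scan_tsv(path: str | Path) -> tuple[np.ndarray, list[str], float]:
    """Read one scan TSV; returns (intensity, columns, sample_rate)."""
    df = pd.read_csv(path, sep="\t")
    if "time_s" not in df.columns:
        raise DataError(f"{path}: missing time_s column")
    t = df.pop("time_s").to_numpy()
    if len(t) < 2:
        raise DataError(f"{path}: scan too short")
    fs = 1.0 / np.median(np.diff(t))
    return df.to_numpy(float), list(df.columns), float(fs)


def write_hemo_tsv(hemo: HemoSeries, path: str | Path) -> None:
    """Preprocessed series TSV: time_s, ch01_HbO ... chNN_HbR (µM)."""
    C = hemo.hbo.shape[1]
    cols = {f"ch{c + 1:02d}_HbO": hemo.hbo[:, c] for c in range(C)}
    cols.update({f"ch{c + 1:02d}_HbR": hemo.hbr[:, c] for c in range(C)})
    df = pd.DataFrame(cols)
    df.insert(0, "time_s", np.arange(len(df)) / hemo.sample_rate)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_hemo_tsv(path: str | Path) -> HemoSeries:
    df = pd.read_csv(path, sep="\t")
    t = df.pop("time_s").to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    hbo_cols = [c for c in df.columns if c.endswith("_HbO")]
    hbr_cols = [c for c in df.columns if c.endswith("_HbR")]
    if not hbo_cols or len(hbo_cols) != len(hbr_cols):
        raise DataError(f"{path}: expected paired *_HbO/*_HbR columns")
    return HemoSeries(hbo=df[hbo_cols].to_numpy(float),
                      hbr=df[hbr_cols].to_numpy(float), sample_rate=float(fs),
                      montage=default_montage(len(hbo_cols)))


def read_snirf(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Minimal SNIRF reader: /nirs/data1 intensities.

    Returns (intensity matrix samples x measurements, time vector, sample
    rate). Only continuous-wave amplitude data are supported; channel
    geometry beyond the measurement list order is ignored.
    """
    import h5py

    with h5py.File(path, "r") as f:
        try:
            data = f["/nirs/data1/dataTimeSeries"][()]
            time = f["/nirs/data1/time"][()]
        except KeyError as exc:
            raise DataError(f"{path}: not a SNIRF file with /nirs/data1") from exc
    time = np.asarray(time).ravel()
    if time.size == 2:  # SNIRF allows (start, step) encoding
        time = time[0] + time[1] * np.arange(data.shape[0])
    fs = 1.0 / np.median(np.diff(time))
    return np.asarray(data, float), time, float(fs)
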