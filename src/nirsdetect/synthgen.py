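"""Synthetic crossover drug-challenge cohort generator.

Emulates a double-blind THC/placebo crossover in regular cannabis users:
each participant is scanned with a 20-channel dual-wavelength (760/850 nm)
prefrontal fNIRS montage before dosing and at two post-dose timepoints per
session, while heart rate and the five-item Drug Effects Questionnaire (DEQ)
are sampled on a ~20-minute grid and a drug-recognition expert administers an
expanded field sobriety test (FST) once per active session.

The generator carries a *latent* impairment state per post-dose timepoint.
Impairment modulates (i) the prefrontal hemodynamic signal (task-response
amplitude for the n-back, low-frequency variance and medial-channel coupling
at rest), (ii) heart rate and subjective drug-effect ratings, and (iii) the
probabilistic behaviour of the clinical raters and the FST. Placebo sessions
are never impaired. All randomness flows through one seeded Generator, so a
fixed config reproduces the cohort exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, NumericalError

THC = "THC"
PLACEBO = "placebo"
PREDOSE = "predose"

#: minutes (relative to dosing) at which each scheduled scan takes place
SCAN_TIMES_MIN = {"predose": -10.0, "postdose1": 100.0, "postdose2": 200.0,
                  "postdose3": 230.0}

#: prefrontal region labels, four channels each for the default 20-channel montage
REGIONS = (
    "left dorsomedial PFC",
    "right dorsomedial PFC",
    "left ventral PFC",
    "right ventral PFC",
    "medial PFC",
)

#: molar extinction coefficients, cm^-1 mM^-1 (base-10), standard adult tabulation
DEFAULT_EXTINCTION = {
    760.0: {"hbo": 0.586, "hbr": 1.5485},
    850.0: {"hbo": 1.058, "hbr": 0.6913},
}


@dataclass(frozen=True)
class ChannelInfo:
    source: int
    detector: int
    region: str
    distance_mm: float = 30.0


def default_montage(n_channels: int = 20) -> list[ChannelInfo]:
    """Fabricate an 8-source/8-detector prefrontal montage with region labels."""
    montage = []
    for c in range(n_channels):
        region = REGIONS[(c * len(REGIONS)) // n_channels]
        montage.append(ChannelInfo(source=c % 8 + 1, detector=(c + 3) % 8 + 1,
                                   region=region))
    return montage


@dataclass
class CohortConfig:
    """Study-design and generator parameters.

    Defaults mirror the simulated study's scale: ~180 participants, two
    crossover sessions, three scan timepoints, 6-minute 20-channel scans,
    and a scan-attrition rate that brings the resting-scan count to ~890.
    """

    n_participants: int = 180
    sessions_per_participant: int = 2
    scan_timepoints: tuple[str, ...] = ("predose", "postdose1", "postdose2")
    scan_types: tuple[str, ...] = ("resting",)
    scan_minutes: float = 6.0
    sample_rate: float = 10.0  # Hz
    n_channels: int = 20
    wavelengths: tuple[float, float] = (760.0, 850.0)

    #: target fraction of post-THC scans with latent impairment
    impairment_prevalence_target: float = 0.40
    #: among responders, fraction impaired at exactly one postdose timepoint
    inconsistent_fraction: float = 0.4
    #: amplitude multiplier of the impairment hemodynamic signature
    effect_size: float = 1.0
    #: restrict the hemodynamic effect to these regions (None = all channels)
    effect_regions: tuple[str, ...] | None = None

    rater_sensitivity: float = 0.95
    rater_specificity: float = 0.97
    fst_sensitivity: float = 0.84
    fst_false_positive_rate: float = 0.34

    #: per-scan probability that a scheduled scan is missing (attrition)
    scan_missing_rate: float = 0.17

    # forward-model / artifact parameters
    source_detector_distance_mm: float = 30.0
    dpf: float = 6.0  # differential pathlength factor, both wavelengths
    extinction: dict = field(default_factory=lambda: {
        w: dict(v) for w, v in DEFAULT_EXTINCTION.items()})
    artifact_spike_prob: float = 0.3
    artifact_shift_prob: float = 0.2
    instrument_noise_sd: float = 0.005  # multiplicative (log-intensity) sd

    # hemodynamic constants
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_ratio: float = 6.0
    hbr_ratio: float = 1.0 / 3.0  # HbR = -ratio * HbO signal component
    resting_signal_sd_um: float = 0.2
    task_amplitude_um: float = 0.4
    noise_sd_um: float = 0.1

    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round(self.sample_rate * self.scan_minutes * 60))

    def validate(self) -> None:
        if self.n_participants < 10:
            raise ConfigurationError(
                "n_participants must be >= 10 (2x the number of outer folds); "
                f"got {self.n_participants}")
        for name in ("impairment_prevalence_target", "inconsistent_fraction",
                     "rater_sensitivity", "rater_specificity",
                     "fst_sensitivity", "fst_false_positive_rate",
                     "scan_missing_rate", "artifact_spike_prob",
                     "artifact_shift_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]; got {v}")
        for name in ("scan_minutes", "sample_rate", "dpf",
                     "source_detector_distance_mm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_channels < 1:
            raise ConfigurationError("n_channels must be >= 1")
        n = self.sample_rate * self.scan_minutes * 60
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                "sample_rate x scan_minutes must yield an integer sample count; "
                f"got {n}")
        unknown = set(self.scan_timepoints) - set(SCAN_TIMES_MIN)
        if unknown:
            raise ConfigurationError(f"scan_timepoints contains unknown names {unknown}")
        if self.scan_timepoints[0] != PREDOSE:
            raise ConfigurationError("scan_timepoints must start with 'predose'")
        if len(self.scan_timepoints) < 3:
            raise ConfigurationError(
                "scan_timepoints must include predose and >=2 postdose points")

    @property
    def postdose_timepoints(self) -> tuple[str, ...]:
        return tuple(t for t in self.scan_timepoints if t != PREDOSE)


@dataclass
class LatentState:
    """Ground-truth state of one participant-session."""

    participant: str
    arm: str  # THC | placebo
    impaired: dict[str, bool]  # postdose timepoint -> latent impairment
    tolerance: float  # [0,1]; attenuates the drug's hemodynamic response
    dose_mg: float

    def any_impaired(self) -> bool:
        return any(self.impaired.values())


@dataclass
class RawScan:
    """One fNIRS scan with co-timed physiology references."""

    participant: str
    arm: str
    timepoint: str
    scan_type: str  # resting | nback
    intensity: np.ndarray | None  # samples x (2 * n_channels), detector units
    columns: list[str]
    montage: list[ChannelInfo]
    sample_rate: float
    scan_time_min: float
    physiology: pd.DataFrame | None = None  # session grid: time_min, hr_bpm, deq1..5
    meta: dict = field(default_factory=dict)


@dataclass
class Cohort:
    config: CohortConfig
    scans: list[RawScan]
    latents: list[LatentState]
    physiology: pd.DataFrame  # participant, session(arm), time_min, hr_bpm, deq1..5
    raters: pd.DataFrame  # participant, arm, timepoint, rater_a, rater_b
    fst: pd.DataFrame  # participant, fst_positive, fst_score, session_impaired

    def truth(self) -> pd.DataFrame:
        """Latent impairment per scheduled postdose (participant, arm, timepoint)."""
        rows = []
        for lat in self.latents:
            for tp, flag in lat.impaired.items():
                rows.append((lat.participant, lat.arm, tp, bool(flag)))
        return pd.DataFrame(rows, columns=["participant", "arm", "timepoint",
                                           "impaired"])


# ---------------------------------------------------------------------------
# hemodynamics


def double_gamma_hrf(sample_rate: float, peak_s: float = 6.0,
                     undershoot_s: float = 16.0, ratio: float = 6.0,
                     duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak amplitude."""
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0, duration_s, 1.0 / sample_rate)
    # shape a, scale 1 gives mode at a-1 seconds
    peak = gamma_dist.pdf(t, peak_s + 1.0)
    under = gamma_dist.pdf(t, undershoot_s + 1.0)
    h = peak - under / ratio
    return h / np.max(h)


def nback_boxcar(n_samples: int, sample_rate: float,
                 block_s: float = 30.0) -> np.ndarray:
    """Alternating 0-back/2-back design: 1 during 2-back blocks.

    A 6-minute scan holds exactly 12 alternating 30-second blocks; the 2-back
    (active) blocks are the even-indexed ones (second, fourth, ...).
    """
    t = np.arange(n_samples) / sample_rate
    block_idx = np.floor(t / block_s).astype(int)
    return (block_idx % 2 == 1).astype(float)


def _bandlimited_noise(rng: np.random.Generator, n: int, sample_rate: float,
                       band: tuple[float, float] = (0.02, 0.08)) -> np.ndarray:
    """Unit-variance Gaussian process confined to the given band."""
    from scipy.signal import butter, filtfilt

    w = rng.standard_normal(n + 2 * int(10 * sample_rate))
    b, a = butter(2, band, btype="bandpass", fs=sample_rate)
    x = filtfilt(b, a, w)[int(10 * sample_rate):int(10 * sample_rate) + n]
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_hemodynamics(state: LatentState, timepoint: str, scan_type: str,
                          config: CohortConfig,
                          rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Simulate per-channel HbO/HbR concentration series (µM) for one scan.

    HbO = slow drift + Mayer (~0.1 Hz) + respiratory (~0.25 Hz) + cardiac
    (~1.1 Hz) oscillations + an impairment-modulated signal term + white
    noise; HbR mirrors the signal term with opposite sign at a fixed ratio.
    """
    n, fs, C = config.n_samples, config.sample_rate, config.n_channels
    t = np.arange(n) / fs
    montage = default_montage(C)

    impaired = bool(state.impaired.get(timepoint, False)) and state.arm == THC
    imp_eff = (1.0 - 0.5 * state.tolerance) if impaired else 0.0
    if config.effect_regions is None:
        effect_ch = np.ones(C, bool)
    else:
        effect_ch = np.array([m.region in config.effect_regions for m in montage])

    hbo = np.empty((n, C))
    hbr = np.empty((n, C))

    f_card = 1.1 + rng.normal(0, 0.05)
    f_resp = 0.25 + rng.normal(0, 0.02)
    f_mayer = 0.1 + rng.normal(0, 0.01)

    if scan_type == "nback":
        hrf = double_gamma_hrf(fs, config.hrf_peak_s, config.hrf_undershoot_s,
                               config.hrf_ratio)
        box = nback_boxcar(n, fs)
        task = np.convolve(box, hrf)[:n]
        task /= max(task.max(), 1e-12)
    else:
        task = None

    # shared low-frequency component coupling the medial channels
    shared = _bandlimited_noise(rng, n, fs)
    w_shared = 0.35 + 0.3 * min(1.0, config.effect_size * imp_eff)
    medial = np.array([m.region == "medial PFC" for m in montage])

    for c in range(C):
        drift = rng.normal(0, 0.05) * (t / t[-1]) + rng.normal(0, 0.02)
        phase_card = rng.uniform(0, 2 * np.pi)
        cardiac = np.sin(2 * np.pi * f_card * t + phase_card)
        phys = (0.1 * rng.uniform(0.5, 1.5) * np.sin(2 * np.pi * f_mayer * t + rng.uniform(0, 2 * np.pi))
                + 0.08 * rng.uniform(0.5, 1.5) * np.sin(2 * np.pi * f_resp * t + rng.uniform(0, 2 * np.pi))
                + 0.15 * rng.uniform(0.7, 1.3) * cardiac)
        boost = 1.0 + config.effect_size * imp_eff * effect_ch[c]
        if scan_type == "nback":
            signal = config.task_amplitude_um * boost * task
        else:
            own = _bandlimited_noise(rng, n, fs)
            if medial[c]:
                proc = np.sqrt(1 - w_shared ** 2) * own + w_shared * shared
            else:
                proc = own
            # variance (not amplitude) scales with the effect multiplier
            signal = config.resting_signal_sd_um * np.sqrt(boost) * proc
        noise = rng.normal(0, config.noise_sd_um, n)
        hbo[:, c] = drift + phys + signal + noise
        # cardiac pulsation is in phase across species (same pulse wave)
        hbr[:, c] = (-config.hbr_ratio * signal + 0.05 * cardiac
                     + rng.normal(0, 0.05, n))
    return hbo, hbr


# ---------------------------------------------------------------------------
# forward optics


def intensity_columns(n_channels: int, wavelengths: Sequence[float]) -> list[str]:
    """Wavelength-major column names: ch01_w760 ... chNN_w850."""
    return [f"ch{c + 1:02d}_w{int(w)}" for w in wavelengths
            for c in range(n_channels)]


def hb_to_intensity(hbo: np.ndarray, hbr: np.ndarray, config: CohortConfig,
                    rng: np.random.Generator, artifacts: bool = True,
                    noise: bool = True,
                    baseline: np.ndarray | None = None) -> tuple[np.ndarray, dict]:
    """Forward modified Beer–Lambert transform to raw detector intensities.

    OD_lambda = eps(lambda) . (HbO, HbR) * d * DPF (concentrations in µM,
    extinction in cm^-1 mM^-1), then I = I0 * 10^(-OD). Motion artifacts
    (short Laplacian-amplitude spikes and persistent step shifts, shared
    across channels) are injected in optical-density space; instrument noise
    is multiplicative log-normal.
    """
    n, C = hbo.shape
    wavelengths = config.wavelengths
    d_cm = config.source_detector_distance_mm / 10.0
    od = np.empty((n, 2 * C))
    _check_extinction_invertible(config)
    for wi, w in enumerate(wavelengths):
        eps = config.extinction[float(w)]
        od[:, wi * C:(wi + 1) * C] = (
            (eps["hbo"] * hbo + eps["hbr"] * hbr) * 1e-3 * d_cm * config.dpf)

    meta: dict = {"spikes": [], "shifts": []}
    if artifacts:
        fs = config.sample_rate
        if rng.random() < config.artifact_spike_prob:
            t0 = rng.integers(0, n)
            dur = rng.uniform(0.2, 2.0)
            width = max(int(dur * fs / 4), 1)
            amp = rng.laplace(0, 0.08)
            idx = np.arange(n)
            bump = amp * np.exp(-0.5 * ((idx - t0) / width) ** 2)
            od += bump[:, None] * rng.uniform(0.5, 1.5, 2 * C)[None, :]
            meta["spikes"].append({"sample": int(t0), "duration_s": float(dur),
                                   "amplitude": float(amp)})
        if rng.random() < config.artifact_shift_prob:
            t0 = int(rng.integers(1, n))
            amp = rng.laplace(0, 0.05)
            od[t0:, :] += amp * rng.uniform(0.5, 1.5, 2 * C)[None, :]
            meta["shifts"].append({"sample": t0, "amplitude": float(amp)})

    if baseline is None:
        baseline = 1000.0 * np.exp(rng.normal(0, 0.1, 2 * C))
    intensity = baseline[None, :] * np.power(10.0, -od)
    if noise:
        intensity = intensity * np.exp(rng.normal(0, config.instrument_noise_sd,
                                                  intensity.shape))
    meta["baseline"] = baseline
    return intensity, meta


def _check_extinction_invertible(config: CohortConfig) -> None:
    w1, w2 = config.wavelengths
    m = np.array([[config.extinction[float(w1)]["hbo"], config.extinction[float(w1)]["hbr"]],
                  [config.extinction[float(w2)]["hbo"], config.extinction[float(w2)]["hbr"]]])
    if abs(np.linalg.det(m)) < 1e-12:
        raise NumericalError("extinction matrix is singular for this wavelength pair")


# ---------------------------------------------------------------------------
# physiology, raters, field sobriety


#: measurement grid in minutes relative to dosing
PHYS_GRID_MIN = np.arange(-20.0, 241.0, 20.0)


def _effect_curve(grid: np.ndarray, d1: float, d2: float) -> np.ndarray:
    """Smooth drug-effect time course, flat within +/-20 min of each scan."""
    knots_t = np.array([0.0, 40.0, 80.0, 120.0, 150.0, 180.0, 220.0, 240.0])
    knots_v = np.array([0.0, 0.5 * d1, d1, d1, 0.5 * (d1 + d2), d2, d2, 0.7 * d2])
    return np.interp(grid, knots_t, knots_v, left=0.0)


def simulate_physiology_and_raters(state: LatentState, config: CohortConfig,
                                   rng: np.random.Generator,
                                   base_hr: float | None = None
                                   ) -> tuple[pd.DataFrame, dict, dict | None]:
    """Heart-rate/DEQ grid, per-scan rater flags, and the FST outcome.

    Impaired timepoints show an elevated heart rate over the predose baseline
    and high "feel drug" DEQ ratings; each clinical rater flips a coin with
    the configured sensitivity/specificity against the latent state. The FST
    (THC sessions only) is a Bernoulli draw at the configured operating point
    plus an ordinal 0-4 failed-component score consistent with the binary
    call (positive iff >=2 components failed).
    """
    # resting HR is a participant trait; sessions only jitter around it
    if base_hr is None:
        base_hr = rng.normal(70.0, 7.0)
    base_hr = base_hr + rng.normal(0.0, 1.5)
    tps = config.postdose_timepoints
    if state.arm == THC:
        d_hr = {tp: (rng.normal(18.0, 4.0) if state.impaired[tp]
                     else rng.normal(4.0, 3.0)) for tp in tps}
        d_feel = {tp: (np.clip(rng.normal(70.0, 12.0), 0, 100) if state.impaired[tp]
                       else np.clip(rng.normal(22.0, 10.0), 0, 100)) for tp in tps}
    else:
        d_hr = {tp: 0.0 for tp in tps}
        d_feel = {tp: 0.0 for tp in tps}

    d1h = d_hr.get("postdose1", 0.0)
    d2h = d_hr.get("postdose2", d1h)
    hr = base_hr + _effect_curve(PHYS_GRID_MIN, d1h, d2h) \
        + rng.normal(0, 2.0, PHYS_GRID_MIN.size)

    d1f = d_feel.get("postdose1", 0.0)
    d2f = d_feel.get("postdose2", d1f)
    feel = _effect_curve(PHYS_GRID_MIN, d1f, d2f) \
        + np.abs(rng.normal(0, 3.0, PHYS_GRID_MIN.size))
    feel = np.clip(feel, 0, 100)
    deq = {"deq1": feel}
    for k in range(2, 6):
        deq[f"deq{k}"] = np.clip(feel * rng.uniform(0.5, 0.9)
                                 + rng.normal(0, 5.0, feel.size), 0, 100)

    phys = pd.DataFrame({"participant": state.participant, "arm": state.arm,
                         "time_min": PHYS_GRID_MIN, "hr_bpm": hr, **deq})

    raters = {}
    for tp in tps:
        truth = bool(state.impaired[tp])
        p = config.rater_sensitivity if truth else 1.0 - config.rater_specificity
        raters[tp] = (bool(rng.random() < p), bool(rng.random() < p))

    fst = None
    if state.arm == THC:
        sess_imp = state.any_impaired()
        p_pos = config.fst_sensitivity if sess_imp else config.fst_false_positive_rate
        positive = bool(rng.random() < p_pos)
        if positive:
            score = 2 + int(rng.binomial(2, 0.5))
        else:
            score = int(rng.binomial(1, 0.5))
        fst = {"participant": state.participant, "fst_positive": positive,
               "fst_score": score, "session_impaired": sess_imp}
    return phys, raters, fst


# ---------------------------------------------------------------------------
# cohort assembly


def generate_cohort(config: CohortConfig, include_signals: bool = True,
                    scan_callback: Callable[[RawScan], None] | None = None
                    ) -> Cohort:
    """Generate the full synthetic crossover cohort.

    With ``include_signals=False`` only the study structure (latent states,
    physiology, raters, FST, scan schedule) is produced — useful for fast
    structural and labeling studies. If ``scan_callback`` is given, each scan
    is passed to it right after generation and its intensity matrix is then
    dropped, keeping memory flat for study-scale cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tps = config.postdose_timepoints
    # per-scan prevalence = P(responder) * (1 - inconsistent/2)
    p_resp = min(1.0, config.impairment_prevalence_target
                 / (1.0 - config.inconsistent_fraction / 2.0))

    scans: list[RawScan] = []
    latents: list[LatentState] = []
    phys_rows, rater_rows, fst_rows = [], [], []
    cols = intensity_columns(config.n_channels, config.wavelengths)
    montage = default_montage(config.n_channels)

    for i in range(config.n_participants):
        pid = f"P{i + 1:03d}"
        base_hr = float(rng.normal(70.0, 7.0))
        tolerance = float(rng.beta(2.0, 2.0))
        dose = float(np.clip(rng.normal(35.0, 14.0), 5.0, 80.0))
        responder = rng.random() < p_resp
        if responder and rng.random() < config.inconsistent_fraction:
            which = rng.integers(0, len(tps))
            impaired = {tp: (j == which) for j, tp in enumerate(tps)}
        elif responder:
            impaired = {tp: True for tp in tps}
        else:
            impaired = {tp: False for tp in tps}

        arms = list(rng.permutation([THC, PLACEBO]))[:config.sessions_per_participant]
        for arm in arms:
            state = LatentState(participant=pid, arm=arm,
                                impaired=(dict(impaired) if arm == THC
                                          else {tp: False for tp in tps}),
                                tolerance=tolerance, dose_mg=dose)
            latents.append(state)
            phys, raters, fst = simulate_physiology_and_raters(state, config,
                                                               rng, base_hr)
            phys_rows.append(phys)
            for tp, (ra, rb) in raters.items():
                rater_rows.append((pid, arm, tp, ra, rb))
            if fst is not None:
                fst_rows.append(fst)

            for scan_type in config.scan_types:
                for tp in config.scan_timepoints:
                    if rng.random() < config.scan_missing_rate:
                        continue
                    if include_signals:
                        hbo, hbr = simulate_hemodynamics(state, tp, scan_type,
                                                         config, rng)
                        intensity, meta = hb_to_intensity(hbo, hbr, config, rng)
                    else:
                        intensity, meta = None, {}
                    scan = RawScan(participant=pid, arm=arm, timepoint=tp,
                                   scan_type=scan_type, intensity=intensity,
                                   columns=cols, montage=montage,
                                   sample_rate=config.sample_rate,
                                   scan_time_min=SCAN_TIMES_MIN[tp],
                                   physiology=phys, meta=meta)
                    if scan_callback is not None:
                        scan_callback(scan)
                        scan.intensity = None
                    scans.append(scan)

    physiology = pd.concat(phys_rows, ignore_index=True)
    raters = pd.DataFrame(rater_rows, columns=["participant", "arm", "timepoint",
                                               "rater_a", "rater_b"])
    fst = pd.DataFrame(fst_rows, columns=["participant", "fst_positive",
                                          "fst_score", "session_impaired"])
    return Cohort(config=config, scans=scans, latents=latents,
                  physiology=physiology, raters=raters, fst=fst)
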