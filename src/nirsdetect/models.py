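"""Scan-level impairment classifiers.

Two model families share one interface (``extract_features`` + ``fit`` giving
a submodel with a raw, unbounded ``score``):

* a random convolutional-kernel transform (normal mean-centered weights,
  log-uniform dilations, random channel subsets; PPV and max pooled per
  kernel) with a closed-form ridge head and *sequential feature detachment* —
  iterative pruning of the least-salient features with refitting, keeping the
  mask that best trades held-out accuracy against model size;
* a parallel feature-extraction ensemble of four submodel blocks (per-channel
  moments, spectral band powers, cross-channel correlations, and a small
  kernel pool) feeding a cross-entropy-trained linear head.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError, DataError, TrainingError

KERNEL_LENGTHS = (7, 9, 11)


# ---------------------------------------------------------------------------
# random convolutional kernels


@dataclass
class KernelBank:
    weights: list[np.ndarray]  # each (n_sel_channels, length), rows mean-centered
    biases: np.ndarray
    dilations: np.ndarray
    paddings: np.ndarray  # 0 or (length-1)*dilation//2
    channels: list[np.ndarray]  # selected series indices per kernel
    seed: int
    n_series: int
    series_length: int

    def __len__(self) -> int:
        return len(self.weights)


def sample_kernels(n_kernels: int, n_series: int, series_length: int,
                   seed: int = 0) -> KernelBank:
    """Draw a reproducible random kernel bank.

    Lengths are uniform on {7, 9, 11}; weights are standard normal,
    mean-centered per channel row; biases uniform on [-1, 1]; dilations
    log-uniform so the effective span never exceeds the series; channel
    subsets have log-uniform size over the available series.
    """
    if n_kernels < 1:
        raise ConfigurationError("n_kernels must be >= 1")
    rng = np.random.default_rng(seed)
    weights, channels = [], []
    biases = np.empty(n_kernels)
    dilations = np.empty(n_kernels, dtype=int)
    paddings = np.empty(n_kernels, dtype=int)
    for k in range(n_kernels):
        length = int(rng.choice(KERNEL_LENGTHS))
        max_exp = np.log2(max((series_length - 1) / (length - 1), 1.0))
        dilation = int(2 ** rng.uniform(0, max_exp))
        # subset size log-uniform, capped at 8 channels per kernel
        cap = min(n_series, 8)
        n_sel = int(np.clip(2 ** rng.uniform(0, np.log2(cap)), 1,
                            cap)) if cap > 1 else 1
        sel = np.sort(rng.choice(n_series, size=n_sel, replace=False))
        w = rng.standard_normal((n_sel, length))
        w -= w.mean(axis=1, keepdims=True)
        pad = ((length - 1) * dilation) // 2 if rng.random() < 0.5 else 0
        weights.append(w)
        channels.append(sel)
        biases[k] = rng.uniform(-1.0, 1.0)
        dilations[k] = dilation
        paddings[k] = pad
    return KernelBank(weights=weights, biases=biases, dilations=dilations,
                      paddings=paddings, channels=channels, seed=seed,
                      n_series=n_series, series_length=series_length)


def kernel_transform(X: np.ndarray, bank: KernelBank) -> np.ndarray:
    """Apply the kernel bank to ``X`` (n_scans, n_series, T).

    Returns (n_scans, 2 * n_kernels): for each kernel the PPV (fraction of
    convolution outputs strictly greater than zero — exact zeros do not
    count) and the max over valid positions. Vectorized over scans; each
    kernel is a dilated multivariate convolution summed over its channel
    subset plus its bias.
    """
    X = np.asarray(X, float)
    if X.ndim != 3:
        raise DataError("X must be (n_scans, n_series, length)")
    n_scans, n_series, T = X.shape
    feats = np.empty((n_scans, 2 * len(bank)))
    for k in range(len(bank)):
        w = bank.weights[k]
        d = int(bank.dilations[k])
        pad = int(bank.paddings[k])
        length = w.shape[1]
        span = (length - 1) * d
        out_len = T + 2 * pad - span
        if out_len < 1:
            raise DataError(
                f"series length {T} shorter than kernel {k} span {span - 2 * pad + 1}")
        sub = X[:, bank.channels[k], :]
        if pad:
            sub = np.pad(sub, ((0, 0), (0, 0), (pad, pad)))
        out = np.full((n_scans, out_len), bank.biases[k])
        for ci in range(w.shape[0]):
            for i in range(length):
                out += w[ci, i] * sub[:, ci, i * d:i * d + out_len]
        feats[:, 2 * k] = (out > 0).mean(axis=1)
        feats[:, 2 * k + 1] = out.max(axis=1)
    return feats


# ---------------------------------------------------------------------------
# linear heads


@dataclass
class TrainedSubmodel:
    """A fitted linear head over (a masked subset of) extracted features."""

    kind: str  # "ridge" | "crossentropy"
    mean: np.ndarray
    scale: np.ndarray
    coef: np.ndarray
    intercept: float
    mask: np.ndarray  # active-feature mask over the full feature vector
    train_scores: np.ndarray | None = None
    detach_curve: list | None = None

    def score(self, features: np.ndarray) -> np.ndarray:
        """Raw, unbounded decision score (linear response / log-odds)."""
        f = np.asarray(features, float)[:, self.mask]
        z = (f - self.mean) / self.scale
        return z @ self.coef + self.intercept


def _standardize(F: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = F.mean(axis=0)
    scale = F.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (F - mean) / scale, mean, scale


DEFAULT_ALPHAS = tuple(float(a) for a in np.logspace(-2, 4, 10))


def fit_ridge_head(features: np.ndarray, labels: np.ndarray,
                   alphas: Sequence[float] = DEFAULT_ALPHAS,
                   mask: np.ndarray | None = None) -> TrainedSubmodel:
    """Closed-form ridge head on standardized features.

    The regularization strength is chosen by efficient leave-one-out scoring;
    class imbalance is absorbed through balanced class weights (equivalent to
    target encoding by class proportions).
    """
    from sklearn.linear_model import RidgeClassifierCV

    F = np.asarray(features, float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise TrainingError("ridge head needs both classes present")
    if mask is None:
        mask = np.ones(F.shape[1], bool)
    Z, mean, scale = _standardize(F[:, mask])
    clf = RidgeClassifierCV(alphas=list(alphas), class_weight="balanced")
    clf.fit(Z, y)
    model = TrainedSubmodel(kind="ridge", mean=mean, scale=scale,
                            coef=clf.coef_.ravel().copy(),
                            intercept=float(np.ravel(clf.intercept_)[0]),
                            mask=mask.copy())
    model.train_scores = model.score(F)
    return model


def sequential_detach(features: np.ndarray, labels: np.ndarray,
                      prune_fraction: float = 0.05,
                      tradeoff_c: float = 0.05,
                      min_features: int = 1,
                      min_fraction: float = 0.0,
                      val_fraction: float = 0.25,
                      alphas: Sequence[float] = DEFAULT_ALPHAS,
                      seed: int = 0) -> TrainedSubmodel:
    """Sequential feature detachment on a ridge head.

    Repeatedly removes the ``prune_fraction`` of active features with the
    smallest saliency |weight| x feature-SD (on standardized features this is
    |weight|), refits, and records accuracy on an internal stratified
    holdout. The returned model uses the mask from the step maximizing
    (holdout accuracy - tradeoff_c * fraction retained); with
    ``tradeoff_c=0`` this is the accuracy argmax alone. Pruning stops before
    the active set would fall below ``min_features`` (or ``min_fraction`` of
    the full set); the active set shrinks monotonically.
    """
    from sklearn.model_selection import train_test_split

    F = np.asarray(features, float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise TrainingError("sequential detachment needs both classes present")
    idx_tr, idx_val = train_test_split(
        np.arange(F.shape[0]), test_size=val_fraction, stratify=y,
        random_state=seed)
    floor = max(min_features, int(np.ceil(min_fraction * F.shape[1])), 1)

    mask = np.ones(F.shape[1], bool)
    curve = []  # (mask, n_active, val_accuracy)
    while True:
        model = fit_ridge_head(F[idx_tr], y[idx_tr], alphas=alphas, mask=mask)
        val_acc = float(((model.score(F[idx_val]) > 0).astype(int)
                         == y[idx_val]).mean())
        curve.append((mask.copy(), int(mask.sum()), val_acc))
        n_active = int(mask.sum())
        if n_active <= floor:
            break
        n_remove = min(max(int(round(prune_fraction * n_active)), 1),
                       n_active - floor)
        saliency = np.abs(model.coef)  # features are standardized: SD = 1
        active_idx = np.flatnonzero(mask)
        drop = active_idx[np.argsort(saliency, kind="stable")[:n_remove]]
        mask = mask.copy()
        mask[drop] = False

    n_full = F.shape[1]
    objective = [acc - tradeoff_c * (na / n_full) for _, na, acc in curve]
    best = int(np.argmax(objective))
    best_mask = curve[best][0]
    final = fit_ridge_head(F, y, alphas=alphas, mask=best_mask)
    final.detach_curve = [{"n_active": na, "val_accuracy": acc, "mask": m}
                          for m, na, acc in curve]
    return final


def fit_crossentropy_head(features: np.ndarray, labels: np.ndarray,
                          l2_c: float = 1.0, balanced: bool = False,
                          max_iter: int = 5000,
                          tol: float = 1e-10) -> TrainedSubmodel:
    """L2-penalized logistic (cross-entropy) linear head, deterministic
    lbfgs fit from zero init; the raw score is the log-odds."""
    from sklearn.linear_model import LogisticRegression

    F = np.asarray(features, float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise TrainingError("cross-entropy head needs both classes present")
    Z, mean, scale = _standardize(F)
    clf = LogisticRegression(C=l2_c, max_iter=max_iter, tol=tol,
                             class_weight="balanced" if balanced else None)
    clf.fit(Z, y)
    if clf.n_iter_[0] >= max_iter:
        raise TrainingError(
            f"cross-entropy head failed to converge in {max_iter} iterations "
            f"(|coef| max {np.abs(clf.coef_).max():.3g})")
    model = TrainedSubmodel(kind="crossentropy", mean=mean, scale=scale,
                            coef=clf.coef_.ravel().copy(),
                            intercept=float(clf.intercept_[0]),
                            mask=np.ones(F.shape[1], bool))
    model.train_scores = model.score(F)
    return model


# ---------------------------------------------------------------------------
# parallel feature extraction (4 submodel blocks)


def band_power(x: np.ndarray, sample_rate: float,
               band: tuple[float, float]) -> np.ndarray:
    """Bandwidth-normalized mean periodogram power inside ``band`` per column
    of ``x`` (samples x channels)."""
    from scipy.signal import periodogram

    freqs, psd = periodogram(x, fs=sample_rate, axis=0)
    sel = (freqs >= band[0]) & (freqs < band[1])
    if not sel.any():
        return np.zeros(x.shape[1])
    return psd[sel].mean(axis=0)


DEFAULT_BANDS = ((0.01, 0.04), (0.04, 0.08), (0.08, 0.15))


def parallel_features(hbo: np.ndarray, hbr: np.ndarray, sample_rate: float,
                      bands: tuple = DEFAULT_BANDS,
                      kernel_pool: KernelBank | None = None
                      ) -> tuple[np.ndarray, dict[str, slice]]:
    """Concatenated features from the four parallel submodel blocks.

    Blocks (per scan): (1) mean/SD/skew/kurtosis per channel for HbO and HbR;
    (2) per-channel power in three low-frequency bands for both species;
    (3) the upper triangle of the HbO cross-channel correlation matrix
    (zero-variance channels contribute 0 by convention); (4) a small random
    kernel pool over the stacked series. Returns the feature vector and the
    block-boundary slices.
    """
    from scipy.stats import kurtosis, skew

    C = hbo.shape[1]
    blocks: list[np.ndarray] = []
    bounds: dict[str, slice] = {}
    pos = 0

    moments = []
    for x in (hbo, hbr):
        moments.extend([x.mean(axis=0), x.std(axis=0),
                        skew(x, axis=0), kurtosis(x, axis=0)])
    m = np.concatenate(moments)
    m = np.nan_to_num(m, nan=0.0)  # zero-variance channels: skew/kurt -> 0
    blocks.append(m)
    bounds["moments"] = slice(pos, pos + m.size)
    pos += m.size

    bp = np.concatenate([band_power(x, sample_rate, b)
                         for x in (hbo, hbr) for b in bands])
    blocks.append(bp)
    bounds["band_power"] = slice(pos, pos + bp.size)
    pos += bp.size

    sd = hbo.std(axis=0)
    ok = sd > 0
    corr = np.zeros((C, C))
    if ok.sum() >= 2:
        sub = np.corrcoef(hbo[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = sub
    iu = np.triu_indices(C, k=1)
    cc = corr[iu]
    blocks.append(cc)
    bounds["correlation"] = slice(pos, pos + cc.size)
    pos += cc.size

    if kernel_pool is not None:
        X = np.concatenate([hbo.T, hbr.T])[None, :, :]
        kf = kernel_transform(X, kernel_pool)[0]
        blocks.append(kf)
        bounds["kernel_pool"] = slice(pos, pos + kf.size)
        pos += kf.size

    return np.concatenate(blocks), bounds


# ---------------------------------------------------------------------------
# model specifications (the interface the cross-validation engine consumes)


@dataclass
class DetachKernelModel:
    """Random-kernel transform + ridge head with sequential detachment."""

    n_kernels: int = 2000
    seed: int = 0
    prune_fraction: float = 0.1
    tradeoff_c: float = 0.05
    min_fraction: float = 0.15
    detach: bool = True
    alphas: Sequence[float] = DEFAULT_ALPHAS
    name: str = "detach_kernel"

    def extract_features(self, X: np.ndarray, sample_rate: float) -> np.ndarray:
        bank = sample_kernels(self.n_kernels, X.shape[1], X.shape[2], self.seed)
        return kernel_transform(X, bank)

    def fit(self, features: np.ndarray, labels: np.ndarray,
            seed: int = 0) -> TrainedSubmodel:
        if self.detach:
            return sequential_detach(features, labels,
                                     prune_fraction=self.prune_fraction,
                                     tradeoff_c=self.tradeoff_c,
                                     min_fraction=self.min_fraction,
                                     alphas=self.alphas, seed=seed)
        return fit_ridge_head(features, labels, alphas=self.alphas)


@dataclass
class ParallelFeatureModel:
    """Four-block parallel feature extraction + cross-entropy linear head."""

    pool_kernels: int = 100
    seed: int = 0
    l2_c: float = 1.0
    bands: tuple = DEFAULT_BANDS
    name: str = "parallel"

    def extract_features(self, X: np.ndarray, sample_rate: float) -> np.ndarray:
        C = X.shape[1] // 2
        pool = sample_kernels(self.pool_kernels, X.shape[1], X.shape[2],
                              self.seed) if self.pool_kernels else None
        feats = []
        for s in range(X.shape[0]):
            hbo, hbr = X[s, :C, :].T, X[s, C:, :].T
            f, _ = parallel_features(hbo, hbr, sample_rate, bands=self.bands,
                                     kernel_pool=pool)
            feats.append(f)
        return np.asarray(feats)

    def fit(self, features: np.ndarray, labels: np.ndarray,
            seed: int = 0) -> TrainedSubmodel:
        return fit_crossentropy_head(features, labels, l2_c=self.l2_c,
                                     balanced=True)
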