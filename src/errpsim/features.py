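"""Windowed-mean temporal features and per-feature normalization.

Single-trial ERP decoding here uses the mean amplitude in eight overlapping
post-stimulus time slots at eight fronto-central/parietal channels, giving 64
features per trial. Window membership is half-open on the sample grid
([a, b) ms) so the overlapping slots are well defined at shared endpoints.
Feature order is channels-outer, windows-inner.

Normalization is per-feature z-scoring, fit on training data only and applied
unchanged to evaluation data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .simulator import EpochsData

__all__ = [
    "DEFAULT_WINDOWS_MS",
    "DEFAULT_CHANNELS",
    "FeatureMatrix",
    "WindowMeanFeaturizer",
    "window_mean_features",
    "FeatureNormalizer",
    "fit_normalizer",
    "apply_normalizer",
]

#: eight overlapping slots, ms relative to the time-locking event
DEFAULT_WINDOWS_MS: tuple[tuple[float, float], ...] = (
    (0, 100), (100, 200), (150, 250), (200, 300),
    (250, 350), (300, 400), (350, 450), (400, 500),
)
#: the eight channels of the reduced (wet-cap) montage
DEFAULT_CHANNELS: tuple[str, ...] = ("FC1", "FC2", "C3", "Cz", "C4", "CP1", "CP2", "Pz")


@dataclass
class FeatureMatrix:
    """Trial-by-feature matrix with window/channel provenance."""

    values: np.ndarray  # (n_trials, n_features)
    window_defs: list[tuple[float, float]]
    channel_subset: list[str]
    labels: np.ndarray  # per-trial condition
    normalizer: "FeatureNormalizer | None" = None
    subject_id: str = ""

    @property
    def feature_names(self) -> list[str]:
        return [f"{ch}:{int(a)}-{int(b)}ms"
                for ch in self.channel_subset for a, b in self.window_defs]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class WindowMeanFeaturizer(BaseEstimator, TransformerMixin):
    """Mean amplitude per (channel, window) as a sklearn transformer.

    Operates on the raw epoch tensor (n_trials, n_channels, n_samples); the
    time axis and channel labels of that tensor are bound at construction.
    Stateless apart from precomputing sample masks in :meth:`fit`.
    """

    def __init__(self, times_ms, channel_labels, channels=DEFAULT_CHANNELS,
                 windows_ms=DEFAULT_WINDOWS_MS):
        self.times_ms = times_ms
        self.channel_labels = channel_labels
        self.channels = channels
        self.windows_ms = windows_ms

    def fit(self, X=None, y=None):
        times = np.asarray(self.times_ms, float)
        labels = list(self.channel_labels)
        missing = [c for c in self.channels if c not in labels]
        if missing:
            raise KeyError(f"channels not in data: {missing}")
        self.channel_idx_ = np.array([labels.index(c) for c in self.channels])
        masks = []
        for a, b in self.windows_ms:
            if a < times[0] or b > times[-1] + (times[1] - times[0]):
                raise ValueError(f"window [{a}, {b}) ms outside epoch time range")
            masks.append((times >= a) & (times < b))
        self.window_masks_ = np.array(masks)
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError("expected (n_trials, n_channels, n_samples)")
        sub = X[:, self.channel_idx_, :]  # (T, C, S)
        # (T, C, W): mean over in-window samples
        counts = self.window_masks_.sum(axis=1)
        sums = np.einsum("tcs,ws->tcw", sub, self.window_masks_.astype(float))
        feats = sums / counts[None, None, :]
        return feats.reshape(X.shape[0], -1)  # channels outer, windows inner


def window_mean_features(
    epochs: EpochsData,
    channels=DEFAULT_CHANNELS,
    windows=DEFAULT_WINDOWS_MS,
) -> FeatureMatrix:
    """Windowed-mean feature extraction for an epoched dataset."""
    fz = WindowMeanFeaturizer(epochs.times, epochs.channel_labels,
                              channels, windows).fit()
    return FeatureMatrix(
        values=fz.transform(epochs.data),
        window_defs=[tuple(w) for w in windows],
        channel_subset=list(channels),
        labels=epochs.labels.copy(),
        subject_id=epochs.subject_id,
    )


class FeatureNormalizer(BaseEstimator, TransformerMixin):
    """Per-feature z-scoring; constant features are left unscaled (sd
    treated as 1) with a warning."""

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            warnings.warn("constant feature(s) left unscaled")
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        if X.shape[1] != self.mean_.size:
            raise ValueError(
                f"feature count mismatch: normalizer fit on {self.mean_.size}, got {X.shape[1]}"
            )
        return (X - self.mean_) / self.scale_


def fit_normalizer(train: FeatureMatrix) -> FeatureNormalizer:
    if train.values.shape[0] == 0:
        raise ValueError("cannot fit a normalizer on an empty feature matrix")
    return FeatureNormalizer().fit(train.values)


def apply_normalizer(fm: FeatureMatrix, normalizer: FeatureNormalizer) -> FeatureMatrix:
    return FeatureMatrix(
        values=normalizer.transform(fm.values),
        window_defs=list(fm.window_defs),
        channel_subset=list(fm.channel_subset),
        labels=fm.labels.copy(),
        normalizer=normalizer,
        subject_id=fm.subject_id,
    )
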