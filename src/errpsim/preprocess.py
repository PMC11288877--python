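"""Preprocessing chain for continuous EEG.

Brings recorded (or concatenated simulated) EEG to the same epoch
representation as the simulator output: downsampling to 250 Hz, zero-phase
Hamming-windowed sinc FIR notch and band-pass (1-20 Hz) filtering, simple
bad-channel detection and interpolation, common-average re-referencing, and
epoch extraction around the feedback events with optional baseline
correction.

Readers for standard recording formats (EEGLAB SET, BrainVision, EDF) are
thin delegations to mne.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .simulator import EpochsData

logger = logging.getLogger(__name__)

__all__ = [
    "ContinuousEEG",
    "load_continuous",
    "resample",
    "filter_band",
    "detect_and_interpolate_bad_channels",
    "rereference_car",
    "extract_epochs",
    "preprocess_chain",
]


@dataclass
class ContinuousEEG:
    """A continuous multichannel recording with event markers."""

    data: np.ndarray  # (n_channels, n_samples), uV
    srate: float
    channel_labels: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)  # (sample, label)

    def __post_init__(self):
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite data")
        n = self.data.shape[1]
        for s, _ in self.events:
            if not 0 <= s < n:
                raise ValueError(f"event sample {s} out of bounds (0..{n - 1})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


def load_continuous(path, **kwargs) -> ContinuousEEG:
    """Read a raw EEG file (.set / .vhdr / .edf) via mne and convert to uV.

    Event labels are taken from the recording's annotations.
    """
    import mne

    path = str(path)
    if path.endswith(".set"):
        raw = mne.io.read_raw_eeglab(path, preload=True, **kwargs)
    elif path.endswith(".vhdr"):
        raw = mne.io.read_raw_brainvision(path, preload=True, **kwargs)
    elif path.endswith(".edf"):
        raw = mne.io.read_raw_edf(path, preload=True, **kwargs)
    else:
        raise ValueError(f"unsupported raw EEG format: {path!r} (.set/.vhdr/.edf)")
    events = [
        (int(round(onset * raw.info["sfreq"])), str(desc))
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
    ]
    return ContinuousEEG(
        data=raw.get_data() * 1e6,  # V -> uV
        srate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        events=events,
    )


def resample(eeg: ContinuousEEG, target_srate: float = 250.0) -> ContinuousEEG:
    """Polyphase resampling to ``target_srate``; event indices are rescaled
    and rounded to the nearest sample. Upsampling is refused."""
    if target_srate > eeg.srate:
        raise ValueError(f"upsampling {eeg.srate} -> {target_srate} Hz not supported")
    if target_srate == eeg.srate:
        return eeg
    from fractions import Fraction

    frac = Fraction(target_srate / eeg.srate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(eeg.data, up, down, axis=1)
    n = data.shape[1]
    events = [
        (min(int(round(s * target_srate / eeg.srate)), n - 1), lab)
        for s, lab in eeg.events
    ]
    return ContinuousEEG(data=data, srate=target_srate,
                         channel_labels=list(eeg.channel_labels), events=events)


def _hamming_sinc_fir(srate: float, low: float | None, high: float | None,
                      pass_zero) -> np.ndarray:
    """Hamming-windowed sinc FIR with the common transition-width heuristic
    (25% of the lower cutoff, at least 2 Hz, at most the cutoff itself)."""
    edges = [f for f in (low, high) if f is not None]
    f_min = min(edges)
    trans = min(max(0.25 * f_min, 2.0), f_min)
    numtaps = int(np.ceil(3.3 / (trans / srate)))
    numtaps += 1 - numtaps % 2  # odd length -> type I linear phase
    return signal.firwin(numtaps, edges, pass_zero=pass_zero, window="hamming", fs=srate)


def _filtfilt(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """One-pass linear-phase FIR filtering with group-delay compensation
    (zero-phase overall), with reflective padding at the edges."""
    pad = len(taps)  # >= group delay
    ext = np.concatenate(
        [data[:, pad:0:-1], data, data[:, -2:-pad - 2:-1]], axis=1
    )
    out = signal.lfilter(taps, 1.0, ext, axis=1)
    delay = (len(taps) - 1) // 2
    return out[:, pad + delay: pad + delay + data.shape[1]]


def filter_band(eeg: ContinuousEEG, low: float = 1.0, high: float = 20.0,
                notch: float | None = 50.0, notch_width: float = 4.0) -> ContinuousEEG:
    """Zero-phase Hamming-windowed sinc FIR filtering.

    A band-stop notch (default 50 Hz, for European mains) is applied before
    the band-pass; pass ``notch=None`` to skip it (it is also skipped when
    it lies at or above Nyquist).
    """
    if not 0 < low < high:
        raise ValueError(f"invalid band: ({low}, {high})")
    if high >= eeg.srate / 2:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist ({eeg.srate / 2} Hz)")
    data = eeg.data
    if notch is not None and notch < eeg.srate / 2:
        taps = _hamming_sinc_fir(
            eeg.srate, notch - notch_width / 2, notch + notch_width / 2, pass_zero=True
        )
        data = _filtfilt(data, taps)
    taps = _hamming_sinc_fir(eeg.srate, low, high, pass_zero=False)
    data = _filtfilt(data, taps)
    return ContinuousEEG(data=data, srate=eeg.srate,
                         channel_labels=list(eeg.channel_labels),
                         events=list(eeg.events))


def detect_and_interpolate_bad_channels(
    eeg: ContinuousEEG, z_thresh: float = 5.0, n_neighbors: int = 4
) -> tuple[ContinuousEEG, list[str]]:
    """Flag channels by robust log-variance z-score (> ``z_thresh``) or
    flatline, and replace them by the inverse-distance weighted average of
    the nearest good channels.

    This is a deliberately simple detector for gross artifact channels; it
    does not attempt ICA-based artifact classification.
    """
    if eeg.n_channels < 4:
        raise ValueError("need at least 4 channels")
    var = eeg.data.var(axis=1)
    flat = var < 1e-12
    logv = np.log(np.where(flat, np.nan, var))
    med = np.nanmedian(logv)
    mad = np.nanmedian(np.abs(logv - med))
    scale = 1.4826 * mad if mad > 0 else np.nanstd(logv) or 1.0
    z = (logv - med) / scale
    bad = flat | (np.abs(np.nan_to_num(z)) > z_thresh)
    bad_idx = np.flatnonzero(bad)
    if bad_idx.size == 0:
        return eeg, []
    if bad_idx.size > eeg.n_channels / 2:
        raise ValueError("recording unusable: more than 50% bad channels")
    from .headmodel import montage_positions

    pos = montage_positions(eeg.channel_labels)
    good_idx = np.flatnonzero(~bad)
    data = eeg.data.copy()
    for b in bad_idx:
        d = np.linalg.norm(pos[good_idx] - pos[b], axis=1)
        nearest = good_idx[np.argsort(d)[:n_neighbors]]
        w = 1.0 / np.maximum(np.sort(d)[:n_neighbors], 1e-6)
        data[b] = (w[:, None] * eeg.data[nearest]).sum(axis=0) / w.sum()
    bad_labels = [eeg.channel_labels[i] for i in bad_idx]
    logger.info("interpolated bad channels: %s", bad_labels)
    return (
        ContinuousEEG(data=data, srate=eeg.srate,
                      channel_labels=list(eeg.channel_labels),
                      events=list(eeg.events)),
        bad_labels,
    )


def rereference_car(eeg: ContinuousEEG) -> ContinuousEEG:
    """Common average reference: subtract the instantaneous channel mean."""
    data = eeg.data - eeg.data.mean(axis=0, keepdims=True)
    return ContinuousEEG(data=data, srate=eeg.srate,
                         channel_labels=list(eeg.channel_labels),
                         events=list(eeg.events))


def extract_epochs(
    eeg: ContinuousEEG,
    window: tuple[float, float] = (-0.2, 0.6),
    baseline: tuple[float, float] | None = (-0.2, 0.0),
    exclude_labels: set[str] | frozenset[str] = frozenset(),
) -> EpochsData:
    """Cut half-open epochs ``[window[0], window[1])`` s around each event.

    Events whose label is in ``exclude_labels`` are dropped; events too close
    to the recording edge are dropped with a warning. Baseline correction
    subtracts the per-trial per-channel mean over the baseline window.
    """
    lo = int(round(window[0] * eeg.srate))
    hi = int(round(window[1] * eeg.srate))
    n_samp = hi - lo
    times = (np.arange(lo, hi) / eeg.srate) * 1000.0
    total = eeg.data.shape[1]
    epochs, labels = [], []
    for s, lab in eeg.events:
        if lab in exclude_labels:
            continue
        a, b = s + lo, s + hi
        if a < 0 or b > total:
            warnings.warn(f"event at sample {s} too close to recording edge; dropped")
            continue
        epochs.append(eeg.data[:, a:b])
        labels.append(lab)
    if not epochs:
        warnings.warn("no epochs extracted")
        data = np.empty((0, eeg.n_channels, n_samp))
    else:
        data = np.stack(epochs)
    if baseline is not None and data.size:
        mask = (times >= baseline[0] * 1000.0) & (times < baseline[1] * 1000.0)
        data = data - data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochsData(
        data=data,
        times=times,
        labels=np.asarray(labels, dtype="U7"),
        srate=eeg.srate,
        channel_labels=list(eeg.channel_labels),
        provenance={"preprocessed": True},
    )


def preprocess_chain(
    eeg: ContinuousEEG,
    target_srate: float = 250.0,
    band: tuple[float, float] = (1.0, 20.0),
    notch: float | None = 50.0,
    window: tuple[float, float] = (-0.2, 0.6),
    baseline: tuple[float, float] | None = (-0.2, 0.0),
    exclude_labels: frozenset[str] = frozenset(),
) -> tuple[EpochsData, list[str]]:
    """The full chain: resample, filter, bad-channel repair, CAR, epoch."""
    eeg = resample(eeg, target_srate)
    eeg = filter_band(eeg, band[0], band[1], notch)
    eeg, bad = detect_and_interpolate_bad_channels(eeg)
    eeg = rereference_car(eeg)
    return extract_epochs(eeg, window, baseline, exclude_labels), bad
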