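"""Brown-noise background activity.

Ongoing background EEG is modelled as brown noise (power spectral density
proportional to 1/f^2) emitted from many spatially dispersed sources and
projected through the lead field. Each noise source gets an independent
realization per epoch, scaled so its maximum absolute value matches a target
amplitude drawn uniformly from [amplitude - dev, amplitude + dev].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend

__all__ = ["NoiseSpec", "brown_noise", "scale_to_amplitude"]


@dataclass
class NoiseSpec:
    """Background-noise configuration.

    Defaults follow common practice for simulated ERP studies: 80 brown-noise
    sources at least 25 mm apart, each scaled to 37.5 +- 0.5 uV per epoch.
    ``gain`` is a single scalar multiplying the summed scalp projection; see
    the methods note for the calibration procedure that sets its default.
    """

    color: str = "brown"
    amplitude: float = 37.5  # uV, per-source max-abs target
    amplitude_dev: float = 0.5  # uV, uniform half-range of the target
    n_sources: int = 80
    min_spacing: float = 25.0  # mm
    gain: float = 1.0

    def __post_init__(self):
        if self.color != "brown":
            raise ValueError(f"unsupported noise color: {self.color!r}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")

    def to_dict(self) -> dict:
        return {
            "color": self.color,
            "amplitude": self.amplitude,
            "amplitude_dev": self.amplitude_dev,
            "n_sources": self.n_sources,
            "min_spacing": self.min_spacing,
            "gain": self.gain,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSpec":
        return cls(**d)


def brown_noise(n_samples: int, rng, size: int | tuple = ()) -> np.ndarray:
    """Unit-scale brown noise: cumulative sum of white Gaussian increments,
    linearly detrended (hence zero mean). log-log PSD slope is ~ -2.

    ``size`` prepends batch dimensions, e.g. ``size=(n_trials, n_sources)``
    yields an (n_trials, n_sources, n_samples) array.
    """
    if n_samples < 16:
        raise ValueError("n_samples must be >= 16")
    if isinstance(size, int):
        size = (size,)
    w = rng.normal(size=tuple(size) + (n_samples,))
    x = np.cumsum(w, axis=-1)
    return detrend(x, axis=-1, type="linear")


def scale_to_amplitude(waveform: np.ndarray, amplitude: float, amplitude_dev: float, rng) -> np.ndarray:
    """Rescale waveform(s) so the max absolute value along the last axis
    equals a target drawn uniformly in [amplitude - dev, amplitude + dev]
    (one independent target per leading element)."""
    w = np.asarray(waveform, float)
    peak = np.abs(w).max(axis=-1)
    if np.any(peak == 0):
        raise ValueError("cannot scale a constant (zero-range) waveform")
    lo, hi = amplitude - amplitude_dev, amplitude + amplitude_dev
    target = rng.uniform(lo, hi, size=peak.shape) if amplitude_dev > 0 else np.full(peak.shape, float(amplitude))
    return w * (target / peak)[..., None] if w.ndim > 1 else w * (target / peak)
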