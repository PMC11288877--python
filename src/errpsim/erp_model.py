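"""ERP class definitions and per-trial waveform rendering.

An experimental condition (error or correct feedback) is a list of peak
components, each with a nominal latency, width and signed source amplitude
plus fractional trial-to-trial deviations and a generation probability.
Per trial, each component is independently present with its probability, its
parameters are drawn within +-dev of nominal (truncated normal, the stated
deviation being the maximum), and a single epoch-wide latency shift is shared
by all components.

Peaks are rendered as Gaussian pulses with sigma = width/6, i.e. the stated
width spans +-3 sigma of the pulse.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ErpComponent",
    "ErpClassSpec",
    "RealizedComponent",
    "RealizedTrialErp",
    "error_class_spec",
    "correct_class_spec",
    "sample_trial",
    "render_erp",
    "DEFAULT_SOURCE_CENTERS",
]

#: default dipole centers, mm head-centered (x right, y anterior, z up).
#: The error complex sits in medial fronto-central cortex so its projection
#: peaks at FCz/Cz; the late negativity is placed more parietally. These are
#: configurable defaults, not literature coordinates.
DEFAULT_SOURCE_CENTERS: dict[str, tuple[float, float, float]] = {
    "error/P200": (0.0, 30.0, 45.0),
    "error/N250": (0.0, 25.0, 40.0),
    "error/P320": (0.0, 20.0, 50.0),
    "error/N450": (0.0, -30.0, 50.0),
    "correct/P270": (0.0, 25.0, 45.0),
    "correct/P350": (0.0, 15.0, 50.0),
    "correct/N450": (0.0, -30.0, 50.0),
}


@dataclass
class ErpComponent:
    """One ERP peak: nominal parameters plus trial-to-trial variability."""

    name: str
    latency: float  # ms, peak center relative to the time-locking event
    width: float  # ms, full peak extent (+-3 sigma)
    amplitude: float  # microvolt at source level, signed
    latency_dev: float = 0.2  # fraction of value, maximum deviation
    width_dev: float = 0.2
    amplitude_dev: float = 0.2
    probability: float = 1.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError(f"{self.name}: width must be > 0")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"{self.name}: probability must be in [0, 1]")
        if min(self.latency_dev, self.width_dev, self.amplitude_dev) < 0:
            raise ValueError(f"{self.name}: deviations must be >= 0")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "latency": self.latency,
            "width": self.width,
            "amplitude": self.amplitude,
            "latency_dev": self.latency_dev,
            "width_dev": self.width_dev,
            "amplitude_dev": self.amplitude_dev,
            "probability": self.probability,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ErpComponent":
        return cls(**d)


@dataclass
class ErpClassSpec:
    """A named condition: components plus the epoch-wide latency shift bound.

    ``source_bindings`` (one per component) are attached by the simulator once
    sources have been selected from a lead field.
    """

    name: str
    components: list[ErpComponent]
    global_shift: float = 100.0  # ms, maximum epoch-wide latency shift
    source_bindings: list = field(default_factory=list)

    def __post_init__(self):
        if not self.components:
            raise ValueError("components must be non-empty")
        if self.source_bindings and len(self.source_bindings) != len(self.components):
            raise ValueError("need exactly one source binding per component")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "global_shift": self.global_shift,
            "components": [c.to_dict() for c in self.components],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ErpClassSpec":
        return cls(
            name=d["name"],
            global_shift=d.get("global_shift", 100.0),
            components=[ErpComponent.from_dict(c) for c in d["components"]],
        )


@dataclass
class RealizedComponent:
    name: str
    present: bool
    latency: float
    width: float
    amplitude: float


@dataclass
class RealizedTrialErp:
    """Parameters actually drawn for one trial."""

    components: list[RealizedComponent]
    shift: float  # ms, shared by all components


def error_class_spec() -> ErpClassSpec:
    """The error condition: a P200-N250-P320-N450 complex.

    All peaks are generated on every trial; deviations 20% of value; the
    whole complex shifts by up to +-100 ms per trial.
    """
    return ErpClassSpec(
        name="error",
        components=[
            ErpComponent("error/P200", latency=200.0, width=50.0, amplitude=20.0),
            ErpComponent("error/N250", latency=250.0, width=50.0, amplitude=-40.0),
            ErpComponent("error/P320", latency=320.0, width=120.0, amplitude=50.0),
            ErpComponent("error/N450", latency=450.0, width=150.0, amplitude=-40.0),
        ],
        global_shift=100.0,
    )


def correct_class_spec(
    rng, probability_range: tuple[float, float] = (0.5, 1.0)
) -> ErpClassSpec:
    """The correct condition: a slow double positivity plus a late negativity.

    The two positive peaks (270 ms / 20 uV / 200 ms and 350 ms / 10 uV /
    250 ms) model the slower, longer positivity of correct feedback; their
    generation probabilities are drawn once (per subject) uniformly from
    ``probability_range``, reflecting that these peaks are not consistently
    reported. The 450 ms negativity (-40 uV, 150 ms) is always generated.
    """
    p1, p2 = rng.uniform(*probability_range, size=2)
    return ErpClassSpec(
        name="correct",
        components=[
            ErpComponent("correct/P270", latency=270.0, width=200.0, amplitude=20.0,
                         probability=float(p1)),
            ErpComponent("correct/P350", latency=350.0, width=250.0, amplitude=10.0,
                         probability=float(p2)),
            ErpComponent("correct/N450", latency=450.0, width=150.0, amplitude=-40.0),
        ],
        global_shift=100.0,
    )


def _truncated_normal(rng, scale: float, bound: float, max_retries: int = 100) -> float:
    """Zero-mean normal draw with sd ``scale``, rejected outside +-bound."""
    if bound == 0.0:
        return 0.0
    for _ in range(max_retries):
        x = rng.normal(0.0, scale)
        if abs(x) <= bound:
            return float(x)
    return 0.0  # 3-sigma truncation: rejection failing 100x is impossible


def sample_trial(spec: ErpClassSpec, rng, max_retries: int = 10) -> RealizedTrialErp:
    """Draw one trial's realized parameters from a class spec.

    Deviations are truncated normal (sd = dev*|value|/3, truncated at
    dev*|value|, so the stated deviation is the maximum); the epoch-wide
    shift follows the same convention (sd = global_shift/3, truncated at
    +-global_shift) and is shared by all components, so the ERP keeps its
    overall shape in the trial average instead of being flattened by a
    heavy-tailed shift. Draw order: shift, then per component presence,
    latency, width, amplitude.
    """
    shift = _truncated_normal(rng, spec.global_shift / 3.0, spec.global_shift)
    comps = []
    for c in spec.components:
        present = bool(rng.random() < c.probability) if c.probability < 1.0 else True
        lat = c.latency + _truncated_normal(rng, c.latency_dev * abs(c.latency) / 3.0,
                                            c.latency_dev * abs(c.latency))
        width = 0.0
        for _ in range(max_retries):
            width = c.width + _truncated_normal(rng, c.width_dev * abs(c.width) / 3.0,
                                                c.width_dev * abs(c.width))
            if width > 0:
                break
        if width <= 0:
            raise ValueError(f"{c.name}: could not realise a positive width")
        amp = c.amplitude + _truncated_normal(rng, c.amplitude_dev * abs(c.amplitude) / 3.0,
                                              c.amplitude_dev * abs(c.amplitude))
        comps.append(RealizedComponent(c.name, present, lat + shift, width, amp))
    return RealizedTrialErp(components=comps, shift=shift)


def render_erp(realized: RealizedTrialErp, times: np.ndarray) -> np.ndarray:
    """Render each component as a Gaussian pulse on the time axis (ms).

    Returns an (n_components, n_times) array of source waveforms in uV;
    absent components render as zeros. Components are kept separate because
    each projects through its own source.
    """
    times = np.asarray(times, float)
    out = np.zeros((len(realized.components), times.size))
    for i, c in enumerate(realized.components):
        if not c.present:
            continue
        sigma = c.width / 6.0
        out[i] = c.amplitude * np.exp(-0.5 * ((times - c.latency) / sigma) ** 2)
    return out
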