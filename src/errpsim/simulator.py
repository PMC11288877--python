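"""Assembly of simulated subjects and datasets.

A simulated subject is built in a documented, reproducible order from a
single seed: (1) the correct-condition peak probabilities are drawn, and one
whole-ERP latency shift (up to +-100 ms) displaces the subject's ERP in time
while keeping its shape; (2) one
dipole is selected per ERP component by jittering a fixed center within a
10 mm radius, oriented to maximise the gain at the reference channel (Cz)
and then perturbed component-wise by +-20%; (3) background-noise sources are
selected (80 sources, >= 25 mm apart) with random orientations; (4) the
error/correct label sequence is laid out (exact error count, shuffled); and
(5) every trial is rendered independently (per-trial ERP parameter draws
plus per-source brown noise) and projected through the lead field.

Trial-to-trial variability parameters are identical across subjects;
inter-subject variability comes from the source jitter, orientation
deviation and correct-peak probabilities.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import yaml

from . import erp_model, headmodel, noise_model

__all__ = [
    "SimConfig",
    "EpochsData",
    "simulate_subject",
    "simulate_dataset",
    "write_epochs",
    "read_epochs",
    "epochs_to_continuous",
]

#: calibrated scalar on the summed projected noise; see docs/methods.md and
#: calibration.calibrate_noise_gain (subject-specific decoding target ~0.82).
DEFAULT_NOISE_GAIN = 0.5


def biosemi64_labels() -> list[str]:
    from mne.channels import make_standard_montage

    return list(make_standard_montage("biosemi64").get_positions()["ch_pos"])


@dataclass
class SimConfig:
    """Simulation parameters for one dataset."""

    srate: float = 250.0  # Hz
    epoch_length: float = 1.5  # s
    prestim: float = 0.5  # s before the time-locking event
    n_epochs: int = 1200
    error_rate: float = 0.2
    n_train_subjects: int = 15
    n_val_subjects: int = 10
    montage: list[str] = field(default_factory=biosemi64_labels)
    source_jitter_radius: float = 10.0  # mm, per-subject dipole jitter
    orientation_dev: float = 0.2  # +-20% per-subject orientation deviation
    reference_channel: str = "Cz"  # channel whose gain fixes orientations
    n_leadfield_sources: int = 6000
    noise: noise_model.NoiseSpec = field(default_factory=noise_model.NoiseSpec)
    noise_gain: float = DEFAULT_NOISE_GAIN
    correct_probability_range: tuple[float, float] = (0.0, 1.0)
    #: how the +-100 ms whole-ERP latency shift is applied: "subject" draws
    #: one shift per subject (shared by both conditions), preserving each
    #: subject's ERP shape while shifting its latency; "trial" redraws the
    #: shift on every trial.
    shift_mode: str = "subject"
    source_centers: dict = field(default_factory=lambda: dict(erp_model.DEFAULT_SOURCE_CENTERS))
    error_spec: dict | None = None  # optional override, ErpClassSpec.to_dict form
    correct_spec: dict | None = None
    master_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.error_rate < 1.0:
            raise ValueError("error_rate must be in (0, 1)")
        if not self.prestim < self.epoch_length:
            raise ValueError("prestim must be smaller than epoch_length")
        n = self.srate * self.epoch_length
        if abs(n - round(n)) > 1e-9:
            raise ValueError("srate * epoch_length must be integral")
        if self.shift_mode not in ("subject", "trial"):
            raise ValueError(f"shift_mode must be 'subject' or 'trial', got {self.shift_mode!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.srate * self.epoch_length))

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms on [-prestim, epoch_length - prestim)."""
        return np.arange(self.n_samples) / self.srate * 1000.0 - self.prestim * 1000.0

    def to_dict(self) -> dict:
        d = {
            "srate": self.srate,
            "epoch_length": self.epoch_length,
            "prestim": self.prestim,
            "n_epochs": self.n_epochs,
            "error_rate": self.error_rate,
            "n_train_subjects": self.n_train_subjects,
            "n_val_subjects": self.n_val_subjects,
            "montage": list(self.montage),
            "source_jitter_radius": self.source_jitter_radius,
            "orientation_dev": self.orientation_dev,
            "reference_channel": self.reference_channel,
            "n_leadfield_sources": self.n_leadfield_sources,
            "noise": self.noise.to_dict(),
            "noise_gain": self.noise_gain,
            "correct_probability_range": list(self.correct_probability_range),
            "shift_mode": self.shift_mode,
            "source_centers": {k: list(v) for k, v in self.source_centers.items()},
            "error_spec": self.error_spec,
            "correct_spec": self.correct_spec,
            "master_seed": self.master_seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "noise" in d:
            d["noise"] = noise_model.NoiseSpec.from_dict(d["noise"])
        if "correct_probability_range" in d:
            d["correct_probability_range"] = tuple(d["correct_probability_range"])
        if "source_centers" in d:
            d["source_centers"] = {k: tuple(v) for k, v in d["source_centers"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class EpochsData:
    """Epoched multichannel data with labels and provenance."""

    data: np.ndarray  # (n_trials, n_channels, n_samples), uV
    times: np.ndarray  # ms, common to all trials
    labels: np.ndarray  # str array, "error" | "correct"
    srate: float
    channel_labels: list[str]
    subject_id: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype="U7")
        bad = set(np.unique(self.labels)) - {"error", "correct"}
        if self.labels.size and bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        if self.data.shape[2] != self.times.size:
            raise ValueError("data/time axis mismatch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label: {label!r}") from None

    def get_channel(self, label: str) -> np.ndarray:
        """(n_trials, n_samples) view of one channel."""
        return self.data[:, self.channel_index(label), :]


def _class_specs(cfg: SimConfig, rng) -> tuple[erp_model.ErpClassSpec, erp_model.ErpClassSpec]:
    err = (erp_model.ErpClassSpec.from_dict(cfg.error_spec)
           if cfg.error_spec else erp_model.error_class_spec())
    if cfg.correct_spec:
        cor = erp_model.ErpClassSpec.from_dict(cfg.correct_spec)
    else:
        cor = erp_model.correct_class_spec(rng, cfg.correct_probability_range)
    return err, cor


def reference_orientation(cfg: SimConfig, lf: headmodel.LeadField,
                          component_name: str) -> np.ndarray:
    """Fixed per-component dipole orientation, shared by all subjects.

    Solved once from the gain tensor at the source nearest the component's
    nominal center: the orientation maximising the gain at the reference
    channel (Cz), standing in for an orientation chosen by inspection of the
    projection patterns. Inter-subject variability comes from the +-20%
    deviation applied on top per subject, not from re-solving per subject.
    """
    center = cfg.source_centers.get(component_name)
    if center is None:
        raise KeyError(f"no source center configured for component {component_name!r}")
    nearest = headmodel.pick_source_near(lf, center, 0.0, None)
    return headmodel.best_orientation_for_channel(lf, nearest.source_index,
                                                  cfg.reference_channel)


def _bind_sources(cfg: SimConfig, lf: headmodel.LeadField,
                  spec: erp_model.ErpClassSpec, rng) -> np.ndarray:
    """Select one dipole per component; returns per-component scalp gain
    vectors, shape (n_components, n_channels)."""
    gains = np.empty((len(spec.components), lf.n_channels))
    bindings = []
    for i, comp in enumerate(spec.components):
        center = cfg.source_centers.get(comp.name)
        if center is None:
            raise KeyError(f"no source center configured for component {comp.name!r}")
        sel = headmodel.pick_source_near(lf, center, cfg.source_jitter_radius, rng)
        sel.component_name = comp.name
        orient = reference_orientation(cfg, lf, comp.name)
        sel.orientation = headmodel.orient_with_deviation(orient, cfg.orientation_dev, rng)
        gains[i] = lf.project(sel.source_index, sel.orientation)
        bindings.append(sel)
    spec.source_bindings = bindings
    return gains


def _render_class(cfg: SimConfig, spec: erp_model.ErpClassSpec,
                  comp_gains: np.ndarray, n_trials: int, rng) -> np.ndarray:
    """Render and project n_trials epochs of one condition (no noise)."""
    times = cfg.times_ms
    out = np.zeros((n_trials, comp_gains.shape[1], times.size), dtype=np.float32)
    for t in range(n_trials):
        realized = erp_model.sample_trial(spec, rng)
        waves = erp_model.render_erp(realized, times)  # (n_comp, n_samples)
        out[t] = (comp_gains.T @ waves).astype(np.float32)
    return out


def _add_noise(cfg: SimConfig, lf: headmodel.LeadField, data: np.ndarray, rng,
               chunk: int = 100) -> None:
    """Add projected brown noise to every epoch, in place."""
    ns = cfg.noise
    idx = headmodel.pick_spaced_sources(lf, ns.n_sources, ns.min_spacing, rng)
    orient = rng.normal(size=(ns.n_sources, 3))
    orient /= np.linalg.norm(orient, axis=1, keepdims=True)
    # (n_channels, n_noise_sources) projection matrix
    M = np.einsum("csk,sk->cs", lf.gains[:, idx, :], orient)
    n_trials, _, n_samples = data.shape
    for lo in range(0, n_trials, chunk):
        hi = min(lo + chunk, n_trials)
        w = noise_model.brown_noise(n_samples, rng, size=(hi - lo, ns.n_sources))
        w = noise_model.scale_to_amplitude(w, ns.amplitude, ns.amplitude_dev, rng)
        data[lo:hi] += (cfg.noise_gain * ns.gain) * np.einsum(
            "cs,tsn->tcn", M, w
        ).astype(np.float32)


def simulate_subject(cfg: SimConfig, lf: headmodel.LeadField,
                     subject_seed, subject_id: str = "") -> EpochsData:
    """Simulate one subject's epochs.

    ``subject_seed`` may be an int or a numpy SeedSequence. The result is
    bit-reproducible for a fixed (config, lead field, seed) triple.
    """
    missing = [ch for ch in cfg.montage if ch not in lf.channel_labels]
    if missing:
        raise headmodel.LeadFieldError(f"lead field missing channels: {missing}")
    ss = (subject_seed if isinstance(subject_seed, np.random.SeedSequence)
          else np.random.SeedSequence(subject_seed))
    ss_setup, ss_trials, ss_noise, ss_order = ss.spawn(4)
    rng_setup = np.random.default_rng(ss_setup)

    err_spec, cor_spec = _class_specs(cfg, rng_setup)
    subject_shift = 0.0
    if cfg.shift_mode == "subject":
        # one whole-ERP latency shift per subject, shared by both conditions:
        # the subject's ERP keeps its shape but is displaced in time, which is
        # the dominant obstacle to cross-subject transfer of temporal features
        bound = max(err_spec.global_shift, cor_spec.global_shift)
        subject_shift = erp_model._truncated_normal(rng_setup, bound / 3.0, bound)
        for spec in (err_spec, cor_spec):
            for comp in spec.components:
                comp.latency += subject_shift
            spec.global_shift = 0.0
    err_gains = _bind_sources(cfg, lf, err_spec, rng_setup)
    cor_gains = _bind_sources(cfg, lf, cor_spec, rng_setup)

    n_err = int(round(cfg.error_rate * cfg.n_epochs))
    n_cor = cfg.n_epochs - n_err

    rng_trials = np.random.default_rng(ss_trials)
    err_data = _render_class(cfg, err_spec, err_gains, n_err, rng_trials)
    cor_data = _render_class(cfg, cor_spec, cor_gains, n_cor, rng_trials)

    order = np.random.default_rng(ss_order).permutation(cfg.n_epochs)
    labels = np.array(["error"] * n_err + ["correct"] * n_cor, dtype="U7")[order]
    data = np.concatenate([err_data, cor_data], axis=0)[order]

    _add_noise(cfg, lf, data, np.random.default_rng(ss_noise))

    return EpochsData(
        data=data,
        times=cfg.times_ms,
        labels=labels,
        srate=cfg.srate,
        channel_labels=list(cfg.montage),
        subject_id=subject_id,
        provenance={
            "config_hash": cfg.config_hash(),
            "seed_entropy": ss.entropy,
            "subject_shift_ms": subject_shift,
            "error_spec": err_spec.to_dict(),
            "correct_spec": cor_spec.to_dict(),
            "error_sources": [int(s.source_index) for s in err_spec.source_bindings],
            "correct_sources": [int(s.source_index) for s in cor_spec.source_bindings],
        },
    )


def subject_seed_sequences(cfg: SimConfig) -> tuple[np.random.SeedSequence, list, list]:
    """Derive the lead-field seed and per-subject seeds from the master seed."""
    ss = np.random.SeedSequence(cfg.master_seed)
    children = ss.spawn(1 + cfg.n_train_subjects + cfg.n_val_subjects)
    lf_ss = children[0]
    train_ss = children[1:1 + cfg.n_train_subjects]
    val_ss = children[1 + cfg.n_train_subjects:]
    return lf_ss, train_ss, val_ss


def build_leadfield(cfg: SimConfig, lf_seed=None) -> headmodel.LeadField:
    lf_ss = lf_seed if lf_seed is not None else subject_seed_sequences(cfg)[0]
    return headmodel.build_spherical_leadfield(
        cfg.montage, n_sources=cfg.n_leadfield_sources, seed=lf_ss
    )


def simulate_dataset(cfg: SimConfig, lf: headmodel.LeadField | None = None
                     ) -> tuple[list[EpochsData], list[EpochsData]]:
    """Simulate the full training + validation dataset.

    Returns (training subjects, validation subjects); per-subject seeds are
    spawned from ``cfg.master_seed`` so any two subjects differ in their
    source selections and per-trial draws.
    """
    lf_ss, train_ss, val_ss = subject_seed_sequences(cfg)
    if lf is None:
        lf = build_leadfield(cfg, lf_ss)
    train = [simulate_subject(cfg, lf, s, subject_id=f"train-{i:02d}")
             for i, s in enumerate(train_ss)]
    val = [simulate_subject(cfg, lf, s, subject_id=f"val-{i:02d}")
           for i, s in enumerate(val_ss)]
    return train, val


# ---------------------------------------------------------------------------
# persistence (HDF5 layout: /data uV, /times_ms, /labels, /channels, /srate,
# /provenance JSON; events as a sibling TSV)

_LAYOUT_VERSION = 1


def write_epochs(epochs: EpochsData, path, events_path=None) -> None:
    """Write epochs plus a tab-separated events table (trial index, onset
    sample in the concatenated recording, label)."""
    path = str(path)
    with h5py.File(path, "w") as f:
        f.attrs["layout_version"] = _LAYOUT_VERSION
        f.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=1)
        f.create_dataset("times_ms", data=epochs.times)
        f.create_dataset("labels", data=np.array([s.encode() for s in epochs.labels]))
        f.create_dataset("channels", data=np.array([s.encode() for s in epochs.channel_labels]))
        f.create_dataset("srate", data=float(epochs.srate))
        f.create_dataset("subject_id", data=epochs.subject_id.encode())
        f.create_dataset("provenance", data=json.dumps(epochs.provenance, default=str).encode())
    if events_path is None:
        events_path = path + ".events.tsv"
    n_samples = epochs.times.size
    onset_in_epoch = int(np.argmin(np.abs(epochs.times)))
    with open(events_path, "w") as f:
        f.write("trial\tonset_sample\tlabel\n")
        for i, lab in enumerate(epochs.labels):
            f.write(f"{i}\t{i * n_samples + onset_in_epoch}\t{lab}\n")


def read_epochs(path) -> EpochsData:
    with h5py.File(path, "r") as f:
        if f.attrs.get("layout_version") != _LAYOUT_VERSION:
            raise ValueError(
                f"unsupported epochs container layout: {f.attrs.get('layout_version')!r}"
            )
        return EpochsData(
            data=f["data"][()],
            times=f["times_ms"][()],
            labels=np.array([s.decode() for s in f["labels"][()]]),
            srate=float(f["srate"][()]),
            channel_labels=[s.decode() for s in f["channels"][()]],
            subject_id=f["subject_id"][()].decode(),
            provenance=json.loads(f["provenance"][()].decode()),
        )


def epochs_to_continuous(epochs: EpochsData):
    """Concatenate epochs into a continuous recording (for testing the
    preprocessing chain on simulated data). Returns a ContinuousEEG."""
    from .preprocess import ContinuousEEG

    n_samples = epochs.times.size
    onset_in_epoch = int(np.argmin(np.abs(epochs.times)))
    data = np.concatenate(list(epochs.data), axis=-1)  # (n_channels, total)
    events = [(i * n_samples + onset_in_epoch, str(lab))
              for i, lab in enumerate(epochs.labels)]
    return ContinuousEEG(
        data=np.ascontiguousarray(data.astype(float)),
        srate=epochs.srate,
        channel_labels=list(epochs.channel_labels),
        events=events,
    )
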