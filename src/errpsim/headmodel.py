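"""Source-to-scalp forward models.

The default head model is an analytic three-shell concentric-sphere conductor
(brain / skull / scalp) with the classical 1 : 1/80 : 1 conductivity profile.
The scalp potential of a current dipole inside the innermost shell is obtained
from the spherical-harmonic series solution: per harmonic order the radial
boundary-value problem (continuity of potential and of radial current at the
two interfaces, zero current through the scalp surface) is solved exactly, and
the series is truncated at a configurable order.

Externally computed lead fields (e.g. exports of realistic BEM/FEM models) can
be plugged in through :func:`load_leadfield`; the HDF5 container layout is
documented there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "LeadField",
    "SourceSelection",
    "build_spherical_leadfield",
    "write_leadfield",
    "load_leadfield",
    "pick_source_near",
    "pick_spaced_sources",
    "orient_with_deviation",
    "best_orientation_for_channel",
    "montage_positions",
]

#: shell radii in mm (brain, skull, scalp) and conductivities (relative)
DEFAULT_RADII = (80.0, 85.0, 92.0)
DEFAULT_SIGMAS = (1.0, 1.0 / 80.0, 1.0)
DEFAULT_N_TERMS = 60
#: sources are kept inside this fraction of the brain-shell radius so the
#: truncated series stays well converged ((0.8)^60 ~ 1.5e-6 relative tail)
SOURCE_DEPTH_FRACTION = 0.92


class LeadFieldError(ValueError):
    """Raised when a lead field fails validation."""


@dataclass
class LeadField:
    """Linear map from dipolar source activity to scalp electrode potentials.

    Attributes
    ----------
    gains : ndarray, shape (n_channels, n_sources, 3)
        Scalp potential per unit dipole moment along x/y/z. Columns are
        rescaled so that each source's best-channel gain along its default
        orientation is 1, making source amplitudes in microvolt directly
        interpretable as best-channel scalp amplitude.
    source_positions : ndarray, shape (n_sources, 3)
        Head-centered source coordinates in mm.
    default_orientations : ndarray, shape (n_sources, 3)
        Unit dipole orientations (radial for the spherical model).
    channel_labels : list of str
    channel_positions : ndarray, shape (n_channels, 3), mm.
    """

    gains: np.ndarray
    source_positions: np.ndarray
    default_orientations: np.ndarray
    channel_labels: list[str]
    channel_positions: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.gains.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gains.shape[1]

    def validate(self) -> "LeadField":
        g = np.asarray(self.gains, float)
        if g.ndim != 3 or g.shape[2] != 3:
            raise LeadFieldError(f"gains must be (n_channels, n_sources, 3), got {g.shape}")
        if not np.all(np.isfinite(g)):
            raise LeadFieldError("non-finite gains")
        if self.n_channels < 8:
            raise LeadFieldError(f"need at least 8 channels, got {self.n_channels}")
        if self.n_sources < 100:
            raise LeadFieldError(f"need at least 100 sources, got {self.n_sources}")
        sp = np.asarray(self.source_positions, float)
        if sp.shape != (self.n_sources, 3):
            raise LeadFieldError(f"source_positions shape {sp.shape} mismatches gains")
        do = np.asarray(self.default_orientations, float)
        if do.shape != (self.n_sources, 3):
            raise LeadFieldError(f"default_orientations shape {do.shape} mismatches gains")
        norms = np.linalg.norm(do, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise LeadFieldError("default_orientations must have unit norm")
        if len(self.channel_labels) != self.n_channels:
            raise LeadFieldError("channel_labels length mismatches gains")
        cp = np.asarray(self.channel_positions, float)
        if cp.shape != (self.n_channels, 3):
            raise LeadFieldError(f"channel_positions shape {cp.shape} mismatches gains")
        return self

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise LeadFieldError(f"unknown channel label: {label!r}") from None

    def project(self, source_index: int, orientation: np.ndarray) -> np.ndarray:
        """Per-channel gain (length n_channels) of a dipole at one source."""
        return self.gains[:, source_index, :] @ np.asarray(orientation, float)


@dataclass
class SourceSelection:
    """One component's dipole: a source index plus an orientation."""

    component_name: str
    source_index: int
    orientation: np.ndarray
    center: np.ndarray
    radius: float

    def __post_init__(self):
        self.orientation = np.asarray(self.orientation, float)
        self.center = np.asarray(self.center, float)
        if not np.isclose(np.linalg.norm(self.orientation), 1.0, atol=1e-9):
            raise ValueError("orientation must be a unit vector")


# ---------------------------------------------------------------------------
# montage positions

def montage_positions(labels: list[str], scalp_radius: float = DEFAULT_RADII[2]) -> np.ndarray:
    """Resolve electrode labels to head-centered positions on the scalp sphere.

    Labels are looked up in mne's bundled biosemi64 and standard_1005 montages
    (biosemi64 takes precedence; its positions are ideally spherical) and
    projected radially onto the scalp radius of the spherical model.
    """
    import warnings

    from mne.channels import make_standard_montage

    lookup: dict[str, np.ndarray] = {}
    for name in ("standard_1005", "biosemi64"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            m = make_standard_montage(name)
        for ch, pos in m.get_positions()["ch_pos"].items():
            lookup[ch] = np.asarray(pos, float)
    out = np.empty((len(labels), 3))
    for i, lab in enumerate(labels):
        if lab not in lookup:
            raise LeadFieldError(f"unknown channel label: {lab!r}")
        p = lookup[lab]
        out[i] = p / np.linalg.norm(p) * scalp_radius
    return out


# ---------------------------------------------------------------------------
# three-shell analytic solution

def _legendre_pair(n_max: int, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P_n(x) and P_n^1(x) (no Condon-Shortley phase) for n = 0..n_max."""
    P = np.zeros((n_max + 1,) + x.shape)
    P1 = np.zeros_like(P)
    P[0] = 1.0
    if n_max >= 1:
        P[1] = x
        s = np.sqrt(np.clip(1.0 - x * x, 0.0, None))
        P1[1] = s
    for n in range(2, n_max + 1):
        P[n] = ((2 * n - 1) * x * P[n - 1] - (n - 1) * P[n - 2]) / n
        if n == 2:
            P1[2] = 3.0 * x * s
        else:
            P1[n] = ((2 * n - 1) * x * P1[n - 1] - n * P1[n - 2]) / (n - 1)
    return P, P1


def _shell_transfer(n_max: int, radii=DEFAULT_RADII, sigmas=DEFAULT_SIGMAS) -> np.ndarray:
    """Per-order scalp transfer coefficients c_n of the layered sphere.

    Radii are normalised by the scalp radius; the potential in layer j is
    a_j rho^n + b_j rho^-(n+1) plus, in the innermost layer, the primary
    dipole term with unit coefficient. c_n is the scalp-surface potential per
    unit primary coefficient; for equal conductivities c_n = (2n+1)/n.
    """
    R = radii[2]
    r1, r2 = radii[0] / R, radii[1] / R
    s1, s2, s3 = sigmas
    c = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        # unknowns: a1, a2, b2, a3, b3
        A = np.zeros((5, 5))
        rhs = np.zeros(5)
        # potential continuity at r1
        A[0] = [r1 ** n, -(r1 ** n), -(r1 ** -(n + 1)), 0, 0]
        rhs[0] = -(r1 ** -(n + 1))
        # radial current continuity at r1
        A[1] = [
            s1 * n * r1 ** (n - 1),
            -s2 * n * r1 ** (n - 1),
            s2 * (n + 1) * r1 ** -(n + 2),
            0,
            0,
        ]
        rhs[1] = s1 * (n + 1) * r1 ** -(n + 2)
        # potential continuity at r2
        A[2] = [0, r2 ** n, r2 ** -(n + 1), -(r2 ** n), -(r2 ** -(n + 1))]
        # radial current continuity at r2
        A[3] = [
            0,
            s2 * n * r2 ** (n - 1),
            -s2 * (n + 1) * r2 ** -(n + 2),
            -s3 * n * r2 ** (n - 1),
            s3 * (n + 1) * r2 ** -(n + 2),
        ]
        # insulating outer boundary (rho = 1)
        A[4] = [0, 0, 0, n, -(n + 1)]
        sol = np.linalg.solve(A, rhs)
        c[n] = sol[3] + sol[4]  # a3 + b3 at rho = 1
    return c


def _spherical_gains(
    channel_positions: np.ndarray,
    source_positions: np.ndarray,
    n_terms: int = DEFAULT_N_TERMS,
    radii=DEFAULT_RADII,
    sigmas=DEFAULT_SIGMAS,
) -> np.ndarray:
    """Gain tensor (n_channels, n_sources, 3) of the layered-sphere model."""
    R = radii[2]
    c = _shell_transfer(n_terms, radii, sigmas)
    E = channel_positions / np.linalg.norm(channel_positions, axis=1, keepdims=True)
    b = np.linalg.norm(source_positions, axis=1)
    b = np.maximum(b, 1e-9)
    Q = source_positions / b[:, None]  # radial unit vectors (S, 3)
    cosg = E @ Q.T  # (E, S)
    # in-plane unit vector from source axis toward each electrode
    u = E[:, None, :] - cosg[:, :, None] * Q[None, :, :]
    su = np.linalg.norm(u, axis=2, keepdims=True)
    u = np.where(su > 1e-12, u / np.where(su > 0, su, 1.0), 0.0)
    P, P1 = _legendre_pair(n_terms, cosg)
    G = np.zeros(cosg.shape + (3,))
    bR = b / R
    for n in range(1, n_terms + 1):
        k = c[n] * bR ** (n - 1) / (4.0 * np.pi * R * R * sigmas[0])  # (S,)
        G += k[None, :, None] * (
            n * P[n][:, :, None] * Q[None, :, :] + P1[n][:, :, None] * u
        )
    return G


def build_spherical_leadfield(
    montage: list[str],
    n_sources: int = 6000,
    seed: int = 0,
    n_terms: int = DEFAULT_N_TERMS,
    radii=DEFAULT_RADII,
    sigmas=DEFAULT_SIGMAS,
    normalize: bool = True,
) -> LeadField:
    """Build an analytic three-shell spherical lead field.

    Sources are sampled uniformly inside the brain shell (kept within
    ``SOURCE_DEPTH_FRACTION`` of its radius for series convergence); gains are
    the truncated-series solution of the layered sphere. Deterministic for a
    fixed seed. With ``normalize`` each source's gain column is rescaled so
    its best-channel gain along the default (radial) orientation is 1.
    """
    if n_sources < 100:
        raise LeadFieldError(f"n_sources must be >= 100, got {n_sources}")
    chan_pos = montage_positions(list(montage), scalp_radius=radii[2])
    rng = np.random.default_rng(seed)
    r_max = SOURCE_DEPTH_FRACTION * radii[0]
    d = rng.normal(size=(n_sources, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    r = r_max * rng.random(n_sources) ** (1.0 / 3.0)
    src_pos = d * r[:, None]
    G = _spherical_gains(chan_pos, src_pos, n_terms, radii, sigmas)
    orient = src_pos / np.linalg.norm(src_pos, axis=1, keepdims=True)
    if normalize:
        radial_gain = np.einsum("esk,sk->es", G, orient)
        scale = np.abs(radial_gain).max(axis=0)
        G = G / scale[None, :, None]
    return LeadField(
        gains=G,
        source_positions=src_pos,
        default_orientations=orient,
        channel_labels=list(montage),
        channel_positions=chan_pos,
    ).validate()


# ---------------------------------------------------------------------------
# container I/O (HDF5 layout: /gains, /source_pos_mm, /orientations,
# /channel_labels, /channel_pos_mm)

def write_leadfield(lf: LeadField, path) -> None:
    lf.validate()
    with h5py.File(path, "w") as f:
        f.create_dataset("gains", data=lf.gains)
        f.create_dataset("source_pos_mm", data=lf.source_positions)
        f.create_dataset("orientations", data=lf.default_orientations)
        f.create_dataset(
            "channel_labels",
            data=np.array([s.encode() for s in lf.channel_labels]),
        )
        f.create_dataset("channel_pos_mm", data=lf.channel_positions)


def load_leadfield(path) -> LeadField:
    """Read a lead field container; raises distinct errors for a missing
    field, a shape mismatch, and non-finite gains."""
    required = ["gains", "source_pos_mm", "orientations", "channel_labels", "channel_pos_mm"]
    with h5py.File(path, "r") as f:
        for key in required:
            if key not in f:
                raise LeadFieldError(f"missing field: /{key}")
        lf = LeadField(
            gains=f["gains"][()],
            source_positions=f["source_pos_mm"][()],
            default_orientations=f["orientations"][()],
            channel_labels=[s.decode() for s in f["channel_labels"][()]],
            channel_positions=f["channel_pos_mm"][()],
        )
    return lf.validate()


# ---------------------------------------------------------------------------
# source selection utilities

def pick_source_near(lf: LeadField, center, radius: float, rng) -> SourceSelection:
    """Uniform random choice among sources within ``radius`` mm of ``center``.

    ``radius`` 0 degenerates to the single nearest source. The returned
    selection carries the source's default orientation.
    """
    center = np.asarray(center, float)
    dist = np.linalg.norm(lf.source_positions - center, axis=1)
    if radius <= 0:
        idx = int(np.argmin(dist))
    else:
        candidates = np.flatnonzero(dist <= radius)
        if candidates.size == 0:
            raise LeadFieldError(
                f"no source within {radius} mm of {center.tolist()}; "
                f"nearest available at {dist.min():.1f} mm"
            )
        idx = int(rng.choice(candidates))
    return SourceSelection(
        component_name="",
        source_index=idx,
        orientation=lf.default_orientations[idx].copy(),
        center=center,
        radius=float(radius),
    )


def pick_spaced_sources(
    lf: LeadField, n: int, min_spacing: float, rng, max_retries: int = 50
) -> np.ndarray:
    """``n`` random source indices with all pairwise distances >= min_spacing.

    Randomised greedy selection with a bounded retry budget; raises with the
    best achieved count if the spacing is infeasible for the source cloud.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pos = lf.source_positions
    best = 0
    for _ in range(max_retries):
        order = rng.permutation(lf.n_sources)
        chosen: list[int] = []
        for idx in order:
            p = pos[idx]
            if all(np.linalg.norm(p - pos[j]) >= min_spacing for j in chosen):
                chosen.append(int(idx))
                if len(chosen) == n:
                    return np.array(chosen)
        best = max(best, len(chosen))
    raise LeadFieldError(
        f"could not place {n} sources at >= {min_spacing} mm spacing "
        f"(achieved {best} after {max_retries} retries)"
    )


def orient_with_deviation(orientation, dev_fraction: float, rng) -> np.ndarray:
    """Perturb each Cartesian component by an independent factor in
    [1 - dev, 1 + dev], then renormalise to unit length."""
    if not 0 <= dev_fraction < 1:
        raise ValueError("dev_fraction must be in [0, 1)")
    o = np.asarray(orientation, float)
    factors = 1.0 + dev_fraction * rng.uniform(-1.0, 1.0, size=3)
    out = o * factors
    norm = np.linalg.norm(out)
    if norm < 1e-12:
        raise ValueError("perturbed orientation has zero norm")
    return out / norm


def best_orientation_for_channel(lf: LeadField, source_index: int, channel: str) -> np.ndarray:
    """Unit orientation maximising the (signed-positive) gain at ``channel``.

    The gain at one electrode is linear in the dipole moment, so the best
    orientation is the electrode's gain 3-vector, normalised.
    """
    g = lf.gains[lf.channel_index(channel), source_index, :]
    norm = np.linalg.norm(g)
    if norm < 1e-15:
        raise LeadFieldError("source has vanishing gain at requested channel")
    return g / norm
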