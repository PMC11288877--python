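"""Metrics, significance testing, ERP-level analysis and QC diagnostics.

The error class is the positive class throughout: TPR is the fraction of
error trials correctly flagged, TNR the fraction of correct trials correctly
passed, and balanced accuracy their arithmetic mean — the natural chance
level is 0.5 regardless of the 20% error prevalence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulator import EpochsData

logger = logging.getLogger(__name__)

__all__ = [
    "ClassMetrics",
    "ErpSummary",
    "balanced_accuracy",
    "permutation_test",
    "compare_paired",
    "pointwise_fdr_mask",
    "grand_average",
    "find_peaks",
    "baseline_rms_distribution",
    "single_trial_spectra",
    "erp_image",
    "plot_grand_average",
    "plot_erp_image",
]

POSITIVE = "error"
NEGATIVE = "correct"


@dataclass(frozen=True)
class ClassMetrics:
    tpr: float
    tnr: float

    @property
    def bacc(self) -> float:
        return 0.5 * (self.tpr + self.tnr)

    def __iter__(self):
        yield from (self.tpr, self.tnr, self.bacc)


def balanced_accuracy(y_true, y_pred) -> ClassMetrics:
    """True positive / true negative rates and their mean; error = positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == POSITIVE
    neg = y_true == NEGATIVE
    if not pos.any() or not neg.any():
        raise ValueError("true labels must contain both classes")
    tpr = float(np.mean(y_pred[pos] == POSITIVE))
    tnr = float(np.mean(y_pred[neg] == NEGATIVE))
    return ClassMetrics(tpr=tpr, tnr=tnr)


def permutation_test(statistic: Callable[[np.ndarray], float], labels,
                     n_perm: int = 1000, rng=None) -> tuple[float, float, np.ndarray]:
    """Label-permutation test with the plus-one estimator.

    ``statistic(labels)`` must evaluate the full pipeline of interest
    (including any fold-internal downsampling/normalization) and return the
    performance figure. Returns (p, observed, permuted distribution) with
    p = (#{permuted >= observed} + 1) / (n_perm + 1), so the smallest
    attainable p is 1/(n_perm + 1).
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    labels = np.asarray(labels)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    observed = float(statistic(labels))
    null = np.array([float(statistic(rng.permutation(labels))) for _ in range(n_perm)])
    p = (np.count_nonzero(null >= observed) + 1) / (n_perm + 1)
    return float(p), observed, null


def compare_paired(a, b, alternative: str = "two-sided") -> float:
    """Wilcoxon signed-rank test on paired metric values.

    ``alternative``: "two-sided", "A-greater" or "A-less". Zero differences
    are dropped; the exact null distribution is used for n <= 25 pairs.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    if np.all(d == 0):
        raise ValueError("degenerate comparison: all paired differences are zero")
    alt = {"two-sided": "two-sided", "A-greater": "greater", "A-less": "less"}
    if alternative not in alt:
        raise ValueError(f"unknown alternative: {alternative!r}")
    n_nonzero = np.count_nonzero(d != 0)
    method = "exact" if n_nonzero <= 25 else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative=alt[alternative],
                         method=method)
    return float(res.pvalue)


def pointwise_fdr_mask(error_epochs: np.ndarray, correct_epochs: np.ndarray,
                       alpha: float = 0.05) -> np.ndarray:
    """Per-timepoint Welch two-sample t-test on single-trial amplitudes with
    Benjamini-Hochberg control over timepoints.

    Inputs are (n_trials, n_samples) single-channel arrays; returns a boolean
    significance mask over time.
    """
    error_epochs = np.atleast_2d(np.asarray(error_epochs, float))
    correct_epochs = np.atleast_2d(np.asarray(correct_epochs, float))
    if min(error_epochs.shape[0], correct_epochs.shape[0]) < 2:
        raise ValueError("need at least 2 trials per class")
    if alpha <= 0:
        return np.zeros(error_epochs.shape[1], dtype=bool)
    _, pvals = stats.ttest_ind(error_epochs, correct_epochs, axis=0, equal_var=False)
    reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject


@dataclass
class ErpSummary:
    """Class averages and difference wave at one channel."""

    times: np.ndarray  # ms
    error_avg: np.ndarray
    correct_avg: np.ndarray
    channel: str
    n_subjects: int
    peaks: pd.DataFrame | None = None
    fdr_mask: np.ndarray | None = None

    @property
    def difference(self) -> np.ndarray:
        """Difference wave: error minus correct, exactly."""
        return self.error_avg - self.correct_avg


def _baseline_correct(x: np.ndarray, times: np.ndarray,
                      baseline: tuple[float, float]) -> np.ndarray:
    mask = (times >= baseline[0]) & (times < baseline[1])
    return x - x[..., mask].mean(axis=-1, keepdims=True)


def grand_average(subjects: Sequence[EpochsData], channel: str,
                  baseline: tuple[float, float] | None = (-200.0, 0.0)) -> ErpSummary:
    """Per-subject class averages, then the unweighted mean across subjects.

    ``baseline`` is in ms; applied per subject-average before pooling.
    """
    times = subjects[0].times
    err_avgs, cor_avgs = [], []
    for s in subjects:
        if s.times.shape != times.shape or not np.allclose(s.times, times):
            raise ValueError("subjects have mismatched time axes")
        x = s.get_channel(channel)
        e = x[s.labels == POSITIVE].mean(axis=0)
        c = x[s.labels == NEGATIVE].mean(axis=0)
        if baseline is not None:
            e = _baseline_correct(e, times, baseline)
            c = _baseline_correct(c, times, baseline)
        err_avgs.append(e)
        cor_avgs.append(c)
    return ErpSummary(
        times=times.copy(),
        error_avg=np.mean(err_avgs, axis=0),
        correct_avg=np.mean(cor_avgs, axis=0),
        channel=channel,
        n_subjects=len(subjects),
    )


#: peak-search intervals of the standard ErrP analysis: (lo ms, hi ms, polarity)
DEFAULT_PEAK_INTERVALS: tuple[tuple[float, float, str], ...] = (
    (50.0, 250.0, "positive"),
    (200.0, 400.0, "positive"),
    (200.0, 400.0, "negative"),
    (400.0, 600.0, "negative"),
)


def find_peaks(erp: np.ndarray, times: np.ndarray,
               intervals=DEFAULT_PEAK_INTERVALS) -> pd.DataFrame:
    """Most prominent peak (maximal signed amplitude) per search interval.

    Positive polarity returns the maximum, negative the minimum; a monotone
    segment therefore yields the interval endpoint. Columns: interval_lo,
    interval_hi, polarity, latency_ms, amplitude.
    """
    erp = np.asarray(erp, float)
    times = np.asarray(times, float)
    rows = []
    for lo, hi, polarity in intervals:
        mask = (times >= lo) & (times <= hi)
        if not mask.any():
            raise ValueError(f"interval [{lo}, {hi}] ms outside the time axis")
        seg = erp[mask]
        tseg = times[mask]
        i = int(np.argmax(seg)) if polarity == "positive" else int(np.argmin(seg))
        rows.append({"interval_lo": lo, "interval_hi": hi, "polarity": polarity,
                     "latency_ms": float(tseg[i]), "amplitude": float(seg[i])})
    return pd.DataFrame(rows)


def baseline_rms_distribution(
    subjects: Sequence[EpochsData],
    n_perm: int = 10_000,
    n_trials_per_perm: int = 575,
    baseline_ms: float = 200.0,
    rng=None,
) -> dict:
    """Permuted distribution of grand-average baseline RMS values.

    Per permutation: draw ``n_trials_per_perm`` correct trials per subject
    (with replacement if fewer are available, logged), compute each trial's
    per-channel RMS over the ``baseline_ms`` window before the event, then
    average over electrodes, trials and subjects, in that order. Returns
    mean_rms, std_rms and the full distribution.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    per_subject_rms = []
    for s in subjects:
        mask = (s.times >= -baseline_ms) & (s.times < 0)
        if not mask.any():
            raise ValueError("no pre-onset samples in the epoch window")
        x = s.data[s.labels == NEGATIVE][:, :, mask]
        # (n_correct,) per-trial RMS already averaged over electrodes
        rms = np.sqrt((x ** 2).mean(axis=2)).mean(axis=1)
        if rms.size < n_trials_per_perm:
            logger.info(
                "subject %s has %d correct trials < %d; sampling with replacement",
                s.subject_id, rms.size, n_trials_per_perm,
            )
        per_subject_rms.append(rms)
    dist = np.empty(n_perm)
    for k in range(n_perm):
        vals = [
            rms[rng.choice(rms.size, size=n_trials_per_perm,
                           replace=rms.size < n_trials_per_perm)].mean()
            for rms in per_subject_rms
        ]
        dist[k] = float(np.mean(vals))
    return {"mean_rms": float(dist.mean()), "std_rms": float(dist.std()),
            "distribution": dist}


def single_trial_spectra(epochs: EpochsData, channel: str,
                         n_trials: int = 575, rng=None,
                         label: str | None = NEGATIVE) -> tuple[np.ndarray, np.ndarray]:
    """Average single-trial FFT amplitude spectrum at one channel.

    Samples ``n_trials`` epochs of the given label (correct by default; with
    replacement if fewer are available, logged). Returns (freqs Hz, mean
    amplitude spectrum of length n_samples // 2 + 1).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = epochs.get_channel(channel)
    if label is not None:
        x = x[epochs.labels == label]
    if x.shape[0] == 0:
        raise ValueError("no trials to compute spectra from")
    replace = x.shape[0] < n_trials
    if replace:
        logger.info("only %d trials available < %d; sampling with replacement",
                    x.shape[0], n_trials)
    idx = rng.choice(x.shape[0], size=n_trials, replace=replace)
    amp = np.abs(np.fft.rfft(x[idx], axis=1)) / x.shape[1]
    freqs = np.fft.rfftfreq(x.shape[1], d=1.0 / epochs.srate)
    return freqs, amp.mean(axis=0)


def plot_grand_average(summary: "ErpSummary", path) -> None:
    """Save class averages and the difference wave as an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(summary.times, summary.error_avg, label="error", color="crimson")
    ax.plot(summary.times, summary.correct_avg, label="correct", color="navy")
    ax.plot(summary.times, summary.difference, label="error - correct",
            color="black", linestyle="--")
    if summary.fdr_mask is not None:
        ax.fill_between(summary.times, *ax.get_ylim(), where=summary.fdr_mask,
                        color="gray", alpha=0.2, label="p < 0.05 (FDR)")
    ax.axvline(0.0, color="gray", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude (uV)")
    ax.set_title(f"grand average at {summary.channel} (n={summary.n_subjects})")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_erp_image(image: np.ndarray, times: np.ndarray, path,
                   mean_erp: np.ndarray | None = None) -> None:
    """Save a single-trial ERP image (first trial at the bottom)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_rows = 2 if mean_erp is not None else 1
    fig, axes = plt.subplots(n_rows, 1, figsize=(7, 5), sharex=True,
                             height_ratios=[3, 1] if n_rows == 2 else None)
    axes = np.atleast_1d(axes)
    vmax = np.abs(image).max() or 1.0
    axes[0].imshow(image, aspect="auto", origin="lower", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax,
                   extent=[times[0], times[-1], 0, image.shape[0]])
    axes[0].set_ylabel("trial")
    if mean_erp is not None:
        axes[1].plot(times, mean_erp, color="black")
        axes[1].axvline(0.0, color="gray", lw=0.5)
        axes[1].set_ylabel("mean (uV)")
    axes[-1].set_xlabel("time (ms)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def erp_image(error_epochs: np.ndarray, correct_average: np.ndarray,
              smooth: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Single-trial difference traces smoothed over consecutive trials.

    ``error_epochs`` is (n_error_trials, n_samples) at one channel in original
    trial order (first trial = bottom row); the correct-trial average is
    subtracted from every trial, then a moving average over ``smooth``
    consecutive trials is applied (window truncated at the trial-sequence
    edges). Returns (image, mean_erp) where mean_erp is the row average.
    """
    error_epochs = np.atleast_2d(np.asarray(error_epochs, float))
    if error_epochs.shape[0] < 1:
        raise ValueError("need at least 1 error trial")
    diff = error_epochs - np.asarray(correct_average, float)[None, :]
    if smooth <= 1:
        img = diff
    else:
        kernel = np.ones(smooth)
        counts = np.convolve(np.ones(diff.shape[0]), kernel, mode="same")
        img = np.apply_along_axis(
            lambda col: np.convolve(col, kernel, mode="same") / counts, 0, diff
        )
    return img, diff.mean(axis=0)
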