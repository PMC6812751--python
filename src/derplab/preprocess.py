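"""Recording-to-clean-epochs steps: re-referencing, artifact rejection,
zero-phase low-pass filtering, baseline correction, time conversion.

Pipeline order is fixed: re-reference -> reject -> average -> filter ->
baseline.  Filtering is applied to averaged traces, not single trials;
rejection uses strict inequality (|x| > threshold) on the re-referenced
signal over the full epoch window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
from scipy import signal as sps

from .synth import EpochSet

__all__ = [
    "PreprocConfig",
    "RejectionReport",
    "rereference",
    "reject_artifacts",
    "lowpass",
    "lowpass_sos",
    "baseline_correct",
    "ms_to_sample",
    "sample_to_ms",
]


@dataclass(frozen=True)
class PreprocConfig:
    reference: tuple[str, ...] = ("TP9", "TP10")
    reject_threshold_uv: float = 150.0
    lowpass_hz: float = 25.0
    baseline_ms: tuple[float, float] = (-60.0, 40.0)
    min_trials: int = 10
    filter_order: int = 4

    def __post_init__(self) -> None:
        if self.reject_threshold_uv <= 0:
            raise ValueError("rejection threshold must be > 0")
        if self.baseline_ms[0] >= self.baseline_ms[1]:
            raise ValueError("empty baseline window")


@dataclass
class RejectionReport:
    """Kept/removed bookkeeping for one EpochSet."""
    subject: str
    group: str
    experiment: str
    condition: str
    n_total: int
    n_kept: int

    @property
    def n_removed(self) -> int:
        return self.n_total - self.n_kept

    @property
    def all_removed(self) -> bool:
        return self.n_kept == 0


def rereference(epochs: EpochSet,
                refs: tuple[str, ...] = ("TP9", "TP10")) -> EpochSet:
    """Subtract the mean of the reference channels from every channel.

    The reference is computed per trial and per sample from the
    pre-subtraction signal.
    """
    missing = [r for r in refs if r not in epochs.channels]
    if missing:
        raise ValueError(f"reference channel(s) not in data: {missing}")
    idx = [epochs.channel_index(r) for r in refs]
    ref = epochs.data[:, idx, :].mean(axis=1, keepdims=True)
    return replace(epochs, data=epochs.data - ref)


def reject_artifacts(epochs: EpochSet, threshold_uv: float = 150.0,
                     ) -> tuple[EpochSet, RejectionReport]:
    """Drop every trial with |value| strictly above ``threshold_uv`` anywhere."""
    if threshold_uv <= 0:
        raise ValueError("threshold must be > 0")
    bad = np.abs(epochs.data) > threshold_uv
    keep = ~bad.any(axis=(1, 2))
    report = RejectionReport(
        subject=epochs.subject, group=epochs.group,
        experiment=epochs.experiment, condition=epochs.condition,
        n_total=epochs.n_trials, n_kept=int(keep.sum()))
    return replace(epochs, data=epochs.data[keep]), report


def lowpass_sos(cutoff_hz: float, rate_hz: float, order: int = 4) -> np.ndarray:
    """Butterworth low-pass sections used by :func:`lowpass` (one pass).

    The filter is applied forward-backward, so the effective magnitude
    response is the square of this design's and the phase is zero.
    """
    if cutoff_hz >= rate_hz / 2:
        raise ValueError("cutoff must be below Nyquist")
    return sps.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")


def lowpass(trace: np.ndarray, cutoff_hz: float, rate_hz: float,
            order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward Butterworth) low-pass along the last axis."""
    trace = np.asarray(trace, dtype=float)
    sos = lowpass_sos(cutoff_hz, rate_hz, order)
    padlen = 3 * (2 * order + 1)
    if trace.shape[-1] <= padlen:
        raise ValueError(
            f"trace too short for filter edge handling "
            f"({trace.shape[-1]} <= {padlen} samples)")
    return sps.sosfiltfilt(sos, trace, axis=-1)


def baseline_correct(trace: np.ndarray, times_ms: np.ndarray,
                     window_ms: tuple[float, float] = (-60.0, 40.0),
                     ) -> np.ndarray:
    """Subtract the per-channel mean over ``window_ms`` (inclusive bounds)."""
    times_ms = np.asarray(times_ms)
    lo, hi = window_ms
    if lo < times_ms[0] or hi > times_ms[-1]:
        raise ValueError(f"baseline window [{lo}, {hi}] ms outside epoch "
                         f"[{times_ms[0]}, {times_ms[-1]}] ms")
    mask = (times_ms >= lo) & (times_ms <= hi)
    trace = np.asarray(trace, dtype=float)
    return trace - trace[..., mask].mean(axis=-1, keepdims=True)


def ms_to_sample(t_ms: float, rate_hz: float, onset_index: int,
                 n_samples: int | None = None) -> int:
    """Nearest-sample index for a post-onset time in ms."""
    idx = onset_index + int(round(t_ms * rate_hz / 1000.0))
    if idx < 0 or (n_samples is not None and idx >= n_samples):
        raise ValueError(f"{t_ms} ms maps to sample {idx}, outside the epoch")
    return idx


def sample_to_ms(index: int, rate_hz: float, onset_index: int) -> float:
    return (index - onset_index) * 1000.0 / rate_hz
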