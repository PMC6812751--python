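"""Selective averaging to per-subject ERPs and reversal-minus-stability
difference traces (dERPs), plus grand means."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import (PreprocConfig, baseline_correct, lowpass)
from .synth import EpochSet

__all__ = ["ErpTrace", "DerpTrace", "average_erp", "compute_derp", "grand_mean"]


@dataclass
class ErpTrace:
    """Per-subject averaged ERP for one experiment x condition."""
    subject: str
    group: str
    experiment: str
    condition: str
    data: np.ndarray          # (channels, samples), uV
    n_trials: int
    sfreq: float
    times_ms: np.ndarray
    channels: tuple[str, ...]
    too_few_trials: bool = False

    def channel_index(self, label: str) -> int:
        return self.channels.index(label)


@dataclass
class DerpTrace:
    """Reversal-minus-stability difference trace for one subject x experiment."""
    subject: str
    group: str
    experiment: str
    data: np.ndarray          # (channels, samples), uV
    n_trials_reversal: int
    n_trials_stability: int
    sfreq: float
    times_ms: np.ndarray
    channels: tuple[str, ...]

    def channel_index(self, label: str) -> int:
        return self.channels.index(label)


def average_erp(epochs: EpochSet, preproc: PreprocConfig | None = None,
                ) -> ErpTrace:
    """Mean over trials, then zero-phase low-pass, then baseline correction.

    Flags (but keeps) the subject when the trial count falls below the
    configured minimum, mirroring exclusion for too few reversal trials.
    """
    preproc = preproc or PreprocConfig()
    if epochs.n_trials == 0:
        raise ValueError(
            f"no trials to average for {epochs.subject}/"
            f"{epochs.experiment}/{epochs.condition}")
    mean = epochs.data.mean(axis=0)
    filtered = lowpass(mean, preproc.lowpass_hz, epochs.sfreq,
                       preproc.filter_order)
    corrected = baseline_correct(filtered, epochs.times_ms,
                                 preproc.baseline_ms)
    return ErpTrace(subject=epochs.subject, group=epochs.group,
                    experiment=epochs.experiment, condition=epochs.condition,
                    data=corrected, n_trials=epochs.n_trials,
                    sfreq=epochs.sfreq, times_ms=epochs.times_ms,
                    channels=epochs.channels,
                    too_few_trials=epochs.n_trials < preproc.min_trials)


def compute_derp(reversal: ErpTrace, stability: ErpTrace) -> DerpTrace:
    """Element-wise reversal minus stability for one subject x experiment."""
    if reversal.subject != stability.subject:
        raise ValueError("subject mismatch between conditions")
    if reversal.experiment != stability.experiment:
        raise ValueError("experiment mismatch between conditions")
    if reversal.data.shape != stability.data.shape:
        raise ValueError("shape mismatch between condition ERPs")
    if reversal.condition != "reversal" or stability.condition != "stability":
        raise ValueError("arguments must be (reversal, stability) ERPs")
    return DerpTrace(subject=reversal.subject, group=reversal.group,
                     experiment=reversal.experiment,
                     data=reversal.data - stability.data,
                     n_trials_reversal=reversal.n_trials,
                     n_trials_stability=stability.n_trials,
                     sfreq=reversal.sfreq, times_ms=reversal.times_ms,
                     channels=reversal.channels)


def grand_mean(derps: list[DerpTrace], group: str | None = None,
               experiment: str | None = None) -> np.ndarray:
    """Unweighted mean over subjects, optionally restricted by selectors."""
    sel = [d for d in derps
           if (group is None or d.group == group)
           and (experiment is None or d.experiment == experiment)]
    if not sel:
        raise ValueError(f"no dERP traces match group={group!r}, "
                         f"experiment={experiment!r}")
    return np.mean([d.data for d in sel], axis=0)
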