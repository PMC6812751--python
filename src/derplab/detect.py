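"""Component-presence testing and ROI peak measurement.

Presence of a difference-trace component is established by running
one-sample t-tests against zero across subjects, sample by sample, and
requiring a minimum number of consecutive sub-alpha samples:

* confirmatory variant -- at least one ROI electrode carries a qualifying
  run (alpha = 0.01, 10 consecutive samples = 20 ms at 500 Hz);
* exploratory variant -- two *adjacent* electrodes carry qualifying runs
  that overlap in time by at least one sample.

Peaks are the largest strict interior local extremum of the ROI polarity;
if the window contains none, the whole-window mean is reported instead
(fallback, with no latency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .derp import DerpTrace
from .montage import Montage, RoiSpec

__all__ = [
    "Run",
    "PSeries",
    "PresenceResult",
    "PeakMeasure",
    "running_ttests",
    "find_runs",
    "presence_confirmatory",
    "presence_exploratory",
    "pick_peak",
    "measure_component",
]

DEFAULT_ALPHA = 0.01
DEFAULT_MIN_RUN_SAMPLES = 10


@dataclass(frozen=True)
class Run:
    """A maximal consecutive stretch of sub-alpha samples."""
    start_index: int   # indices into the tested window
    end_index: int     # inclusive
    start_ms: float
    end_ms: float

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index + 1

    def overlaps(self, other: "Run") -> bool:
        return (self.start_index <= other.end_index
                and other.start_index <= self.end_index)


@dataclass
class PSeries:
    """Sample-wise one-sample t-test results for one electrode x window."""
    electrode: str
    times_ms: np.ndarray
    t: np.ndarray
    p: np.ndarray
    degenerate: np.ndarray  # bool: zero across-subject variance at sample
    n_subjects: int


@dataclass
class PresenceResult:
    component: str
    group: str
    experiment: str
    variant: str                      # "confirmatory" | "exploratory"
    series: dict[str, PSeries]
    runs: dict[str, list[Run]]        # qualifying runs per electrode
    met: bool
    qualifying: list = field(default_factory=list)
    # confirmatory: electrode labels; exploratory: (a, b) adjacent pairs


@dataclass
class PeakMeasure:
    subject: str
    electrode: str
    component: str
    amplitude_uv: float
    latency_ms: float | None
    fallback: bool


def _cell(derps: list[DerpTrace]) -> tuple[str, str]:
    groups = {d.group for d in derps}
    experiments = {d.experiment for d in derps}
    if len(groups) != 1 or len(experiments) != 1:
        raise ValueError("dERP set spans more than one group x experiment "
                         f"cell: groups={groups}, experiments={experiments}")
    return groups.pop(), experiments.pop()


def _window_mask(times_ms: np.ndarray, window_ms: tuple[float, float],
                 ) -> np.ndarray:
    lo, hi = window_ms
    return (times_ms >= lo) & (times_ms <= hi)


def running_ttests(derps: list[DerpTrace], electrode: str,
                   window_ms: tuple[float, float],
                   tail: str = "two-sided") -> PSeries:
    """Sample-wise one-sample t-tests of subjects' dERP values against zero.

    Zero across-subject variance at a sample is flagged degenerate; its p
    is 0 when the mean is nonzero, 1 otherwise.
    """
    if len(derps) < 3:
        raise ValueError("need at least 3 subjects for running t-tests")
    _cell(derps)
    times = derps[0].times_ms
    mask = _window_mask(times, window_ms)
    if not mask.any():
        raise ValueError(f"window {window_ms} ms outside the epoch")
    ci = derps[0].channel_index(electrode)
    x = np.stack([d.data[ci, mask] for d in derps])   # (subjects, samples)
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[degenerate] = np.where(mean[degenerate] != 0, np.inf, 0.0)
    if tail == "two-sided":
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    elif tail == "greater":
        p = stats.t.sf(t, df=n - 1)
    elif tail == "less":
        p = stats.t.cdf(t, df=n - 1)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    p[degenerate] = np.where(mean[degenerate] != 0, 0.0, 1.0)
    return PSeries(electrode=electrode, times_ms=times[mask], t=t, p=p,
                   degenerate=degenerate, n_subjects=n)


def find_runs(p_series: np.ndarray, alpha: float,
              min_run_samples: int,
              times_ms: np.ndarray | None = None) -> list[Run]:
    """Maximal consecutive stretches with p < alpha of sufficient length."""
    if min_run_samples < 1:
        raise ValueError("min_run_samples must be >= 1")
    p = np.asarray(p_series)
    if times_ms is None:
        times_ms = np.arange(len(p), dtype=float)
    below = p < alpha
    runs: list[Run] = []
    # edges of the boolean mask delimit maximal stretches
    padded = np.concatenate(([False], below, [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1
    for s, e in zip(starts, ends):
        if e - s + 1 >= min_run_samples:
            runs.append(Run(start_index=int(s), end_index=int(e),
                            start_ms=float(times_ms[s]),
                            end_ms=float(times_ms[e])))
    return runs


def presence_confirmatory(derps: list[DerpTrace], roi: RoiSpec,
                          alpha: float = DEFAULT_ALPHA,
                          min_run_samples: int = DEFAULT_MIN_RUN_SAMPLES,
                          tail: str = "two-sided") -> PresenceResult:
    """Component present iff any ROI electrode carries a qualifying run."""
    group, experiment = _cell(derps)
    series: dict[str, PSeries] = {}
    runs: dict[str, list[Run]] = {}
    hits: list[str] = []
    for electrode in roi.electrodes:
        ps = running_ttests(derps, electrode, (roi.start_ms, roi.end_ms), tail)
        series[electrode] = ps
        rr = find_runs(ps.p, alpha, min_run_samples, ps.times_ms)
        runs[electrode] = rr
        if rr:
            hits.append(electrode)
    return PresenceResult(component=roi.name, group=group,
                          experiment=experiment, variant="confirmatory",
                          series=series, runs=runs, met=bool(hits),
                          qualifying=hits)


def presence_exploratory(derps: list[DerpTrace], montage: Montage,
                         window_ms: tuple[float, float],
                         electrodes: tuple[str, ...],
                         alpha: float = DEFAULT_ALPHA,
                         min_run_samples: int = DEFAULT_MIN_RUN_SAMPLES,
                         tail: str = "two-sided",
                         component: str = "scan") -> PresenceResult:
    """Deflection detected iff two adjacent electrodes carry time-overlapping
    qualifying runs."""
    unknown = [e for e in electrodes if e not in montage]
    if unknown:
        raise ValueError(f"electrodes not in montage: {unknown}")
    group, experiment = _cell(derps)
    series: dict[str, PSeries] = {}
    runs: dict[str, list[Run]] = {}
    for electrode in electrodes:
        ps = running_ttests(derps, electrode, window_ms, tail)
        series[electrode] = ps
        runs[electrode] = find_runs(ps.p, alpha, min_run_samples, ps.times_ms)
    pairs: list[tuple[str, str]] = []
    for i, a in enumerate(electrodes):
        for b in electrodes[i + 1:]:
            if frozenset((a, b)) not in montage.adjacency:
                continue
            if any(ra.overlaps(rb) for ra in runs[a] for rb in runs[b]):
                pairs.append((a, b))
    return PresenceResult(component=component, group=group,
                          experiment=experiment, variant="exploratory",
                          series=series, runs=runs, met=bool(pairs),
                          qualifying=pairs)


def pick_peak(trace: np.ndarray, times_ms: np.ndarray, roi: RoiSpec,
              subject: str = "", electrode: str = "") -> PeakMeasure:
    """Largest strict interior local extremum of the ROI polarity.

    Window endpoints are never peaks.  Among equal-magnitude extrema the
    earliest wins.  Without any interior extremum the whole-window mean is
    returned (fallback; latency undefined).
    """
    mask = _window_mask(np.asarray(times_ms), (roi.start_ms, roi.end_ms))
    if mask.sum() < 1:
        raise ValueError(f"trace does not cover ROI window "
                         f"[{roi.start_ms}, {roi.end_ms}] ms")
    w = np.asarray(trace, dtype=float)[mask]
    wt = np.asarray(times_ms)[mask]
    v = w * roi.sign  # search maxima in the polarity direction
    best_i: int | None = None
    for i in range(1, len(v) - 1):
        if v[i] > v[i - 1] and v[i] > v[i + 1]:
            if best_i is None or v[i] > v[best_i]:
                best_i = i
    if best_i is None:
        return PeakMeasure(subject=subject, electrode=electrode,
                           component=roi.name,
                           amplitude_uv=float(w.mean()),
                           latency_ms=None, fallback=True)
    return PeakMeasure(subject=subject, electrode=electrode,
                       component=roi.name, amplitude_uv=float(w[best_i]),
                       latency_ms=float(wt[best_i]), fallback=False)


def measure_component(derps: list[DerpTrace], roi: RoiSpec) -> pd.DataFrame:
    """Peak table: one row per subject x ROI electrode.

    Columns: subject, group, experiment, electrode, component,
    amplitude_uv, latency_ms (NaN on fallback), fallback.
    """
    rows = []
    for d in derps:
        for electrode in roi.electrodes:
            pm = pick_peak(d.data[d.channel_index(electrode)], d.times_ms,
                           roi, subject=d.subject, electrode=electrode)
            rows.append({
                "subject": d.subject, "group": d.group,
                "experiment": d.experiment, "electrode": electrode,
                "component": roi.name, "amplitude_uv": pm.amplitude_uv,
                "latency_ms": (np.nan if pm.latency_ms is None
                               else pm.latency_ms),
                "fallback": pm.fallback,
            })
    return pd.DataFrame(rows)
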