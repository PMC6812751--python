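"""Synthetic trial-level EEG with planted reversal-related components.

The generator emits stimulus-locked epochs for a two-group cohort
(meditators / non-meditators) in two experiments (passive / hold) and two
conditions (reversal / stability).  Components are Gaussian-in-time
deflections with fixed scalp topographies; components tagged
``reversal``-only survive the reversal-minus-stability subtraction while
``both``-condition components cancel exactly.  Noise is white plus
1/f-shaped, independent across channels, with optional large-amplitude
artifact excursions to exercise the rejection stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
import json

import numpy as np
import yaml

from .montage import Montage, standard_montage_32

__all__ = [
    "ComponentTemplate",
    "TrialCountSpec",
    "CohortSpec",
    "EpochSet",
    "generate_cohort",
    "iter_cohort",
    "inject_artifacts",
    "paper_fixture",
    "default_times",
]

GROUPS = ("meditator", "non_meditator")
EXPERIMENTS = ("passive", "hold")
CONDITIONS = ("reversal", "stability")

DEFAULT_SFREQ = 500.0
DEFAULT_TMIN_MS = -100.0
DEFAULT_TMAX_MS = 800.0


def default_times(sfreq: float = DEFAULT_SFREQ,
                  tmin_ms: float = DEFAULT_TMIN_MS,
                  tmax_ms: float = DEFAULT_TMAX_MS) -> np.ndarray:
    """Sample times in ms, 0 at stimulus onset, inclusive of both ends."""
    step = 1000.0 / sfreq
    n = int(round((tmax_ms - tmin_ms) / step)) + 1
    return tmin_ms + step * np.arange(n)


@dataclass(frozen=True)
class ComponentTemplate:
    """One planted deflection: Gaussian time course x fixed topography.

    ``width_ms`` is the Gaussian temporal width (SD).  ``conditions`` is
    either ``"reversal"`` (survives the difference trace) or ``"both"``
    (cancels in it).
    """

    name: str
    latency_ms: float
    width_ms: float
    amplitude_uv: float
    topography: dict[str, float]
    conditions: str = "reversal"

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError(f"{self.name}: width must be > 0")
        if not any(w != 0 for w in self.topography.values()):
            raise ValueError(f"{self.name}: all-zero topography")
        if self.conditions not in ("reversal", "both"):
            raise ValueError(f"{self.name}: conditions {self.conditions!r}")
        if not all(-1 <= w <= 1 for w in self.topography.values()):
            raise ValueError(f"{self.name}: topography weight outside [-1, 1]")

    def waveform(self, times_ms: np.ndarray) -> np.ndarray:
        z = (times_ms - self.latency_ms) / self.width_ms
        return self.amplitude_uv * np.exp(-0.5 * z * z)

    def peak_electrode(self) -> str:
        return max(self.topography, key=lambda e: abs(self.topography[e]))


@dataclass(frozen=True)
class TrialCountSpec:
    mean: float
    sd: float
    floor: int = 1

    def __post_init__(self) -> None:
        if self.floor < 1:
            raise ValueError("trial floor must be >= 1")
        if self.sd < 0:
            raise ValueError("trial-count SD must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to simulate a cohort deterministically."""

    n_meditators: int
    n_non_meditators: int
    trial_counts: dict[tuple[str, str], TrialCountSpec]
    components: dict[str, tuple[ComponentTemplate, ...]]
    white_sd_uv: float = 6.0
    pink_sd_uv: float = 4.0
    latency_jitter_sd_ms: float = 6.0
    amplitude_jitter_rel_sd: float = 0.15
    artifact_rate: float = 0.0
    artifact_magnitude_uv: float = 250.0
    channel_noise_scale: dict[str, float] = field(default_factory=dict)
    sfreq: float = DEFAULT_SFREQ
    tmin_ms: float = DEFAULT_TMIN_MS
    tmax_ms: float = DEFAULT_TMAX_MS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_meditators < 1 or self.n_non_meditators < 1:
            raise ValueError("group sizes must be >= 1")
        if self.white_sd_uv < 0 or self.pink_sd_uv < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact rate must be in [0, 1]")
        for key in self.components:
            if key not in GROUPS:
                raise ValueError(f"unknown group {key!r} in component sets")
        for g, e in self.trial_counts:
            if g not in GROUPS or e not in EXPERIMENTS:
                raise ValueError(f"bad trial-count key ({g!r}, {e!r})")

    def group_sizes(self) -> dict[str, int]:
        return {"meditator": self.n_meditators,
                "non_meditator": self.n_non_meditators}


@dataclass
class EpochSet:
    """One subject x experiment x condition block of stimulus-locked trials."""

    subject: str
    group: str
    experiment: str
    condition: str
    data: np.ndarray          # (trials, channels, samples), uV
    sfreq: float
    times_ms: np.ndarray
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (trials, channels, samples)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel-axis length does not match labels")
        if self.data.shape[2] != len(self.times_ms):
            raise ValueError("sample-axis length does not match time axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, label: str) -> int:
        return self.channels.index(label)

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy())


def _pink_shaper(n_samples: int) -> tuple[np.ndarray, float]:
    """Frequency-domain 1/f amplitude shaper and its output-std factor.

    Returns ``(H, norm)`` such that ``irfft(rfft(w) * H) / norm`` has unit
    variance in expectation when ``w`` is unit white noise.
    """
    h = np.zeros(n_samples // 2 + 1)
    h[1:] = 1.0 / np.sqrt(np.arange(1, len(h)))
    # var of irfft(rfft(w) * H) for unit white w:
    # each rfft bin k (0<k<N/2) carries E|W_k|^2 = N, weight 2/N^2 after irfft
    w = np.full(len(h), 2.0)
    w[0] = 1.0
    if n_samples % 2 == 0:
        w[-1] = 1.0
    norm = float(np.sqrt(np.sum(w * h**2) / n_samples))
    return h, norm


def pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
               sd: float) -> np.ndarray:
    """1/f-shaped noise along the last axis with the given standard deviation."""
    n = shape[-1]
    h, norm = _pink_shaper(n)
    white = rng.standard_normal(shape)
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * h, n=n, axis=-1)
    return shaped * (sd / norm)


def _noise(rng: np.random.Generator, shape: tuple[int, ...],
           white_sd: float, pink_sd: float,
           channel_scale: np.ndarray) -> np.ndarray:
    out = np.zeros(shape)
    if white_sd > 0:
        out += white_sd * rng.standard_normal(shape)
    if pink_sd > 0:
        out += pink_noise(rng, shape, pink_sd)
    return out * channel_scale[:, None]


def _subject_signal(templates: tuple[ComponentTemplate, ...],
                    condition: str,
                    montage: Montage,
                    times_ms: np.ndarray,
                    gains: dict[str, float],
                    shifts_ms: dict[str, float]) -> np.ndarray:
    """Noise-free (channels, samples) signal for one subject and condition."""
    sig = np.zeros((len(montage.labels), len(times_ms)))
    for tpl in templates:
        if tpl.conditions == "reversal" and condition != "reversal":
            continue
        shifted = replace(tpl, latency_ms=tpl.latency_ms + shifts_ms[tpl.name])
        wave = gains[tpl.name] * shifted.waveform(times_ms)
        for label, weight in tpl.topography.items():
            sig[montage.index(label)] += weight * wave
    return sig


def iter_cohort(spec: CohortSpec, montage: Montage | None = None):
    """Yield :class:`EpochSet` objects for every subject x experiment x condition.

    Deterministic: the same spec (including seed) yields bit-identical
    arrays in the same order.
    """
    montage = montage or standard_montage_32()
    rng = np.random.default_rng(spec.seed)
    times = default_times(spec.sfreq, spec.tmin_ms, spec.tmax_ms)
    chan_scale = np.array([spec.channel_noise_scale.get(c, 1.0)
                           for c in montage.labels])

    for group in GROUPS:
        templates = tuple(spec.components.get(group, ()))
        for i in range(spec.group_sizes()[group]):
            subject = f"{group[:3]}{i + 1:02d}"
            gains = {t.name: max(0.0, 1.0 + spec.amplitude_jitter_rel_sd
                                 * rng.standard_normal())
                     for t in templates}
            shifts = {t.name: spec.latency_jitter_sd_ms * rng.standard_normal()
                      for t in templates}
            for experiment in EXPERIMENTS:
                tc = spec.trial_counts.get(
                    (group, experiment), TrialCountSpec(60.0, 0.0, 10))
                for condition in CONDITIONS:
                    n_trials = max(tc.floor, int(round(
                        tc.mean + tc.sd * rng.standard_normal())))
                    signal = _subject_signal(templates, condition, montage,
                                             times, gains, shifts)
                    data = signal[None, :, :] + _noise(
                        rng, (n_trials, len(montage.labels), len(times)),
                        spec.white_sd_uv, spec.pink_sd_uv, chan_scale)
                    epochs = EpochSet(subject=subject, group=group,
                                      experiment=experiment,
                                      condition=condition, data=data,
                                      sfreq=spec.sfreq, times_ms=times,
                                      channels=montage.labels)
                    if spec.artifact_rate > 0:
                        epochs, _ = inject_artifacts(
                            epochs, spec.artifact_rate,
                            spec.artifact_magnitude_uv,
                            seed=int(rng.integers(2**31)))
                    yield epochs


def generate_cohort(spec: CohortSpec,
                    montage: Montage | None = None) -> list[EpochSet]:
    return list(iter_cohort(spec, montage))


def inject_artifacts(epochs: EpochSet, rate: float, magnitude_uv: float,
                     seed: int) -> tuple[EpochSet, int]:
    """Add a +-``magnitude_uv`` excursion to a Bernoulli(rate) subset of trials.

    Each hit trial gets the excursion at one random channel/sample.
    Returns the modified copy and the number of trials touched.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    if magnitude_uv <= 0:
        raise ValueError("magnitude must be > 0")
    rng = np.random.default_rng(seed)
    out = epochs.copy()
    hits = rng.random(out.n_trials) < rate
    n_ch, n_s = out.data.shape[1:]
    count = 0
    for t in np.flatnonzero(hits):
        ch = int(rng.integers(n_ch))
        s = int(rng.integers(n_s))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out.data[t, ch, s] += sign * magnitude_uv
        count += 1
    return out, count


# ---------------------------------------------------------------------------
# Shipped default cohort
# ---------------------------------------------------------------------------

def _fixture_templates() -> dict[str, tuple[ComponentTemplate, ...]]:
    rp = ComponentTemplate(
        name="RP", latency_ms=140.0, width_ms=25.0, amplitude_uv=2.0,
        topography={"O1": 0.9, "Oz": 1.0, "O2": 0.9, "POz": 0.8,
                    "P3": 0.55, "Pz": 0.6, "P4": 0.55, "P7": 0.3, "P8": 0.3})
    rn = ComponentTemplate(
        name="RN", latency_ms=260.0, width_ms=35.0, amplitude_uv=-2.5,
        topography={"O1": 0.9, "Oz": 1.0, "O2": 0.9, "POz": 0.9,
                    "P3": 0.8, "Pz": 0.85, "P4": 0.8, "P7": 0.4, "P8": 0.4,
                    "CP1": 0.3, "CP2": 0.3})
    pp_parietal = ComponentTemplate(
        name="PP_parietal", latency_ms=540.0, width_ms=70.0, amplitude_uv=4.0,
        topography={"Pz": 1.0, "Cz": 0.75, "CP1": 0.7, "CP2": 0.7,
                    "P3": 0.7, "P4": 0.7, "POz": 0.6, "C3": 0.4, "C4": 0.4,
                    "Oz": 0.25, "O1": 0.2, "O2": 0.2})
    pp_frontal = ComponentTemplate(
        name="PP_frontal", latency_ms=480.0, width_ms=70.0, amplitude_uv=3.0,
        topography={"Fpz": 1.0, "Fp1": 0.8, "Fp2": 0.8, "Fz": 0.7,
                    "F3": 0.5, "F4": 0.5, "FC1": 0.3, "FC2": 0.3})
    fn = ComponentTemplate(
        name="FN", latency_ms=160.0, width_ms=25.0, amplitude_uv=-2.5,
        topography={"Fz": 1.0, "F3": 0.8, "F4": 0.8, "Cz": 0.75,
                    "C3": 0.55, "C4": 0.55, "Fp1": 0.6, "Fp2": 0.6,
                    "Fpz": 0.7, "FC1": 0.6, "FC2": 0.6})
    shared = (rp, rn, pp_parietal, pp_frontal)
    return {"meditator": shared + (fn,), "non_meditator": shared}


def paper_fixture(seed: int = 2019) -> CohortSpec:
    """Default cohort: 12 meditators + 15 non-meditators, published trial
    counts, and the four-component chain (FN planted in meditators only).

    Noise magnitudes and jitters are assumptions (no single-trial noise
    levels are published); they are tuned so the pipeline recovers the
    planted parameters at these trial counts.  Mastoid reference channels
    get reduced noise so re-referencing injects little shared noise.
    """
    return CohortSpec(
        n_meditators=12,
        n_non_meditators=15,
        trial_counts={
            ("non_meditator", "passive"): TrialCountSpec(78.7, 26.2, 34),
            ("non_meditator", "hold"): TrialCountSpec(61.0, 28.4, 26),
            ("meditator", "passive"): TrialCountSpec(65.8, 34.6, 12),
            ("meditator", "hold"): TrialCountSpec(43.3, 25.4, 13),
        },
        components=_fixture_templates(),
        white_sd_uv=6.0,
        pink_sd_uv=4.0,
        latency_jitter_sd_ms=6.0,
        amplitude_jitter_rel_sd=0.15,
        artifact_rate=0.05,
        artifact_magnitude_uv=250.0,
        channel_noise_scale={"TP9": 0.3, "TP10": 0.3},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_epochset(epochs: EpochSet, directory: str | Path) -> Path:
    """Write data as .npy plus a JSON sidecar; returns the sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{epochs.subject}_{epochs.experiment}_{epochs.condition}"
    np.save(directory / f"{stem}.npy", epochs.data)
    meta = {
        "subject": epochs.subject, "group": epochs.group,
        "experiment": epochs.experiment, "condition": epochs.condition,
        "sfreq": epochs.sfreq, "times_ms": epochs.times_ms.tolist(),
        "channels": list(epochs.channels), "data_file": f"{stem}.npy",
    }
    sidecar = directory / f"{stem}.json"
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def load_epochset(sidecar: str | Path) -> EpochSet:
    sidecar = Path(sidecar)
    meta = json.loads(sidecar.read_text())
    data = np.load(sidecar.parent / meta["data_file"])
    return EpochSet(subject=meta["subject"], group=meta["group"],
                    experiment=meta["experiment"], condition=meta["condition"],
                    data=data, sfreq=meta["sfreq"],
                    times_ms=np.asarray(meta["times_ms"]),
                    channels=tuple(meta["channels"]))


def spec_to_yaml(spec: CohortSpec, path: str | Path) -> None:
    d = asdict(spec)
    d["trial_counts"] = {f"{g}/{e}": asdict(tc)
                         for (g, e), tc in spec.trial_counts.items()}
    d["components"] = {g: [asdict(t) for t in tpls]
                       for g, tpls in spec.components.items()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def spec_from_yaml(path: str | Path) -> CohortSpec:
    d = yaml.safe_load(Path(path).read_text())
    d["trial_counts"] = {tuple(k.split("/")): TrialCountSpec(**v)
                         for k, v in d["trial_counts"].items()}
    d["components"] = {g: tuple(ComponentTemplate(**t) for t in tpls)
                       for g, tpls in d["components"].items()}
    return CohortSpec(**d)
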