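"""Minimal BrainVision (.vhdr / .vmrk / binary data) reader and writer.

Supports the subset produced by the study hardware: binary multiplexed
data in IEEE_FLOAT_32 or INT_16 with per-channel resolution, stimulus and
response markers.  The writer exists chiefly for round-trip testing.
"""

from __future__ import annotations

import configparser
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synth import EpochSet

__all__ = ["Marker", "Recording", "read_brainvision", "write_brainvision",
           "epoch_recording", "BrainVisionError"]


class BrainVisionError(ValueError):
    """Malformed or inconsistent header/marker/data triplet."""


@dataclass(frozen=True)
class Marker:
    kind: str           # e.g. "Stimulus", "Response"
    description: str    # e.g. "S 10"
    position: int       # sample index into the continuous recording
    length: int = 1
    channel: int = 0


@dataclass
class Recording:
    """Continuous multichannel recording plus its marker stream."""
    data: np.ndarray            # (channels, samples), uV
    sfreq: float
    channels: tuple[str, ...]
    markers: tuple[Marker, ...] = field(default_factory=tuple)


def _read_ini(path: Path) -> configparser.ConfigParser:
    cp = configparser.ConfigParser(strict=False, interpolation=None)
    cp.optionxform = str
    text = path.read_text(encoding="utf-8", errors="replace")
    # strip the signature line ("Brain Vision Data Exchange ... File")
    lines = [ln for ln in text.splitlines() if not ln.startswith("Brain Vision")]
    cp.read_string("\n".join(lines))
    return cp


def read_brainvision(header_path: str | Path) -> Recording:
    """Parse a .vhdr header and its data/marker companions."""
    header_path = Path(header_path)
    if not header_path.exists():
        raise BrainVisionError(f"header file not found: {header_path}")
    cp = _read_ini(header_path)
    try:
        common = cp["Common Infos"]
        n_channels = int(common["NumberOfChannels"])
        sampling_interval_us = float(common["SamplingInterval"])
        data_file = header_path.parent / common["DataFile"]
        marker_file = header_path.parent / common["MarkerFile"]
    except KeyError as exc:
        raise BrainVisionError(f"header missing field {exc}") from exc
    if common.get("DataFormat", "BINARY").upper() != "BINARY":
        raise BrainVisionError("only BINARY DataFormat is supported")
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise BrainVisionError("only MULTIPLEXED orientation is supported")
    binfmt = cp["Binary Infos"]["BinaryFormat"].upper() \
        if cp.has_section("Binary Infos") else "IEEE_FLOAT_32"
    dtype = {"IEEE_FLOAT_32": np.float32, "INT_16": np.int16}.get(binfmt)
    if dtype is None:
        raise BrainVisionError(f"unsupported BinaryFormat {binfmt!r}")

    labels, resolutions = [], []
    if not cp.has_section("Channel Infos"):
        raise BrainVisionError("header missing [Channel Infos]")
    for i in range(1, n_channels + 1):
        try:
            entry = cp["Channel Infos"][f"Ch{i}"]
        except KeyError:
            raise BrainVisionError(f"header missing Ch{i}") from None
        parts = entry.split(",")
        labels.append(parts[0])
        res = parts[2] if len(parts) > 2 and parts[2] else "1"
        resolutions.append(float(res))

    if not data_file.exists():
        raise BrainVisionError(f"data file not found: {data_file}")
    raw = np.fromfile(data_file, dtype=dtype)
    if raw.size % n_channels != 0:
        raise BrainVisionError(
            f"data file truncated: {raw.size} values not divisible by "
            f"{n_channels} channels")
    data = raw.reshape(-1, n_channels).T.astype(float)
    data *= np.asarray(resolutions)[:, None]

    if not marker_file.exists():
        raise BrainVisionError(f"marker file not found: {marker_file}")
    markers = _read_markers(marker_file, n_samples=data.shape[1])

    return Recording(data=data, sfreq=1e6 / sampling_interval_us,
                     channels=tuple(labels), markers=markers)


def _read_markers(path: Path, n_samples: int) -> tuple[Marker, ...]:
    cp = _read_ini(path)
    if not cp.has_section("Marker Infos"):
        raise BrainVisionError("marker file missing [Marker Infos]")
    markers = []
    for key in sorted(cp["Marker Infos"],
                      key=lambda k: int(re.sub(r"\D", "", k) or 0)):
        parts = cp["Marker Infos"][key].split(",")
        if len(parts) < 4:
            raise BrainVisionError(f"malformed marker entry {key}")
        kind, desc, pos, length = parts[0], parts[1], int(parts[2]), \
            int(parts[3])
        # vmrk positions are 1-based
        position = pos - 1
        if position < 0 or position >= n_samples:
            raise BrainVisionError(
                f"marker {key} at sample {pos} outside the recording")
        channel = int(parts[4]) if len(parts) > 4 and parts[4] else 0
        markers.append(Marker(kind=kind, description=desc,
                              position=position, length=length,
                              channel=channel))
    return tuple(markers)


def write_brainvision(recording: Recording, header_path: str | Path) -> None:
    """Write a Recording as a .vhdr/.vmrk/.eeg triplet (IEEE_FLOAT_32)."""
    header_path = Path(header_path)
    stem = header_path.with_suffix("")
    data_name = stem.with_suffix(".eeg").name
    marker_name = stem.with_suffix(".vmrk").name
    n_channels = len(recording.channels)
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        f"DataFile={data_name}",
        f"MarkerFile={marker_name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_channels}",
        f"SamplingInterval={1e6 / recording.sfreq:g}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    lines += [f"Ch{i + 1}={lab},,1,µV"
              for i, lab in enumerate(recording.channels)]
    header_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    recording.data.T.astype(np.float32).tofile(stem.with_suffix(".eeg"))

    mlines = ["Brain Vision Data Exchange Marker File, Version 1.0",
              "[Common Infos]", f"DataFile={data_name}", "[Marker Infos]"]
    for i, mk in enumerate(recording.markers):
        mlines.append(f"Mk{i + 1}={mk.kind},{mk.description},"
                      f"{mk.position + 1},{mk.length},{mk.channel}")
    stem.with_suffix(".vmrk").write_text("\n".join(mlines) + "\n",
                                         encoding="utf-8")


def epoch_recording(recording: Recording,
                    condition_map: dict[str, str],
                    subject: str, group: str, experiment: str,
                    tmin_ms: float = -100.0,
                    tmax_ms: float = 800.0) -> list[EpochSet]:
    """Cut stimulus-locked epochs around markers whose description appears
    in ``condition_map`` (description -> condition label).

    Markers too close to the recording edges for a full epoch are skipped.
    Returns one EpochSet per condition present.
    """
    step = 1000.0 / recording.sfreq
    pre = int(round(-tmin_ms / step))
    post = int(round(tmax_ms / step))
    times = (np.arange(pre + post + 1) - pre) * step
    by_condition: dict[str, list[np.ndarray]] = {}
    for mk in recording.markers:
        cond = condition_map.get(mk.description)
        if cond is None:
            continue
        lo, hi = mk.position - pre, mk.position + post + 1
        if lo < 0 or hi > recording.data.shape[1]:
            continue
        by_condition.setdefault(cond, []).append(recording.data[:, lo:hi])
    out = []
    for cond, trials in by_condition.items():
        out.append(EpochSet(subject=subject, group=group,
                            experiment=experiment, condition=cond,
                            data=np.stack(trials), sfreq=recording.sfreq,
                            times_ms=times, channels=recording.channels))
    return out
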