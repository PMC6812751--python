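"""32-channel extended 10-20 montage, electrode adjacency, and spatio-temporal ROIs.

The montage, its neighbourhood graph, and the four built-in regions of
interest are shipped as plain-text tables under :mod:`derplab.data` and can
be overridden by passing alternative file paths to the loaders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "Montage",
    "RoiSpec",
    "standard_montage_32",
    "builtin_rois",
    "neighbors",
    "load_montage",
    "load_rois",
]


class UnknownElectrodeError(KeyError):
    """Raised when an electrode label is not part of the montage."""


@dataclass(frozen=True)
class Montage:
    """Electrode labels, 2D scalp positions, and the neighbourhood graph.

    Positions are unit-disc coordinates from a polar projection of the
    10-20 system (x: left-negative, y: anterior-positive).  They are used
    for plotting only; statistics rely on labels and adjacency alone.
    """

    labels: tuple[str, ...]
    positions: dict[str, tuple[float, float]]
    adjacency: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate electrode labels")
        for pair in self.adjacency:
            if len(pair) != 2:
                raise ValueError(f"adjacency pair {set(pair)} is not a 2-set")
            if not pair <= set(self.labels):
                raise ValueError(f"adjacency pair {set(pair)} off-montage")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise UnknownElectrodeError(label) from None

    def __contains__(self, label: str) -> bool:
        return label in self.labels


@dataclass(frozen=True)
class RoiSpec:
    """A named spatio-temporal region of interest.

    ``start_ms``/``end_ms`` are inclusive bounds relative to stimulus
    onset; ``polarity`` states the expected sign of the deflection.
    """

    name: str
    electrodes: tuple[str, ...]
    start_ms: float
    end_ms: float
    polarity: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if not 0 <= self.start_ms < self.end_ms:
            raise ValueError(f"ROI {self.name}: bad window "
                             f"[{self.start_ms}, {self.end_ms}]")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"ROI {self.name}: polarity {self.polarity!r}")

    @property
    def sign(self) -> int:
        return 1 if self.polarity == "positive" else -1


def _data_path(name: str) -> Path:
    return Path(str(resources.files("derplab.data").joinpath(name)))


def load_montage(montage_file: str | Path | None = None,
                 adjacency_file: str | Path | None = None) -> Montage:
    """Read a montage from tab-separated position and adjacency tables."""
    mf = Path(montage_file) if montage_file else _data_path("montage32.tsv")
    af = Path(adjacency_file) if adjacency_file else _data_path("adjacency32.tsv")
    pos = pd.read_csv(mf, sep="\t")
    adj = pd.read_csv(af, sep="\t")
    labels = tuple(pos["label"])
    positions = {r.label: (float(r.x), float(r.y)) for r in pos.itertuples()}
    pairs = set()
    for r in adj.itertuples():
        if r.a == r.b:
            raise ValueError(f"self-adjacency for {r.a}")
        pairs.add(frozenset((r.a, r.b)))
    return Montage(labels=labels, positions=positions,
                   adjacency=frozenset(pairs))


def standard_montage_32() -> Montage:
    """The shipped 32-electrode extended 10-20 montage (TP9/TP10 included)."""
    return load_montage()


def neighbors(montage: Montage, electrode: str) -> set[str]:
    """Adjacent electrodes of ``electrode`` per the montage graph."""
    if electrode not in montage:
        raise UnknownElectrodeError(electrode)
    out = set()
    for pair in montage.adjacency:
        if electrode in pair:
            out |= pair - {electrode}
    return out


def adjacent(montage: Montage, a: str, b: str) -> bool:
    for lab in (a, b):
        if lab not in montage:
            raise UnknownElectrodeError(lab)
    return frozenset((a, b)) in montage.adjacency


def load_rois(roi_file: str | Path | None = None) -> list[RoiSpec]:
    rf = Path(roi_file) if roi_file else _data_path("rois.tsv")
    df = pd.read_csv(rf, sep="\t")
    return [
        RoiSpec(
            name=r.name,
            electrodes=tuple(e.strip() for e in r.electrodes.split(",")),
            start_ms=float(r.start_ms),
            end_ms=float(r.end_ms),
            polarity=r.polarity,
        )
        for r in df.itertuples(index=False)
    ]


def builtin_rois() -> list[RoiSpec]:
    """The four shipped component ROIs (RP, RN, PP, FN)."""
    return load_rois()


def get_roi(name: str, rois: list[RoiSpec] | None = None) -> RoiSpec:
    for roi in rois if rois is not None else builtin_rois():
        if roi.name == name:
            return roi
    raise KeyError(name)
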