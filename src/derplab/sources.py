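"""Source-statistics stage on arbitrary 3D point clouds: per-vertex
one-sample t-tests, alpha thresholding, and repeated k-means with
explained-variance (elbow) model selection per hemisphere.

Hemispheres are split on the x coordinate (x <= 0 left, x > 0 right).
The elbow rule: smallest k whose explained-variance ratio
``1 - SSW(k)/SST`` reaches the cutoff; a hemisphere with (near-)zero
total variance is a single cluster; if no k reaches the cutoff, the k
with maximal explained variance (the cap) is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.cluster import KMeans

__all__ = [
    "VertexField",
    "ClusterResult",
    "vertex_ttest",
    "threshold_map",
    "cluster_sources",
]

_SST_TOL = 1e-9


@dataclass
class VertexField:
    """3D vertex coordinates plus per-subject contrast values per vertex."""
    coords: np.ndarray   # (n_vertices, 3), mm; x sign encodes hemisphere
    values: np.ndarray   # (n_subjects, n_vertices)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_vertices, 3)")
        if self.values.shape[1] != self.coords.shape[0]:
            raise ValueError("value columns must match vertex count")
        if self.values.shape[0] < 2:
            raise ValueError("need >= 2 subjects for vertex t-tests")


@dataclass
class ClusterResult:
    hemisphere: str            # "left" | "right"
    members: np.ndarray        # indices into the thresholded vertex array
    centroid: np.ndarray       # (3,), mm
    peak_t: float | None
    peak_p: float | None


def vertex_ttest(field: VertexField) -> tuple[np.ndarray, np.ndarray,
                                              np.ndarray]:
    """Two-tailed one-sample t vs zero per vertex: (t, p, degenerate)."""
    x = field.values
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[degenerate] = np.where(mean[degenerate] != 0, np.inf, 0.0)
    p = 2.0 * sstats.t.sf(np.abs(t), df=n - 1)
    p[degenerate] = np.where(mean[degenerate] != 0, 0.0, 1.0)
    return t, p, degenerate


def threshold_map(t: np.ndarray, p: np.ndarray, alpha: float) -> np.ndarray:
    """Indices of vertices with p < alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return np.flatnonzero(np.asarray(p) < alpha)


def _explained_curve(points: np.ndarray, max_k: int, reps: int,
                     seed: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Explained-variance ratio and labelings for k = 1..max_k."""
    n = points.shape[0]
    sst = float(((points - points.mean(axis=0)) ** 2).sum())
    ratios = np.empty(max_k)
    labelings = []
    for k in range(1, max_k + 1):
        if k == 1 or sst <= _SST_TOL:
            labels = np.zeros(n, dtype=int)
            ssw = sst
        elif k >= n:
            labels = np.arange(n)
            ssw = 0.0
        else:
            km = KMeans(n_clusters=k, n_init=reps, random_state=seed)
            labels = km.fit_predict(points)
            ssw = float(km.inertia_)
        ratios[k - 1] = 1.0 - ssw / sst if sst > _SST_TOL else 1.0
        labelings.append(labels)
    return ratios, labelings


def select_k(ratios: np.ndarray, cutoff: float) -> int:
    """Smallest k reaching the cutoff, else the argmax of the curve."""
    above = np.flatnonzero(ratios >= cutoff)
    if len(above):
        return int(above[0]) + 1
    return int(np.argmax(ratios)) + 1


def cluster_sources(coords: np.ndarray, reps: int = 1000,
                    elbow_cutoff: float = 0.95,
                    max_k_per_hemisphere: int = 8,
                    seed: int = 0,
                    t: np.ndarray | None = None,
                    p: np.ndarray | None = None) -> list[ClusterResult]:
    """Group suprathreshold vertices per hemisphere by repeated k-means.

    ``reps`` is the number of random restarts per k.  ``t``/``p`` (aligned
    with ``coords``) are optional; when given, each cluster reports the
    t and p of its largest-|t| member.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("empty suprathreshold vertex set")
    results: list[ClusterResult] = []
    for hemi, mask in (("left", coords[:, 0] <= 0),
                       ("right", coords[:, 0] > 0)):
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        pts = coords[idx]
        max_k = min(max_k_per_hemisphere, len(idx))
        ratios, labelings = _explained_curve(pts, max_k, reps, seed)
        k = select_k(ratios, elbow_cutoff)
        labels = labelings[k - 1]
        for c in range(k):
            members = idx[labels == c]
            if len(members) == 0:
                continue
            peak_t = peak_p = None
            if t is not None:
                tm = np.asarray(t)[members]
                j = members[int(np.argmax(np.abs(tm)))]
                peak_t = float(np.asarray(t)[j])
                peak_p = float(np.asarray(p)[j]) if p is not None else None
            results.append(ClusterResult(
                hemisphere=hemi, members=members,
                centroid=coords[members].mean(axis=0),
                peak_t=peak_t, peak_p=peak_p))
    return results


def cluster_table(clusters: list[ClusterResult]) -> pd.DataFrame:
    """Tabular summary: position (x y z), hemisphere, size, peak T and p."""
    rows = []
    for cl in clusters:
        rows.append({
            "hemisphere": cl.hemisphere,
            "x_mm": cl.centroid[0], "y_mm": cl.centroid[1],
            "z_mm": cl.centroid[2], "n_vertices": len(cl.members),
            "peak_T": cl.peak_t, "peak_p": cl.peak_p,
        })
    return pd.DataFrame(rows)


def read_vertex_field(path) -> VertexField:
    """Read a delimiter-separated table with columns x, y, z, then one
    column per subject."""
    df = pd.read_csv(path, sep="\t")
    coords = df[["x", "y", "z"]].to_numpy()
    values = df.drop(columns=["x", "y", "z"]).to_numpy().T
    return VertexField(coords=coords, values=values)


def write_vertex_field(field: VertexField, path) -> None:
    df = pd.DataFrame(field.coords, columns=["x", "y", "z"])
    for i, row in enumerate(field.values):
        df[f"subj{i + 1:02d}"] = row
    df.to_csv(path, sep="\t", index=False)
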