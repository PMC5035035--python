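"""Density-peak clustering on a 2-D map completed by an SVM.

A 2-D Gaussian kernel density is estimated on the t-SNE map, local
maxima of the density grid seed the clusters, and each peak claims the
cells inside a circle of half the distance to its nearest neighboring
peak. Cells left outside every circle are then classified by a
multi-class RBF support-vector machine trained on the marker-expression
profiles of the circle-assigned cells, so that every cell ends up with
a label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.spatial.distance import cdist
from scipy.stats import norm
from sklearn.svm import SVC

from .clusterx import ClusterResult
from .dimred import Embedding

__all__ = ["PeakSet", "kde2d", "find_peaks_2d", "circle_assign", "svm_complete", "densvm"]


@dataclass
class PeakSet:
    peak_coords: np.ndarray  # (K, 2)
    d_k: np.ndarray          # per-peak distance to its nearest neighboring peak
    radius: np.ndarray       # d_k / 2

    @property
    def n_peaks(self) -> int:
        return self.peak_coords.shape[0]


def _nrd_bandwidth(v: np.ndarray) -> float:
    # normal-reference rule per axis
    sd = float(np.std(v, ddof=1))
    iqr = float(np.subtract(*np.percentile(v, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread == 0:
        raise ValueError("degenerate axis: zero variance")
    return 1.06 * spread * v.size ** (-0.2)


def kde2d(
    coords: np.ndarray,
    grid: int = 256,
    bandwidth: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Product-Gaussian KDE of a 2-D embedding on a grid x grid lattice.

    The lattice spans the data range padded by 3 bandwidths per axis;
    bandwidths default to the normal-reference rule. Returns
    (density, x_grid, y_grid) with density integrating to ~1.
    """
    xy = np.asarray(coords, dtype=np.float64)
    n = xy.shape[0]
    if n < 10:
        raise ValueError("need at least 10 cells for a density estimate")
    if grid < 32:
        raise ValueError("grid must be >= 32")
    if bandwidth is None:
        bandwidth = (_nrd_bandwidth(xy[:, 0]), _nrd_bandwidth(xy[:, 1]))
    hx, hy = bandwidth
    if hx <= 0 or hy <= 0:
        raise ValueError("bandwidths must be positive")
    gx = np.linspace(xy[:, 0].min() - 3 * hx, xy[:, 0].max() + 3 * hx, grid)
    gy = np.linspace(xy[:, 1].min() - 3 * hy, xy[:, 1].max() + 3 * hy, grid)
    kern_x = norm.pdf((gx[:, None] - xy[None, :, 0]) / hx) / hx  # (grid, n)
    kern_y = norm.pdf((gy[:, None] - xy[None, :, 1]) / hy) / hy
    density = kern_x @ kern_y.T / n  # (grid_x, grid_y)
    return density, gx, gy


def find_peaks_2d(
    density: np.ndarray,
    gx: np.ndarray,
    gy: np.ndarray,
    floor_frac: float = 0.01,
) -> PeakSet:
    """Local maxima of the density grid (strict 8-neighborhood).

    Maxima below ``floor_frac`` of the global maximum are ignored. With
    a single surviving peak, its claiming radius falls back to half the
    grid-range diagonal so the one circle covers all cells.
    """
    if density.size == 0 or float(density.max()) <= 0:
        raise ValueError("flat or empty density grid: no peaks")
    neighborhood = maximum_filter(density, size=3, mode="constant", cval=-np.inf)
    is_peak = (density == neighborhood) & (density >= floor_frac * density.max())
    # strictness: demote plateau cells that equal a neighbor
    ix, iy = np.nonzero(is_peak)
    keep = []
    padded = np.pad(density, 1, constant_values=-np.inf)
    for a, b in zip(ix, iy):
        window = padded[a : a + 3, b : b + 3]
        if np.sum(window == density[a, b]) == 1:
            keep.append((a, b))
    if not keep:
        raise ValueError("no strict local maxima found in the density grid")
    coords = np.array([[gx[a], gy[b]] for a, b in keep])
    if len(keep) == 1:
        diag = float(np.hypot(gx[-1] - gx[0], gy[-1] - gy[0]))
        d_k = np.array([diag])
    else:
        dmat = cdist(coords, coords)
        np.fill_diagonal(dmat, np.inf)
        d_k = dmat.min(axis=1)
    return PeakSet(peak_coords=coords, d_k=d_k, radius=d_k / 2.0)


def circle_assign(coords: np.ndarray, peaks: PeakSet) -> np.ndarray:
    """Provisional labels: cells inside a peak's circle take that peak.

    A cell inside several circles goes to the nearest peak; a cell
    outside every circle stays 0 (unassigned).
    """
    xy = np.asarray(coords, dtype=np.float64)
    dists = cdist(xy, peaks.peak_coords)
    inside = dists <= peaks.radius[None, :]
    masked = np.where(inside, dists, np.inf)
    nearest = masked.argmin(axis=1)
    labels = np.where(inside.any(axis=1), nearest + 1, 0)
    return labels.astype(np.int64)


def svm_complete(
    markers: np.ndarray,
    partial: np.ndarray,
    C: float = 10.0,
) -> ClusterResult:
    """Assign the leftover cells with an SVM trained on marker profiles.

    The classifier (RBF kernel, one-vs-one) learns the marker-expression
    patterns of circle-assigned cells and predicts labels for the rest;
    circle assignments themselves are never changed. Classes with fewer
    than two training cells are merged into the class whose training
    centroid is nearest in marker space.
    """
    x = np.asarray(getattr(markers, "values", markers), dtype=np.float64)
    partial = np.asarray(partial, dtype=np.int64).copy()
    if partial.shape[0] != x.shape[0]:
        raise ValueError("labels and marker matrix disagree on cell count")

    labels_present, counts = np.unique(partial[partial > 0], return_counts=True)
    if labels_present.size == 0:
        raise ValueError("no assigned cells to train on")
    small = labels_present[counts < 2]
    big = labels_present[counts >= 2]
    if small.size and big.size:
        centroids = {int(l): x[partial == l].mean(axis=0) for l in big}
        for l in small:
            member = x[partial == l]
            dists = {b: np.linalg.norm(member.mean(axis=0) - c) for b, c in centroids.items()}
            target = min(dists, key=dists.get)
            warnings.warn(f"cluster {int(l)} has <2 training cells; merged into {target}")
            partial[partial == l] = target
        labels_present = np.unique(partial[partial > 0])

    unassigned = partial == 0
    if labels_present.size < 2:
        # single class: nothing to learn, everything joins it
        full = partial.copy()
        full[unassigned] = labels_present[0]
        return ClusterResult(labels=full, method="DensVM")

    if not unassigned.any():
        return ClusterResult(labels=partial.copy(), method="DensVM")

    clf = SVC(kernel="rbf", C=C, gamma="scale", decision_function_shape="ovo")
    clf.fit(x[~unassigned], partial[~unassigned])
    full = partial.copy()
    full[unassigned] = clf.predict(x[unassigned])
    return ClusterResult(labels=full, method="DensVM")


def densvm(
    markers,
    embedding: Embedding | np.ndarray,
    grid: int = 256,
    bandwidth: tuple[float, float] | None = None,
) -> ClusterResult:
    """Full pipeline: 2-D KDE -> peak circles -> SVM completion."""
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding, float)
    density, gx, gy = kde2d(coords, grid=grid, bandwidth=bandwidth)
    peaks = find_peaks_2d(density, gx, gy)
    partial = circle_assign(coords, peaks)
    if not (partial > 0).any():
        raise RuntimeError("no cell fell inside any peak circle")
    result = svm_complete(markers, partial)
    result.params = {"grid": grid, "n_peaks": peaks.n_peaks}
    result.centers = list(range(peaks.n_peaks))
    return result
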