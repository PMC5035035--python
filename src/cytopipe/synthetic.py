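"""Synthetic inputs with ground truth for testing and benchmarking.

Three generators: Gaussian mixtures in (asinh-scale) marker space with a
controllable separation, a 600-point 2-D layout of 15 well-separated
Gaussian groups arranged like the classic R15 clustering benchmark
(center point plus two concentric rings), and left-censored linear data
for exercising the Tobit fit. Everything is seeded and returns the true
labels; none of it emulates real CyTOF noise physics (spillover,
doublets).
"""

from __future__ import annotations

import numpy as np

from .fcs import write_fcs

__all__ = ["marker_mixture", "r15_like", "censored_linear", "mixture_to_fcs"]


def marker_mixture(
    n_clusters: int,
    n_per: int,
    n_markers: int,
    separation: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian mixture in marker space with unit within-cluster sd.

    Cluster means are drawn uniformly and rescaled so the minimum
    inter-mean distance equals ``separation`` (in within-cluster sd
    units), then shifted into the nonnegative range typical of
    asinh-transformed intensities. ``separation`` 0 collapses all
    clusters onto one point.
    """
    if min(n_clusters, n_per, n_markers) < 1 or separation < 0:
        raise ValueError("all sizes must be >= 1 and separation >= 0")
    rng = np.random.default_rng(seed)
    means = rng.uniform(0.0, 1.0, size=(n_clusters, n_markers))
    if n_clusters > 1:
        diffs = means[:, None, :] - means[None, :, :]
        dists = np.sqrt((diffs**2).sum(-1))
        np.fill_diagonal(dists, np.inf)
        dmin = dists.min()
        means = means * (separation / dmin) if dmin > 0 else means
    else:
        means = means * separation
    data = np.vstack(
        [rng.normal(means[c], 1.0, size=(n_per, n_markers)) for c in range(n_clusters)]
    )
    data -= data.min()  # nonnegative, asinh-like scale
    labels = np.repeat(np.arange(1, n_clusters + 1), n_per)
    return data, labels


def r15_like(seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """600 points in 15 isotropic Gaussian groups, 40 points each.

    Geometry mimics the classic R15 benchmark: one central group, an
    inner ring of six and an outer ring of eight. The component sd
    (0.4) keeps the minimal center spacing at >= 8 sd, so the groups
    are visually crisp and the density landscape has 15 clear peaks.
    """
    rng = np.random.default_rng(seed)
    centers = [(0.0, 0.0)]
    for i in range(6):
        ang = 2 * np.pi * i / 6
        centers.append((3.5 * np.cos(ang), 3.5 * np.sin(ang)))
    for i in range(8):
        ang = 2 * np.pi * i / 8 + np.pi / 8
        centers.append((7.0 * np.cos(ang), 7.0 * np.sin(ang)))
    centers = np.asarray(centers)
    sd = 0.4
    data = np.vstack([rng.normal(c, sd, size=(40, 2)) for c in centers])
    labels = np.repeat(np.arange(1, 16), 40)
    return data, labels


def censored_linear(
    n: int,
    beta0: float,
    beta1: float,
    sigma: float,
    left: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Left-censored linear data: x ~ U(0, 10), y = max(y*, left).

    Returns (x, observed y, latent y*). ``left = -inf`` produces fully
    uncensored data.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 10.0, size=n)
    y_star = beta0 + beta1 * x + rng.normal(0.0, sigma, size=n)
    y = np.maximum(y_star, left)
    return x, y, y_star


def mixture_to_fcs(
    path,
    data: np.ndarray,
    marker_names: list[str],
    cofactor: float = 5.0,
) -> str:
    """Emit mixture data as a raw-intensity FCS file.

    The asinh-scale values are pushed back through the inverse of the
    cofactor arcsinh transform (x = sinh(y) * cofactor + 1), so reading
    the file and applying the standard transform recovers the input.
    """
    raw = np.sinh(np.asarray(data, dtype=np.float64)) * cofactor + 1.0
    return write_fcs(path, raw, short_names=list(marker_names))
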