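"""Low-dimensional embeddings of the expression matrix.

Four reductions are exposed behind one entry point: PCA (linear),
Barnes-Hut t-SNE (local structure, the default substrate for the
density-based clusterers), ISOMAP (geodesic global structure) and a
diffusion map (continuum structure, used for inter-subset relatedness).
PCA/t-SNE/ISOMAP are delegated to scikit-learn; the diffusion map is
implemented here with anisotropic (alpha = 1) density normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE, Isomap
from sklearn.neighbors import kneighbors_graph

__all__ = ["Embedding", "reduce", "diffusion_map", "METHODS"]

METHODS = ("pca", "tsne", "isomap", "diffusionmap")


@dataclass
class Embedding:
    coords: np.ndarray
    method: str
    d: int = 2
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")
        if self.coords.shape[1] != self.d:
            raise ValueError("coords column count disagrees with d")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    def to_frame(self, cell_ids: list | None = None) -> pd.DataFrame:
        cols = [f"{self.method}_{i + 1}" for i in range(self.d)]
        frame = pd.DataFrame(self.coords, columns=cols)
        if cell_ids is not None:
            frame.insert(0, "cell_id", [getattr(c, "id", c) for c in cell_ids])
        return frame


def _as_matrix(data) -> np.ndarray:
    values = getattr(data, "values", data)
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected a 2-D cells x markers matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    return x


def reduce(data, method: str, d: int = 2, params: dict | None = None, seed: int = 0) -> Embedding:
    """Embed cells into ``d`` dimensions with the chosen method.

    t-SNE runs the Barnes-Hut approximation (theta 0.5, 1000 iterations,
    perplexity 30 by default) after an optional PCA compression to 50
    components when more than 50 markers are present. ISOMAP grows its
    neighborhood size from k = 5 until the neighbor graph is connected.
    """
    params = dict(params or {})
    x = _as_matrix(data)
    n = x.shape[0]
    if n < d + 1:
        raise ValueError(f"need at least d+1={d + 1} cells, got {n}")

    if method == "pca":
        model = PCA(n_components=d, svd_solver="full")
        coords = model.fit_transform(x)
        params["explained_variance_ratio"] = model.explained_variance_ratio_.tolist()
    elif method == "tsne":
        perplexity = float(params.setdefault("perplexity", 30.0))
        if perplexity >= (n - 1) / 3:
            raise ValueError(
                f"perplexity {perplexity} too large for {n} cells (must be < (n-1)/3)"
            )
        work = x
        if x.shape[1] > 50:
            work = PCA(n_components=50, svd_solver="full").fit_transform(x)
        model = TSNE(
            n_components=d,
            perplexity=perplexity,
            angle=float(params.setdefault("theta", 0.5)),
            max_iter=int(params.setdefault("max_iter", 1000)),
            init="pca",
            method="barnes_hut" if d <= 3 else "exact",
            random_state=seed,
        )
        coords = model.fit_transform(work).astype(np.float64)
    elif method == "isomap":
        k = int(params.get("k", 5))
        k = min(max(k, 1), n - 1)
        while True:
            graph = kneighbors_graph(x, n_neighbors=k, mode="connectivity")
            n_comp, _ = connected_components(graph, directed=False)
            if n_comp == 1:
                break
            if k >= n - 1:
                raise ValueError(
                    "ISOMAP neighbor graph disconnected even at k = n - 1"
                )
            k = min(2 * k, n - 1)
        params["k"] = k
        coords = Isomap(n_neighbors=k, n_components=d).fit_transform(x)
    elif method == "diffusionmap":
        return diffusion_map(x, d=d, sigma=params.get("sigma"), seed=seed)
    else:
        raise ValueError(f"unknown reduction method {method!r}; choose from {METHODS}")

    return Embedding(coords=coords, method=method, d=d, params=params, seed=seed)


def diffusion_map(data, d: int = 2, sigma: float | None = None, seed: int = 0) -> Embedding:
    """Diffusion-map embedding with anisotropic density normalization.

    A Gaussian kernel k(x, y) = exp(-||x-y||^2 / (2 sigma^2)) (sigma
    defaulting to the median pairwise distance) is normalized by the
    product of its row sums (alpha = 1), which removes the influence of
    sampling density, then row-normalized to a Markov matrix. The
    embedding uses eigenvectors 2..d+1 scaled by their eigenvalues; the
    trivial constant eigenvector (eigenvalue 1) is dropped.
    """
    x = _as_matrix(data)
    n = x.shape[0]
    if n < d + 2:
        raise ValueError(f"need at least d+2={d + 2} cells, got {n}")
    dists = squareform(pdist(x))
    if sigma is None:
        offdiag = squareform(dists)
        sigma = float(np.median(offdiag)) if offdiag.size else 1.0
        if sigma == 0:
            sigma = 1.0
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    kernel = np.exp(-(dists**2) / (2.0 * sigma**2))

    q = kernel.sum(axis=1)
    kernel_a = kernel / np.outer(q, q)  # alpha = 1 normalization
    deg = kernel_a.sum(axis=1)
    # symmetric conjugate of the Markov matrix for a stable eigendecomposition
    sym = kernel_a / np.sqrt(np.outer(deg, deg))
    eigvals, eigvecs = np.linalg.eigh(sym)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    phi = eigvecs[:, order] / np.sqrt(deg)[:, None]
    # deterministic sign: largest-magnitude entry positive
    for j in range(phi.shape[1]):
        pivot = np.argmax(np.abs(phi[:, j]))
        if phi[pivot, j] < 0:
            phi[:, j] = -phi[:, j]
    coords = phi[:, 1 : d + 1] * eigvals[1 : d + 1]
    return Embedding(
        coords=coords,
        method="diffusionmap",
        d=d,
        params={"sigma": sigma, "eigenvalues": eigvals[: d + 1].tolist()},
        seed=seed,
    )
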