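"""Inter-subset relatedness and marker-trend inference.

After clustering, subsets are down-sampled to an equal size (removing
the dominance of large populations), re-embedded with a global-geometry
method (ISOMAP or diffusion map), and summarized by their per-cluster
median positions. Marker expression along a chosen embedding component
over a user-annotated ordered path of clusters is then modeled with a
left-censored (Tobit) Gaussian regression, since transformed cytometry
intensities pile up at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from .clusterx import ClusterResult
from .dimred import Embedding

__all__ = [
    "TobitFit",
    "downsample_equal",
    "cluster_medians",
    "tobit_loglik",
    "fit_tobit",
    "marker_trend",
]


@dataclass
class TobitFit:
    beta0: float
    beta1: float
    scale: float
    left_limit: float
    loglik: float
    converged: bool
    n_censored: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Latent (uncensored) regression line."""
        return self.beta0 + self.beta1 * np.asarray(x, dtype=np.float64)


def downsample_equal(
    labels: np.ndarray | ClusterResult, target: int = 500, seed: int = 0
) -> np.ndarray:
    """Up-to-``target`` cells per cluster, sampled without replacement."""
    if target < 1:
        raise ValueError("target must be >= 1")
    lab = labels.labels if isinstance(labels, ClusterResult) else np.asarray(labels)
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for c in np.unique(lab):
        members = np.flatnonzero(lab == c)
        if members.size == 0:
            warnings.warn(f"cluster {c} is empty; skipped")
            continue
        take = min(target, members.size)
        chosen.append(np.sort(rng.choice(members, size=take, replace=False)))
    return np.sort(np.concatenate(chosen))


def cluster_medians(
    embedding: Embedding | np.ndarray, labels: np.ndarray | ClusterResult
) -> pd.DataFrame:
    """Coordinate-wise median position of each cluster."""
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding, float)
    lab = labels.labels if isinstance(labels, ClusterResult) else np.asarray(labels)
    if coords.shape[0] != lab.shape[0]:
        raise ValueError("labels and embedding disagree on cell count")
    uniq = np.unique(lab)
    rows = [np.median(coords[lab == c], axis=0) for c in uniq]
    cols = [f"dim_{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(rows, index=pd.Index(uniq, name="cluster"), columns=cols)


def tobit_loglik(
    params: np.ndarray, x: np.ndarray, y: np.ndarray, left: float
) -> float:
    """Log-likelihood of the left-censored Gaussian linear model.

    params = (beta0, beta1, log sigma). Uncensored observations
    contribute the Gaussian density of the residual; observations at or
    below the limit contribute Phi((L - mu)/sigma).
    """
    beta0, beta1, log_sigma = params
    sigma = np.exp(log_sigma)
    mu = beta0 + beta1 * x
    censored = y <= left
    ll = 0.0
    if np.any(~censored):
        z = (y[~censored] - mu[~censored]) / sigma
        ll += float(np.sum(norm.logpdf(z) - log_sigma))
    if np.any(censored):
        ll += float(np.sum(norm.logcdf((left - mu[censored]) / sigma)))
    return ll


def fit_tobit(x: np.ndarray, y: np.ndarray, left_limit: float = 0.0) -> TobitFit:
    """Maximum-likelihood Tobit fit of y on x, left-censored at ``left_limit``.

    Optimization runs on (beta0, beta1, log sigma) — keeping the scale
    positive — from an ordinary-least-squares start. With no censored
    observations the MLE coincides with OLS.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 10:
        raise ValueError("x and y must be equal-length vectors with >= 10 points")
    censored = y <= left_limit
    n_cens = int(censored.sum())
    if n_cens == y.size:
        raise ValueError("fully censored response: every y is at or below the limit")

    beta1_0, beta0_0 = np.polyfit(x, y, 1)
    resid = y - (beta0_0 + beta1_0 * x)
    sigma0 = max(float(np.std(resid)), 1e-6)
    start = np.array([beta0_0, beta1_0, np.log(sigma0)])

    res = optimize.minimize(
        lambda p: -tobit_loglik(p, x, y, left_limit),
        start,
        method="BFGS",
        options={"maxiter": 500},
    )
    # keep the better of start and optimum: the MLE never loses to the start
    if tobit_loglik(res.x, x, y, left_limit) < tobit_loglik(start, x, y, left_limit):
        res.x = start
        res.success = False
    beta0, beta1, log_sigma = res.x
    return TobitFit(
        beta0=float(beta0),
        beta1=float(beta1),
        scale=float(np.exp(log_sigma)),
        left_limit=float(left_limit),
        loglik=float(tobit_loglik(res.x, x, y, left_limit)),
        converged=bool(res.success),
        n_censored=n_cens,
    )


def marker_trend(
    expression,
    embedding: Embedding | np.ndarray,
    labels: np.ndarray | ClusterResult,
    path: list[int],
    marker: str,
    component: int = 2,
    reverse: bool = False,
    grid_points: int = 100,
) -> tuple[TobitFit, pd.DataFrame]:
    """Tobit trend of one marker along an embedding component over a path.

    ``path`` is the user-annotated ordered list of cluster labels to
    include; the predictor is the chosen embedding component (optionally
    sign-reversed to match the annotated direction), the response is the
    marker's transformed expression, left-censored at zero. Returns the
    fit plus the fitted latent line evaluated on an x-grid.
    """
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding, float)
    lab = labels.labels if isinstance(labels, ClusterResult) else np.asarray(labels)
    if component < 1 or component > coords.shape[1]:
        raise ValueError(f"component {component} outside 1..{coords.shape[1]}")
    try:
        col = expression.marker_names.index(marker)
        values = expression.values[:, col]
    except AttributeError:
        raise TypeError("expression must be an ExpressionMatrix")
    except ValueError:
        raise KeyError(
            f"marker {marker!r} not found; available: {expression.marker_names}"
        )
    mask = np.isin(lab, path)
    if not mask.any():
        raise ValueError("no cells belong to the requested path clusters")
    xx = coords[mask, component - 1]
    if reverse:
        xx = -xx
    yy = values[mask]
    fit = fit_tobit(xx, yy, left_limit=0.0)
    grid = np.linspace(xx.min(), xx.max(), grid_points)
    curve = pd.DataFrame({"x": grid, "fitted": fit.predict(grid)})
    return fit, curve
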