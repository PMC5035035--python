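"""Intensity transforms and multi-sample merging.

Mass cytometry intensities are variance-stabilized before clustering,
either with the cofactor-5 inverse hyperbolic sine customary for CyTOF
(``cytofAsinh``) or with a per-channel automatically parameterized
logicle transform (``autoLgcl``) as used for fluorescence data. After
per-file transformation, the files are combined into a single
expression matrix by one of four strategies (ceil / all / min / fixed).

Transforms are applied per channel BEFORE merging; merging never
re-transforms, because channel ranges differ between files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .fcs import CellId, make_cell_ids

__all__ = [
    "TransformSpec",
    "MergeSpec",
    "ExpressionMatrix",
    "transform_cytof_asinh",
    "LogicleTransform",
    "transform_auto_logicle",
    "merge_samples",
]


@dataclass(frozen=True)
class TransformSpec:
    method: str = "cytofAsinh"  # cytofAsinh | autoLgcl | none
    cofactor: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("cytofAsinh", "autoLgcl", "none"):
            raise ValueError(f"unknown transform method {self.method!r}")
        if self.cofactor <= 0:
            raise ValueError("cofactor must be positive")


@dataclass(frozen=True)
class MergeSpec:
    method: str = "ceil"  # ceil | all | min | fixed
    fixed_num: int | None = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("ceil", "all", "min", "fixed"):
            raise ValueError(f"unknown merge method {self.method!r}")
        if self.method in ("ceil", "fixed") and (
            self.fixed_num is None or self.fixed_num < 1
        ):
            raise ValueError(f"merge method {self.method!r} requires fixed_num >= 1")


@dataclass
class ExpressionMatrix:
    """Cells x selected markers after transform and merge."""

    values: np.ndarray
    cell_ids: list[CellId]
    marker_names: list[str]
    transform: TransformSpec | None = None
    merge: MergeSpec | None = None

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.cell_ids), len(self.marker_names)):
            raise ValueError("values shape inconsistent with cell_ids/marker_names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


# --------------------------------------------------------------------------
# cytofAsinh


def transform_cytof_asinh(
    values: np.ndarray,
    cofactor: float = 5.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Negative-value-pruned arcsinh transform: asinh((x - 1)/cofactor).

    Shifted values x - 1 that fall below zero are replaced with a small
    seeded Normal(0, 0.01^2) draw, so zero-count events stay near zero
    on the transformed scale instead of mapping to a spurious negative
    mode. The uncensored range x >= 1 is left fully deterministic.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    x = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("input values must be finite")
    if rng is None:
        rng = np.random.default_rng(seed)
    shifted = x - 1.0
    neg = shifted < 0
    if np.any(neg):
        shifted = shifted.copy()
        shifted[neg] = rng.normal(0.0, 0.01, size=int(neg.sum()))
    return np.arcsinh(shifted / cofactor)


# --------------------------------------------------------------------------
# logicle


class LogicleTransform:
    """Logicle (biexponential) display transform.

    Parameters follow the standard convention: ``T`` top of scale, ``M``
    display decades, ``W`` linearization width in decades, ``A`` extra
    negative decades. The forward transform maps data values onto the
    normalized display scale [0, 1] (x = T maps to exactly 1) by
    bracketed root-finding on the monotone biexponential inverse.
    """

    def __init__(self, T: float, W: float, M: float = 4.5, A: float = 0.0):
        if T <= 0:
            raise ValueError("T must be positive")
        if W < 0 or W > M / 2:
            raise ValueError("W must lie in [0, M/2]")
        self.T, self.W, self.M, self.A = float(T), float(W), float(M), float(A)
        span = M + A
        self._w = W / span
        self._x2 = A / span
        self._x1 = self._x2 + self._w
        self._x0 = self._x2 + 2.0 * self._w
        self._b = span * np.log(10.0)
        self._d = self._solve_d(self._w, self._b)
        c_a = np.exp(self._x0 * (self._b + self._d))
        mf_a = np.exp(self._b * self._x1) - c_a / np.exp(self._d * self._x1)
        self._a = T / (np.exp(self._b) - mf_a - c_a / np.exp(self._d))
        self._c = c_a * self._a
        self._f = -mf_a * self._a  # fixes B(x1) = 0, hence B(1) = T

    @staticmethod
    def _solve_d(w: float, b: float) -> float:
        # root of  w (b + d) + 2 (ln d - ln b) = 0  in (0, b]
        if w == 0:
            return b
        func = lambda d: w * (b + d) + 2.0 * (np.log(d) - np.log(b))
        return brentq(func, 1e-12, b, xtol=1e-12, rtol=1e-14)

    def inverse(self, y: float | np.ndarray) -> float | np.ndarray:
        """Display scale -> data value (the biexponential)."""
        arr = np.atleast_1d(np.asarray(y, dtype=np.float64))
        out = np.empty_like(arr)
        above = arr >= self._x1
        out[above] = self._series(arr[above])
        out[~above] = -self._series(2.0 * self._x1 - arr[~above])
        return out if np.ndim(y) else float(out[0])

    def _series(self, y: np.ndarray) -> np.ndarray:
        return self._a * np.exp(self._b * y) - self._c * np.exp(-self._d * y) + self._f

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Data values -> normalized display scale (monotone)."""
        x = np.atleast_1d(np.asarray(values, dtype=np.float64))
        uniq, inv = np.unique(x, return_inverse=True)
        # bracket: inverse() is strictly increasing on the real line
        lo, hi = -0.5, 1.5
        while self.inverse(lo) > uniq[0]:
            lo -= 0.5
        while self.inverse(hi) < uniq[-1]:
            hi += 0.5
        ys = np.array(
            [
                brentq(lambda t, v=v: float(self.inverse(t)) - v, lo, hi, xtol=1e-10)
                for v in uniq
            ]
        )
        out = ys[inv]
        return out if np.ndim(values) else float(out[0])


def transform_auto_logicle(values: np.ndarray, M: float = 4.5) -> np.ndarray:
    """Logicle transform with per-channel automatic parameters.

    T is the channel maximum, A = 0, and the linearization width is
    estimated from the negative tail as W = (M - log10(T/|q|)) / 2 with
    q the 0.25 quantile of the channel's negative values. Channels with
    no negative events, or whose estimate falls outside (0, M/2], use
    the conservative fallback W = 0.1.
    """
    x = np.asarray(values, dtype=np.float64)
    finite = x[np.isfinite(x)]
    if finite.size < 10:
        raise ValueError("need at least 10 finite values to parameterize logicle")
    if np.ptp(finite) == 0:
        raise ValueError("degenerate channel: all values identical")
    T = float(np.max(finite))
    if T <= 0:
        raise ValueError("channel maximum must be positive for logicle scaling")
    neg = finite[finite < 0]
    W = 0.1
    if neg.size > 0:
        q = float(np.quantile(neg, 0.25))
        cand = (M - np.log10(T / abs(q))) / 2.0
        if 0 < cand <= M / 2:
            W = cand
    return LogicleTransform(T=T, W=W, M=M, A=0.0).apply(x)


# --------------------------------------------------------------------------
# merging


def merge_samples(
    blocks: list[tuple[np.ndarray, str]],
    marker_names: list[str],
    spec: MergeSpec,
    transform: TransformSpec | None = None,
) -> ExpressionMatrix:
    """Combine per-file (already transformed) matrices into one.

    Strategies: ``ceil`` samples up to ``fixed_num`` cells without
    replacement from each file; ``all`` keeps every cell; ``min``
    samples the smallest per-file count from each file without
    replacement; ``fixed`` samples exactly ``fixed_num`` per file, with
    replacement when a file holds fewer cells. One seeded generator is
    consumed in file order, so a fixed seed reproduces the merge.
    """
    if not blocks:
        raise ValueError("no input blocks")
    n_markers = len(marker_names)
    for mat, name in blocks:
        if mat.ndim != 2 or mat.shape[1] != n_markers:
            raise ValueError(
                f"block {name!r} has {mat.shape} columns; expected {n_markers} markers"
            )
        if mat.shape[0] == 0:
            raise ValueError(f"block {name!r} is empty")

    rng = np.random.default_rng(spec.seed)
    sizes = [mat.shape[0] for mat, _ in blocks]
    min_size = min(sizes)

    parts: list[np.ndarray] = []
    ids: list[CellId] = []
    for (mat, name), n_b in zip(blocks, sizes):
        if spec.method == "all":
            idx = np.arange(n_b)
        elif spec.method == "min":
            idx = np.sort(rng.choice(n_b, size=min_size, replace=False))
        elif spec.method == "ceil":
            take = min(spec.fixed_num, n_b)
            idx = np.sort(rng.choice(n_b, size=take, replace=False))
        else:  # fixed
            replace = n_b < spec.fixed_num
            idx = np.sort(rng.choice(n_b, size=spec.fixed_num, replace=replace))
        parts.append(mat[idx])
        file_ids = make_cell_ids(name, n_b)
        ids.extend(file_ids[i] for i in idx)

    return ExpressionMatrix(
        values=np.vstack(parts),
        cell_ids=ids,
        marker_names=list(marker_names),
        transform=transform,
        merge=spec,
    )
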