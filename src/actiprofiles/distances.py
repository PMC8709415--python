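"""Distances between hourly activity profiles and metric agreement.

Supports plain Euclidean distance and classical dynamic time warping
(absolute-difference local cost, unit match/insert/delete steps, optional
Sakoe-Chiba band), plus a rank-correlation summary quantifying how far the
two metrics order profile pairs the same way. On hourly activity data the
two orderings agree closely, which justifies using the cheaper Euclidean
distance for clustering at scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

__all__ = [
    "DistanceMatrix",
    "euclidean",
    "dtw",
    "pairwise",
    "metric_agreement",
]


def euclidean(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (not squared) Euclidean distance between equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def _dtw_python(a: np.ndarray, b: np.ndarray, band: int) -> float:
    n, m = a.size, b.size
    inf = np.inf
    prev = np.full(m + 1, inf)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur = np.full(m + 1, inf)
        if band >= 0:
            lo = max(1, i - band)
            hi = min(m, i + band)
        else:
            lo, hi = 1, m
        for j in range(lo, hi + 1):
            cost = abs(a[i - 1] - b[j - 1])
            cur[j] = cost + min(prev[j], cur[j - 1], prev[j - 1])
        prev = cur
    return float(prev[m])


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _dtw_kernel = njit(_dtw_python)
except Exception:  # pragma: no cover
    _dtw_kernel = _dtw_python


def dtw(a: np.ndarray, b: np.ndarray, band: int | None = None) -> float:
    """Classical DTW distance with optional Sakoe-Chiba band.

    Local cost is the absolute difference; steps are the unit match, insert
    and delete moves; no path-length normalisation. ``band`` is the
    half-width of the allowed corridor around the diagonal, in samples; it
    must be at least the length difference of the inputs for a path to
    exist.
    """
    a = np.ascontiguousarray(a, dtype=float)
    b = np.ascontiguousarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size == 0 or b.size == 0:
        raise ValueError("dtw requires two non-empty one-dimensional vectors")
    if band is not None:
        band = int(band)
        if band < 1:
            raise ValueError("band must be >= 1")
        if band < abs(a.size - b.size):
            raise ValueError(
                f"band {band} smaller than length difference "
                f"{abs(a.size - b.size)}: no feasible warping path")
    return float(_dtw_kernel(a, b, -1 if band is None else band))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances for a set of profiles."""

    ids: list
    metric: str
    entries: np.ndarray
    band: int | None = None

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        n = len(self.ids)
        if self.entries.shape != (n, n):
            raise ValueError("entries must be square and match ids")
        if not np.allclose(self.entries, self.entries.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.entries) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.entries < 0):
            raise ValueError("distances must be non-negative")

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.entries[iu]

    def to_long_frame(self) -> pd.DataFrame:
        iu = np.triu_indices(len(self.ids), k=1)
        return pd.DataFrame({
            "id1": [self.ids[i] for i in iu[0]],
            "id2": [self.ids[j] for j in iu[1]],
            "distance": self.entries[iu],
        })


def pairwise(
    X: np.ndarray,
    metric: str = "euclidean",
    ids: list | None = None,
    sample_size: int | None = None,
    seed: int | None = None,
    band: int | None = None,
) -> DistanceMatrix:
    """All unordered pairwise distances, optionally on a seeded subsample."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("pairwise requires an n x p matrix with n >= 2")
    ids = list(range(X.shape[0])) if ids is None else list(ids)
    if len(ids) != X.shape[0]:
        raise ValueError("one id required per profile")
    if sample_size is not None and sample_size < X.shape[0]:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(X.shape[0], size=sample_size, replace=False))
        X = X[keep]
        ids = [ids[i] for i in keep]

    if metric == "euclidean":
        entries = squareform(pdist(X, metric="euclidean"))
    elif metric == "dtw":
        n = X.shape[0]
        entries = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                entries[i, j] = entries[j, i] = dtw(X[i], X[j], band=band)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(ids=ids, metric=metric, entries=entries, band=band)


def metric_agreement(d1: DistanceMatrix, d2: DistanceMatrix) -> dict:
    """Rank agreement between two distance matrices over the same profiles.

    Returns the Spearman correlation of the vectorised upper triangles and
    the per-pair long table for scatter plotting.
    """
    if d1.ids != d2.ids:
        raise ValueError("distance matrices must cover the same ids in order")
    u1, u2 = d1.upper_triangle(), d2.upper_triangle()
    rho = spearmanr(u1, u2).statistic
    pairs = d1.to_long_frame().rename(columns={"distance": f"distance_{d1.metric}"})
    pairs[f"distance_{d2.metric}"] = u2
    return {
        "spearman": float(rho),
        "n_profiles": len(d1.ids),
        "n_pairs": int(u1.size),
        "metrics": (d1.metric, d2.metric),
        "pairs": pairs,
    }
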