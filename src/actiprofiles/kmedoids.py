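"""Partitioning Around Medoids (PAM) for weekly activity profiles.

k-medoids constrains every cluster centre to be an actual profile in the
data and scores a partition by the sum of plain (not squared) Euclidean
distances from each profile to its medoid, which makes it markedly less
sensitive to outlying profiles than k-means. The implementation is the
classical Kaufman-Rousseeuw scheme: a greedy BUILD initialisation followed
by steepest-descent SWAP exchanges, each accepted swap strictly decreasing
the total dissimilarity. A CLARA-style subsampling variant is provided for
cohorts too large for the full n x n distance matrix.

Choosing k uses the total-dissimilarity scree over a range of k and a
formal first-difference rule: the suggested k is the last one whose
dissimilarity reduction still stands out against the reductions that follow
it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "MedoidSolution",
    "ScreeCurve",
    "total_dissimilarity",
    "pam_build",
    "fit",
    "fit_clara",
    "scree",
    "select_k",
    "assign",
]

#: Relative guard against floating-point cycling in SWAP acceptance.
SWAP_RTOL = 1e-12


@dataclass
class MedoidSolution:
    """A fitted k-medoids partition.

    ``medoid_indices`` point into the fitted data matrix; ``medoid_profiles``
    carry the centre vectors themselves so the solution can label new
    profiles without the training data.
    """

    k: int
    medoid_indices: np.ndarray
    medoid_profiles: np.ndarray
    assignments: np.ndarray
    total_dissimilarity: float
    n_iterations: int
    seed: int | None = None
    converged: bool = True
    dissimilarity_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.medoid_indices = np.asarray(self.medoid_indices, dtype=int)
        self.medoid_profiles = np.asarray(self.medoid_profiles, dtype=float)
        self.assignments = np.asarray(self.assignments, dtype=int)
        if len(set(self.medoid_indices.tolist())) != self.k:
            raise ValueError("medoid indices must be k distinct rows")

    def to_json(self) -> str:
        return json.dumps({
            "k": self.k,
            "medoid_indices": self.medoid_indices.tolist(),
            "medoid_profiles": self.medoid_profiles.tolist(),
            "assignments": self.assignments.tolist(),
            "total_dissimilarity": self.total_dissimilarity,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "converged": self.converged,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MedoidSolution":
        data = json.loads(text)
        return cls(
            k=data["k"],
            medoid_indices=np.asarray(data["medoid_indices"]),
            medoid_profiles=np.asarray(data["medoid_profiles"]),
            assignments=np.asarray(data["assignments"]),
            total_dissimilarity=data["total_dissimilarity"],
            n_iterations=data["n_iterations"],
            seed=data.get("seed"),
            converged=data.get("converged", True),
        )


def _distance_matrix(X: np.ndarray) -> np.ndarray:
    return squareform(pdist(np.asarray(X, dtype=float), metric="euclidean"))


def total_dissimilarity(X: np.ndarray, medoids: np.ndarray,
                        assignments: Sequence[int]) -> float:
    """Sum of plain Euclidean distances of each profile to its medoid.

    ``medoids`` may be row indices into ``X`` or a k x p matrix of medoid
    profiles; ``assignments`` are positions into that medoid list.
    """
    X = np.asarray(X, dtype=float)
    medoids = np.asarray(medoids)
    profiles = X[medoids.astype(int)] if medoids.ndim == 1 else medoids
    assignments = np.asarray(assignments, dtype=int)
    return float(np.linalg.norm(X - profiles[assignments], axis=1).sum())


def pam_build(X: np.ndarray, k: int, D: np.ndarray | None = None) -> np.ndarray:
    """Greedy BUILD initialisation (deterministic, seed-free).

    The first medoid minimises the total distance to all profiles; each
    further medoid is the point that most reduces the total dissimilarity
    when added. Ties break to the lowest row index.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n, got k={k}, n={n}")
    if D is None:
        D = _distance_matrix(X)
    medoids = [int(np.argmin(D.sum(axis=1)))]
    d_nearest = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.clip(d_nearest[:, None] - D, 0.0, None).sum(axis=0)
        gains[medoids] = -np.inf
        nxt = int(np.argmax(gains))
        medoids.append(nxt)
        d_nearest = np.minimum(d_nearest, D[:, nxt])
    return np.asarray(medoids, dtype=int)


def _nearest(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest-medoid position, its distance, and the second-nearest distance."""
    dm = D[:, medoids]
    pos = np.argmin(dm, axis=1)
    rows = np.arange(D.shape[0])
    d1 = dm[rows, pos]
    if medoids.size == 1:
        d2 = np.full(D.shape[0], np.inf)
    else:
        dm2 = dm.copy()
        dm2[rows, pos] = np.inf
        d2 = dm2.min(axis=1)
    return pos, d1, d2


def _swap(D: np.ndarray, medoids: np.ndarray, max_iter: int) -> tuple[
        np.ndarray, np.ndarray, float, int, bool, list]:
    """Steepest-descent SWAP; each accepted exchange strictly lowers cost."""
    medoids = np.array(medoids, dtype=int)
    n = D.shape[0]
    history = []
    n_swaps = 0
    converged = False
    for _ in range(max_iter):
        pos, d1, d2 = _nearest(D, medoids)
        total = float(d1.sum())
        if not history:
            history.append(total)
        best_delta = 0.0
        best_pair = None
        for mi in range(medoids.size):
            mask = pos == mi
            # cost change of replacing medoid mi with every candidate h
            delta = np.minimum(D[mask], d2[mask, None]).sum(axis=0) \
                - d1[mask].sum() \
                + np.minimum(D[~mask] - d1[~mask, None], 0.0).sum(axis=0)
            delta[medoids] = np.inf
            h = int(np.argmin(delta))
            if delta[h] < best_delta:
                best_delta = float(delta[h])
                best_pair = (mi, h)
        if best_pair is None or -best_delta <= SWAP_RTOL * max(total, 1.0):
            converged = True
            break
        medoids[best_pair[0]] = best_pair[1]
        n_swaps += 1
        _, d1_new, _ = _nearest(D, medoids)
        history.append(float(d1_new.sum()))

    order = np.argsort(medoids)
    medoids = medoids[order]
    pos, d1, _ = _nearest(D, medoids)
    return medoids, pos, float(d1.sum()), n_swaps, converged, history


def fit(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    n_restarts: int = 3,
    D: np.ndarray | None = None,
    extra_inits: Sequence[np.ndarray] = (),
) -> MedoidSolution:
    """Fit PAM: BUILD + SWAP, best of ``n_restarts`` initialisations.

    Restart 0 is the deterministic BUILD start; further restarts use random
    distinct medoid sets drawn from ``seed``. ``extra_inits`` allows warm
    starts (used by :func:`scree` to keep the curve monotone). If SWAP does
    not converge within ``max_iter`` passes the best solution is still
    returned with ``converged=False``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n, got k={k}, n={n}")
    if D is None:
        D = _distance_matrix(X)
    rng = np.random.default_rng(seed)

    inits: list[np.ndarray] = [pam_build(X, k, D)]
    for _ in range(max(0, n_restarts - 1)):
        inits.append(rng.choice(n, size=k, replace=False))
    inits.extend(np.asarray(e, dtype=int) for e in extra_inits)

    best = None
    for init in inits:
        medoids, pos, total, n_swaps, converged, history = _swap(D, init, max_iter)
        if best is None or total < best[2]:
            best = (medoids, pos, total, n_swaps, converged, history)
    medoids, pos, total, n_swaps, converged, history = best
    return MedoidSolution(
        k=k,
        medoid_indices=medoids,
        medoid_profiles=X[medoids],
        assignments=pos,
        total_dissimilarity=total,
        n_iterations=n_swaps,
        seed=seed,
        converged=converged,
        dissimilarity_history=history,
    )


def fit_clara(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    sample_size: int | None = None,
    n_samples: int = 5,
    max_iter: int = 100,
) -> MedoidSolution:
    """CLARA-style PAM for large n: best of PAM fits on seeded subsamples.

    Each candidate medoid set is fitted on a random subsample and scored on
    the full data; the best-scoring set is kept. Avoids the full n x n
    distance matrix.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if sample_size is None:
        sample_size = min(n, 40 + 2 * k)
    sample_size = min(n, max(sample_size, k))
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_samples):
        idx = np.sort(rng.choice(n, size=sample_size, replace=False))
        sub = fit(X[idx], k, seed=seed, max_iter=max_iter)
        medoid_idx = idx[sub.medoid_indices]
        labels, dists = assign(X, X[medoid_idx])
        total = float(dists.sum())
        if best is None or total < best[1]:
            best = (medoid_idx, total, labels, sub)
    medoid_idx, total, labels, sub = best
    order = np.argsort(medoid_idx)
    medoid_idx = medoid_idx[order]
    labels, dists = assign(X, X[medoid_idx])
    return MedoidSolution(
        k=k,
        medoid_indices=medoid_idx,
        medoid_profiles=X[medoid_idx],
        assignments=labels,
        total_dissimilarity=float(dists.sum()),
        n_iterations=sub.n_iterations,
        seed=seed,
        converged=sub.converged,
    )


# ---------------------------------------------------------------------------
# Choosing k
# ---------------------------------------------------------------------------

@dataclass
class ScreeCurve:
    """Total dissimilarity as a function of k, with first differences."""

    k_values: list
    dissimilarities: np.ndarray
    first_differences: np.ndarray
    suggested_k: int
    rule_params: dict
    solutions: dict = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.k_values,
            "dissimilarity": self.dissimilarities,
            "first_difference": np.concatenate(
                [[np.nan], self.first_differences]),
        })


def scree(
    X: np.ndarray,
    k_min: int = 1,
    k_max: int = 16,
    seed: int = 0,
    n_restarts: int = 3,
    max_iter: int = 100,
    tau: float = 0.5,
) -> ScreeCurve:
    """Fit PAM for every k in [k_min, k_max] and record the dissimilarity scree.

    The same restart seed policy is shared across all k so the curve is
    comparable, and each k additionally warm-starts from the previous k's
    medoids extended by the best additional point, which makes the curve
    non-increasing by construction.
    """
    X = np.asarray(X, dtype=float)
    if not 1 <= k_min <= k_max <= X.shape[0]:
        raise ValueError("need 1 <= k_min <= k_max <= n")
    D = _distance_matrix(X)
    dissimilarities = []
    prev_medoids: np.ndarray | None = None
    solutions = {}
    for k in range(k_min, k_max + 1):
        extra = []
        if prev_medoids is not None:
            _, d1, _ = _nearest(D, prev_medoids)
            gains = np.clip(d1[:, None] - D, 0.0, None).sum(axis=0)
            gains[prev_medoids] = -np.inf
            extra.append(np.append(prev_medoids, int(np.argmax(gains))))
        sol = fit(X, k, seed=seed, max_iter=max_iter, n_restarts=n_restarts,
                  D=D, extra_inits=extra)
        solutions[k] = sol
        dissimilarities.append(sol.total_dissimilarity)
        prev_medoids = sol.medoid_indices
    dissimilarities = np.asarray(dissimilarities)
    first_differences = dissimilarities[:-1] - dissimilarities[1:]
    curve = ScreeCurve(
        k_values=list(range(k_min, k_max + 1)),
        dissimilarities=dissimilarities,
        first_differences=first_differences,
        suggested_k=k_min,
        rule_params={"tau": tau, "k_max": k_max},
    )
    curve.suggested_k = select_k(curve, tau=tau)
    curve.solutions.update(solutions)
    return curve


def select_k(curve: ScreeCurve, tau: float = 0.5) -> int:
    """Last k whose dissimilarity reduction stands out against what follows.

    A reduction counts as sizeable when it exceeds ``(1 + tau)`` times the
    median of the reductions at all larger k. The suggested k is the largest
    k with a sizeable reduction; a flat curve suggests ``k_min``.
    """
    if len(curve.k_values) < 3:
        raise ValueError("select_k needs a scree over at least 3 values of k")
    k_values = curve.k_values
    deltas = curve.first_differences  # deltas[i] is the drop reaching k_values[i+1]
    suggested = k_values[0]
    for i in range(len(deltas) - 1):  # last k has no tail to compare against
        tail = deltas[i + 1:]
        if deltas[i] > (1.0 + tau) * float(np.median(tail)):
            suggested = k_values[i + 1]
    return suggested


def assign(profiles: np.ndarray, medoid_profiles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Label profiles by the nearest medoid (Euclidean; ties to lowest index)."""
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    medoid_profiles = np.atleast_2d(np.asarray(medoid_profiles, dtype=float))
    if profiles.shape[1] != medoid_profiles.shape[1]:
        raise ValueError("profiles and medoids must have the same dimension")
    dists = cdist(profiles, medoid_profiles, metric="euclidean")
    labels = np.argmin(dists, axis=1)
    return labels, dists[np.arange(profiles.shape[0]), labels]
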