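"""Subtractive and fuzzy C-means clustering over the joint input-output space.

Both clusterers run on [0, 1]-normalized data.  Subtractive clustering
(Chiu's method) scores every data point by its potential — a sum of
Gaussian kernels over all points,

    D_i = sum_j exp(-||x_i - x_j||^2 / (r/2)^2),

with r the influence range expressed as a fraction of the data width —
and greedily extracts high-potential points as cluster centers, revising
the potentials after each pick.  Fuzzy C-means then (optionally) refines
those centers by alternating minimization of the fuzzified within-cluster
objective J_m = sum_ij u_ij^m ||x_i - c_j||^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SubtractiveParams:
    """Chiu subtractive-clustering constants.

    ``radius`` is the influence range as a fraction of the (normalized)
    data width; 1/3 is the operating point used throughout this package.
    ``squash_factor`` widens the potential-revision kernel so accepted
    centers suppress their neighborhood; accept/reject ratios bound the
    greedy extraction, with the standard distance-based tie band between.
    """

    radius: float = 1.0 / 3.0
    squash_factor: float = 1.25
    accept_ratio: float = 0.5
    reject_ratio: float = 0.15

    def __post_init__(self) -> None:
        if not 0 < self.radius <= 1:
            raise ValueError("radius must lie in (0, 1]")
        if self.squash_factor <= 1:
            raise ValueError("squash_factor must exceed 1")
        if not 0 < self.reject_ratio < self.accept_ratio <= 1:
            raise ValueError("require 0 < reject_ratio < accept_ratio <= 1")


@dataclass(frozen=True)
class FcmParams:
    """Fuzzy C-means settings: cluster count C, fuzzifier m, termination eps."""

    n_clusters: int
    fuzzifier: float = 2.0
    eps: float = 1e-5
    max_iterations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier m must exceed 1")
        if not 0 < self.eps < 1:
            raise ValueError("eps must lie in (0, 1)")


@dataclass
class ClusterResult:
    """Cluster centers plus algorithm-specific diagnostics.

    For subtractive clustering, ``potentials`` holds the initial potential
    of every data point and ``center_indices`` the rows chosen as centers
    (centers are always a subset of the data).  For FCM, ``memberships``
    is the row-stochastic N x C membership matrix and
    ``objective_history`` the non-increasing J_m sequence.
    """

    centers: np.ndarray
    memberships: np.ndarray | None = None
    potentials: np.ndarray | None = None
    objective_history: np.ndarray | None = None
    center_indices: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances, (len(a), len(b))."""
    diff = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def compute_potentials(points: np.ndarray, radius: float) -> np.ndarray:
    """Potential of each point: sum of Gaussian kernels of width r/2 over all points.

    Every potential is >= 1 because the self-term contributes exp(0).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 1:
        raise ValueError("need at least one point")
    if radius <= 0:
        raise ValueError("radius must be positive")
    d2 = _sq_dists(points, points)
    return np.exp(-d2 / (radius / 2.0) ** 2).sum(axis=1)


def subtractive_cluster(
    points: np.ndarray, params: SubtractiveParams | None = None
) -> ClusterResult:
    """Greedy potential-based center extraction (Chiu's subtractive clustering).

    The max-potential point becomes the first center; a squashed Gaussian
    (radius ``squash_factor * radius``) of its potential is subtracted from
    all points, and extraction continues while the relative potential stays
    above ``accept_ratio``, stops below ``reject_ratio``, and applies the
    standard distance-based tie band in between.  Ties in potential break
    to the lowest index, making the procedure fully deterministic.
    """
    params = params or SubtractiveParams()
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    potentials = compute_potentials(points, params.radius)
    work = potentials.copy()
    squash_sq = (params.squash_factor * params.radius / 2.0) ** 2
    centers: list[int] = []
    first_potential = None
    while len(centers) < n:
        k = int(np.argmax(work))  # lowest index wins ties
        p_k = float(work[k])
        if first_potential is None:
            accept = True
        else:
            ratio = p_k / first_potential
            if ratio > params.accept_ratio:
                accept = True
            elif ratio < params.reject_ratio:
                break
            else:
                # tie band: keep the candidate only if it is far from existing
                # centers relative to its (reduced) potential
                d_min = np.sqrt(
                    _sq_dists(points[k : k + 1], points[centers]).min()
                )
                if d_min / params.radius + ratio >= 1.0:
                    accept = True
                else:
                    work[k] = 0.0
                    continue
        if accept:
            if first_potential is None:
                first_potential = p_k
            centers.append(k)
            d2 = _sq_dists(points, points[k : k + 1])[:, 0]
            work = work - p_k * np.exp(-d2 / squash_sq)
    idx = np.asarray(centers, dtype=int)
    return ClusterResult(
        centers=points[idx].copy(), potentials=potentials, center_indices=idx
    )


def _memberships_from_centers(
    points: np.ndarray, centers: np.ndarray, m: float
) -> np.ndarray:
    """Standard FCM membership update; a point on a center gets membership 1 there."""
    d2 = _sq_dists(points, centers)
    u = np.zeros_like(d2)
    zero_rows = (d2 <= 0).any(axis=1)
    if np.any(zero_rows):
        hits = d2[zero_rows] <= 0
        u[zero_rows] = hits / hits.sum(axis=1, keepdims=True)
    ok = ~zero_rows
    if np.any(ok):
        inv = d2[ok] ** (-1.0 / (m - 1.0))
        u[ok] = inv / inv.sum(axis=1, keepdims=True)
    return u


def fcm(
    points: np.ndarray,
    params: FcmParams,
    initial_centers: np.ndarray | None = None,
) -> ClusterResult:
    """Fuzzy C-means by alternating membership/center updates.

    Centers default to subtractive-clustering picks (topped up with seeded
    random data points if subtractive yields fewer than C).  Iteration
    stops when ``max |U(k+1) - U(k)| < eps`` or after ``max_iterations``.
    The recorded objective J_m is non-increasing by construction of the
    alternating updates.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if n == 0:
        raise ValueError("empty input")
    C = params.n_clusters
    if C > n:
        raise ValueError(f"C={C} clusters exceed N={n} points")
    if initial_centers is None:
        sub = subtractive_cluster(points)
        picked = list(sub.center_indices[:C])
        if len(picked) < C:
            rng = np.random.default_rng(params.seed)
            pool = [i for i in range(n) if i not in picked]
            extra = rng.choice(pool, size=C - len(picked), replace=False)
            picked.extend(int(i) for i in extra)
        centers = points[np.asarray(picked)].copy()
    else:
        centers = np.atleast_2d(np.asarray(initial_centers, dtype=float)).copy()
        if centers.shape[0] != C:
            raise ValueError("initial_centers count must equal n_clusters")

    m = params.fuzzifier
    history = []
    u = _memberships_from_centers(points, centers, m)
    for _ in range(params.max_iterations):
        um = u**m
        centers = (um.T @ points) / um.sum(axis=0)[:, None]
        history.append(float((um * _sq_dists(points, centers)).sum()))
        u_new = _memberships_from_centers(points, centers, m)
        delta = float(np.abs(u_new - u).max())
        u = u_new
        if delta < params.eps:
            break
    return ClusterResult(
        centers=centers,
        memberships=u,
        objective_history=np.asarray(history),
    )
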