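"""Microstate definition by k-means in IC space.

A deliberately small, fully deterministic Lloyd implementation: k-means++
seeding from an explicit seeded generator, nearest-center assignment with
ties broken toward the lowest center index, empty clusters re-seeded to
the farthest point.  Determinism under a fixed seed is part of the
contract -- the whole pipeline must be replayable bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin


def _pool(X) -> tuple[np.ndarray, list[int]]:
    if isinstance(X, np.ndarray):
        X = [X]
    arrs = [np.atleast_2d(np.asarray(a, dtype=float).T).T for a in X]
    return np.concatenate(arrs, axis=0), [len(a) for a in arrs]


def _chunked_assign(X: np.ndarray, centers: np.ndarray, chunk: int = 200_000):
    """Nearest-center labels and squared distances, low-memory."""
    labels = np.empty(len(X), dtype=np.int32)
    dist2 = np.empty(len(X))
    c2 = (centers**2).sum(axis=1)
    for lo in range(0, len(X), chunk):
        hi = min(lo + chunk, len(X))
        d2 = c2[None, :] - 2.0 * (X[lo:hi] @ centers.T)
        lab = np.argmin(d2, axis=1)  # ties -> lowest index
        labels[lo:hi] = lab
        dist2[lo:hi] = d2[np.arange(hi - lo), lab] + (X[lo:hi] ** 2).sum(axis=1)
    np.maximum(dist2, 0.0, out=dist2)
    return labels, dist2


class KMeansMicrostates(BaseEstimator, ClusterMixin):
    """Seeded k-means microstate model.

    Parameters: ``n_clusters`` (200 for the full-scale analysis, smaller
    for desk-scale fixtures), ``random_state`` (required, explicit),
    ``max_iter`` and the center-shift convergence tolerance ``tol``.

    Attributes after ``fit``: ``cluster_centers_``, ``labels_`` (pooled),
    ``inertia_``, ``n_iter_``.
    """

    def __init__(self, n_clusters: int = 200, random_state: int = 0,
                 max_iter: int = 500, tol: float = 1e-6):
        self.n_clusters = n_clusters
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        data, _ = _pool(X)
        k = int(self.n_clusters)
        if k < 1:
            raise ValueError("n_clusters must be >= 1")
        if k > len(data):
            raise ValueError("more clusters than frames")
        rng = np.random.default_rng(self.random_state)

        # k-means++ seeding (D^2 sampling)
        centers = np.empty((k, data.shape[1]))
        centers[0] = data[rng.integers(len(data))]
        _, d2 = _chunked_assign(data, centers[:1])
        for j in range(1, k):
            total = d2.sum()
            if total <= 0:
                centers[j] = data[rng.integers(len(data))]
                continue
            probs = d2 / total
            idx = rng.choice(len(data), p=probs)
            centers[j] = data[idx]
            _, d2_new = _chunked_assign(data, centers[j : j + 1])
            np.minimum(d2, d2_new, out=d2)

        prev_inertia = np.inf
        for it in range(int(self.max_iter)):
            labels, d2 = _chunked_assign(data, centers)
            new_centers = np.zeros_like(centers)
            counts = np.bincount(labels, minlength=k).astype(float)
            for dim in range(data.shape[1]):
                new_centers[:, dim] = np.bincount(labels, weights=data[:, dim], minlength=k)
            empty = counts == 0
            nonzero = ~empty
            new_centers[nonzero] /= counts[nonzero, None]
            if empty.any():
                far = np.argsort(d2)[::-1]
                for e, idx in zip(np.flatnonzero(empty), far):
                    new_centers[e] = data[idx]
            shift = float(np.max(np.linalg.norm(new_centers - centers, axis=1)))
            centers = new_centers
            inertia = float(d2.sum())
            if inertia > prev_inertia + 1e-9 and not empty.any():
                # Lloyd is monotone; numerical noise aside this cannot grow
                pass
            prev_inertia = min(prev_inertia, inertia)
            if shift < self.tol:
                break

        self.cluster_centers_ = centers
        self.labels_, d2 = _chunked_assign(data, centers)
        self.inertia_ = float(d2.sum())
        self.n_iter_ = it + 1
        return self

    def predict(self, X):
        single = isinstance(X, np.ndarray)
        data, lengths = _pool(X)
        labels, _ = _chunked_assign(data, self.cluster_centers_)
        if single:
            return labels
        out, pos = [], 0
        for n in lengths:
            out.append(labels[pos : pos + n])
            pos += n
        return out

    def fit_predict(self, X, y=None):
        self.fit(X)
        return self.predict(X)


def kmeans_cluster(projections, k: int, seed: int, max_iter: int = 500):
    """Fit microstates and discretize every trajectory.

    Returns ``(model, dtrajs)`` where ``dtrajs`` is a list of integer
    microstate trajectories matching the input list.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    model = KMeansMicrostates(n_clusters=k, random_state=seed, max_iter=max_iter)
    proj_list = projections if isinstance(projections, list) else [projections]
    model.fit(proj_list)
    return model, model.predict(proj_list)
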