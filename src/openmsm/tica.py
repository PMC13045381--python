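"""Time-lagged independent component analysis (tICA) and VAMP-2 scoring.

tICA solves the generalized eigenproblem ``C_tau v = lambda C_0 v`` with
the symmetrized (reversible) time-lagged covariance ``C_tau`` and the
instantaneous covariance ``C_0`` of mean-free features, pooled over all
trajectories.  The leading components are the slowest linear collective
coordinates; their eigenvalues are lag-``tau`` autocorrelations and map to
relaxation timescales ``-tau / ln|lambda|``.

Component screening discards fast components whose marginal is fit as well
by a single Gaussian as by a two-component mixture (strong-evidence BIC
margin), keeping at least the two slowest -- the (IC1, IC2) plane on which
free-energy landscapes are drawn.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.mixture import GaussianMixture

from .featurize import FeatureTrajectory


def _as_arrays(data) -> list[np.ndarray]:
    if isinstance(data, FeatureTrajectory):
        return [data.values]
    if isinstance(data, np.ndarray):
        return [np.atleast_2d(data.T).T if data.ndim == 1 else data]
    out = []
    for d in data:
        out.append(d.values if isinstance(d, FeatureTrajectory) else np.asarray(d, dtype=float))
    return out


class TICA(BaseEstimator, TransformerMixin):
    """Reversible tICA estimator with a relative-variance floor.

    Parameters
    ----------
    lag : int
        Lag time in frames.
    epsilon : float
        Relative eigenvalue floor on the instantaneous covariance; feature
        directions with variance below ``epsilon * max_variance`` are
        projected out before the generalized eigenproblem is solved.
    reversible : bool
        Use the symmetrized covariance estimator (default).  The plain
        non-symmetric estimator is available for diagnostics; eigenvalues
        are then not guaranteed real.

    Attributes (after ``fit``)
    --------------------------
    mean_ : (n_features,) pooled mean over all lagged windows.
    eigenvalues_ : descending, in [-1, 1] for the reversible estimator.
    components_ : (n_components, n_features) eigenvectors, normalized to
        unit variance under the instantaneous covariance metric.
    timescales_ : ``-lag / ln|eigenvalue|`` in frames.
    """

    def __init__(self, lag: int = 1, epsilon: float = 1e-10, reversible: bool = True):
        self.lag = lag
        self.epsilon = epsilon
        self.reversible = reversible

    def fit(self, X, y=None):
        trajs = _as_arrays(X)
        lag = int(self.lag)
        if lag < 1:
            raise ValueError("lag must be >= 1 frame")
        usable = [t for t in trajs if len(t) > lag]
        if not usable:
            raise ValueError("every trajectory is shorter than the lag")
        dim = usable[0].shape[1]
        if dim < 2:
            raise ValueError("tICA needs at least 2 features")

        # all-frame pooled mean: the projection of the training data is
        # then exactly mean-free (a common centre keeps C0 PSD and the
        # symmetrized eigenvalues inside [-1, 1])
        n = 0
        n_frames_total = 0
        s_all = np.zeros(dim)
        for t in usable:
            n += len(t) - lag
            n_frames_total += len(t)
            s_all += t.sum(axis=0)
        mean = s_all / n_frames_total
        C0 = np.zeros((dim, dim))
        Ct = np.zeros((dim, dim))
        for t in usable:
            a, b = t[:-lag] - mean, t[lag:] - mean
            Ct += a.T @ b
            if self.reversible:
                C0 += a.T @ a + b.T @ b
            else:
                C0 += a.T @ a
        C0 /= (2.0 * n) if self.reversible else n
        Ct /= n
        if self.reversible:
            Ct = 0.5 * (Ct + Ct.T)

        s, U = np.linalg.eigh(C0)
        keep = s > self.epsilon * s.max()
        if keep.sum() < 2:
            raise ValueError("covariance is rank-deficient after flooring")
        W = U[:, keep] / np.sqrt(s[keep])
        M = W.T @ Ct @ W
        if self.reversible:
            evals, evecs = np.linalg.eigh(0.5 * (M + M.T))
        else:
            evals, evecs = np.linalg.eig(M)
            evals, evecs = evals.real, evecs.real
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        if self.reversible and (evals.max() > 1.0 + 1e-6 or evals.min() < -1.0 - 1e-6):
            raise RuntimeError(
                "tICA eigenvalues escaped [-1, 1]; the covariance estimate is ill-conditioned"
            )
        evals = np.clip(evals, -1.0, 1.0) if self.reversible else evals

        self.mean_ = mean
        self.eigenvalues_ = evals
        self.components_ = (W @ evecs).T
        with np.errstate(divide="ignore"):
            self.timescales_ = -lag / np.log(np.abs(evals))
        self.n_frames_ = n
        self.kept_indices_ = np.arange(len(evals))
        return self

    def transform(self, X):
        single = isinstance(X, (np.ndarray, FeatureTrajectory))
        trajs = _as_arrays(X)
        out = [(t - self.mean_) @ self.components_.T for t in trajs]
        return out[0] if single else out

    def timescales_ns(self, frame_interval: float) -> np.ndarray:
        return self.timescales_ * frame_interval

    def to_json_dict(self) -> dict:
        return {
            "lag": int(self.lag),
            "mean": self.mean_.tolist(),
            "eigenvalues": self.eigenvalues_.tolist(),
            "components": self.components_.tolist(),
            "kept_indices": [int(i) for i in self.kept_indices_],
        }


def estimate_tica(
    features: list[FeatureTrajectory],
    lag_ns: float,
    regularization: float = 1e-10,
) -> TICA:
    """Fit a reversible :class:`TICA` at a physical lag given in ns."""
    features = list(features) if not isinstance(features, FeatureTrajectory) else [features]
    interval = features[0].frame_interval
    lag_frames = max(1, int(round(lag_ns / interval)))
    model = TICA(lag=lag_frames, epsilon=regularization)
    model.fit(features)
    return model


def screen_components(
    model: TICA,
    projections,
    delta_bic: float = 10.0,
    max_points: int = 100_000,
    min_keep: int = 2,
) -> np.ndarray:
    """Keep components whose marginals are not single-Gaussian.

    For each component the pooled projection is fit with 1- and
    2-component Gaussian mixtures; the component is discarded when the
    single Gaussian wins by at least ``delta_bic`` (strong evidence).  The
    slowest ``min_keep`` components are always retained so a 2D landscape
    remains definable.  Mixture fits use an evenly strided subsample of at
    most ``max_points`` frames and are deterministic.

    Updates ``model.kept_indices_`` and returns it.
    """
    arrs = projections if isinstance(projections, list) else [projections]
    pooled = np.concatenate([np.atleast_2d(a.T).T for a in arrs], axis=0)
    n_comp = pooled.shape[1]
    if n_comp < 2:
        raise ValueError("screening requires at least 2 components")
    stride = max(1, len(pooled) // max_points)
    sample = pooled[::stride]

    kept = []
    for k in range(n_comp):
        x = sample[:, k : k + 1]
        bics = []
        for m in (1, 2):
            gm = GaussianMixture(
                n_components=m, covariance_type="full", random_state=0, n_init=1, max_iter=200
            ).fit(x)
            bics.append(gm.bic(x))
        if not (bics[0] - bics[1] < delta_bic):
            kept.append(k)  # multimodal: 2-mixture wins decisively enough
    # components are sorted slowest-first; never drop below the 2D floor
    kept = sorted(set(kept) | set(range(min_keep)))
    model.kept_indices_ = np.asarray(kept, dtype=int)
    return model.kept_indices_


def select_structured_components(
    projections,
    kurtosis_threshold: float = 0.1,
    min_keep: int = 2,
) -> np.ndarray:
    """Components whose marginals deviate from Gaussian: the clustering space.

    A component that only carries within-state (AR) noise has a Gaussian
    marginal (excess kurtosis ~ 0 at these sample sizes); components that
    separate metastable states are either multimodal (negative excess
    kurtosis) or carry rare-state satellites (strongly positive).  Keeping
    components with ``|excess kurtosis| > kurtosis_threshold`` therefore
    selects exactly the state-structured subspace, including separations
    of states too rare to register in a slow eigenvalue.  Falls back to
    the ``min_keep`` slowest components if nothing exceeds the threshold.
    """
    arrs = projections if isinstance(projections, list) else [projections]
    pooled = np.concatenate([np.atleast_2d(a.T).T for a in arrs], axis=0)
    x = pooled - pooled.mean(axis=0)
    m2 = (x**2).mean(axis=0)
    kurt = (x**4).mean(axis=0) / m2**2 - 3.0
    kept = np.flatnonzero(np.abs(kurt) > kurtosis_threshold)
    if len(kept) < min_keep:
        kept = np.arange(min_keep)
    return kept


def vamp2_score(data, lag: int, rank: int | None = None) -> float:
    """VAMP-2 score: sum of squared singular values of the propagator.

    Accepts either discrete trajectories (integer arrays; indicator
    features are implied) or continuous feature arrays.  The stationary
    process is included, so a one-state system scores exactly 1 and a
    two-state chain with second eigenvalue ``lambda`` scores
    ``1 + lambda**2`` at its lag.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    arrs = data if isinstance(data, list) else [data]
    arrs = [np.asarray(a) for a in arrs]
    if not any(len(a) > lag for a in arrs):
        raise ValueError("no transitions available at this lag")

    if np.issubdtype(arrs[0].dtype, np.integer):
        nstates = int(max(a.max() for a in arrs)) + 1
        joint = np.zeros((nstates, nstates))
        for a in arrs:
            if len(a) <= lag:
                continue
            np.add.at(joint, (a[:-lag], a[lag:]), 1.0)
        total = joint.sum()
        joint /= total
        p0 = joint.sum(axis=1)
        p1 = joint.sum(axis=0)
        nz0, nz1 = p0 > 0, p1 > 0
        K = (
            np.diag(1.0 / np.sqrt(p0[nz0]))
            @ joint[np.ix_(nz0, nz1)]
            @ np.diag(1.0 / np.sqrt(p1[nz1]))
        )
    else:
        dim = arrs[0].shape[1] if arrs[0].ndim > 1 else 1
        arrs = [a.reshape(len(a), -1) for a in arrs]
        n = 0
        s0 = np.zeros(dim)
        s1 = np.zeros(dim)
        for a in arrs:
            if len(a) <= lag:
                continue
            n += len(a) - lag
            s0 += a[:-lag].sum(axis=0)
            s1 += a[lag:].sum(axis=0)
        m0, m1 = s0 / n, s1 / n
        C00 = np.zeros((dim, dim))
        C11 = np.zeros((dim, dim))
        C01 = np.zeros((dim, dim))
        for a in arrs:
            if len(a) <= lag:
                continue
            h, t = a[:-lag] - m0, a[lag:] - m1
            C00 += h.T @ h
            C11 += t.T @ t
            C01 += h.T @ t
        C00 /= n
        C11 /= n
        C01 /= n

        def inv_sqrt(C):
            s, U = np.linalg.eigh(C)
            keep = s > 1e-12 * s.max()
            return U[:, keep] @ np.diag(1.0 / np.sqrt(s[keep])) @ U[:, keep].T

        K = inv_sqrt(C00) @ C01 @ inv_sqrt(C11)
        # mean-free features exclude the stationary singular function; add it back
        sv = np.linalg.svd(K, compute_uv=False)
        sv = np.concatenate([[1.0], sv])
        if rank is not None:
            if rank < 1:
                raise ValueError("rank must be >= 1")
            sv = sv[:rank]
        return float(np.sum(np.minimum(sv, 1.0) ** 2))

    sv = np.linalg.svd(K, compute_uv=False)
    if rank is not None:
        if rank < 1:
            raise ValueError("rank must be >= 1")
        sv = sv[:rank]
    return float(np.sum(np.minimum(sv, 1.0) ** 2))
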