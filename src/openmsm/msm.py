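"""Markov state model estimation and validation.

Transition counting (sliding or strided), reversible maximum-likelihood
estimation by the standard self-consistent fixed point on symmetric flow
variables, implied-timescale scans with a plateau rule for lag selection,
Chapman-Kolmogorov validation on metastable sets, and Bayesian sampling
of reversible transition matrices for uncertainty quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator


@dataclass
class CountMatrix:
    """Transition counts at a lag, with the largest connected active set."""

    counts: np.ndarray
    lag: int
    mode: str
    active_set: np.ndarray

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]

    def active_counts(self) -> np.ndarray:
        return self.counts[np.ix_(self.active_set, self.active_set)]


@dataclass
class TransitionModel:
    """Row-stochastic reversible transition matrix over the active set."""

    transition_matrix: np.ndarray
    stationary: np.ndarray
    lag: int
    active_set: np.ndarray
    frame_interval: float = 1.0

    @property
    def eigenvalues(self) -> np.ndarray:
        ev = np.linalg.eigvals(self.transition_matrix).real
        return np.sort(ev)[::-1]

    def timescales(self, n: int | None = None) -> np.ndarray:
        """Implied timescales in frames for eigenvalues in (0, 1)."""
        ev = self.eigenvalues[1:]
        ev = ev[(ev > 0) & (ev < 1.0 - 1e-12)]
        ts = -self.lag / np.log(ev)
        return ts[:n] if n is not None else ts


def count_transitions(dtrajs, lag: int, mode: str = "sliding") -> CountMatrix:
    """Count (t, t+lag) microstate transitions over all trajectories.

    ``sliding`` counts every window; ``strided`` counts non-overlapping
    windows only.  The active set is the largest strongly connected
    component of the directed count graph (largest by state count, ties by
    total counts).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    if mode not in ("sliding", "strided"):
        raise ValueError("mode must be 'sliding' or 'strided'")
    dtrajs = [np.asarray(d, dtype=int) for d in (dtrajs if isinstance(dtrajs, list) else [dtrajs])]
    if not any(len(d) > lag for d in dtrajs):
        raise ValueError("every trajectory is shorter than the lag")
    n = int(max(d.max() for d in dtrajs if len(d))) + 1
    C = np.zeros((n, n))
    for d in dtrajs:
        if len(d) <= lag:
            continue
        if mode == "sliding":
            a, b = d[:-lag], d[lag:]
        else:
            # pairs at multiples of the lag; at lag 1 this equals sliding
            a = d[0 : len(d) - lag : lag]
            b = d[lag :: lag][: len(a)]
        np.add.at(C, (a, b), 1.0)
    graph = csr_matrix(C > 0)
    n_comp, assignment = connected_components(graph, directed=True, connection="strong")
    best, best_key = None, None
    for comp in range(n_comp):
        members = np.flatnonzero(assignment == comp)
        key = (len(members), C[np.ix_(members, members)].sum())
        if best_key is None or key > best_key:
            best, best_key = members, key
    return CountMatrix(counts=C, lag=lag, mode=mode, active_set=np.sort(best))


def mle_reversible(
    counts: CountMatrix | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    frame_interval: float = 1.0,
) -> TransitionModel:
    """Reversible maximum-likelihood transition matrix.

    Maximizes ``sum_ij c_ij log T_ij`` over row-stochastic matrices with
    detailed balance, using the classical fixed-point update on symmetric
    flows ``x_ij``:

        ``x_ij <- (c_ij + c_ji) / (c_i / x_i + c_j / x_j)``

    Convergence is declared when the largest element change of the
    normalized flow matrix falls below ``tol``.
    """
    if isinstance(counts, CountMatrix):
        active = counts.active_set
        C = counts.active_counts()
        lag = counts.lag
    else:
        C = np.asarray(counts, dtype=float)
        active = np.arange(C.shape[0])
        lag = 1
    if C.shape[0] == 0:
        raise ValueError("empty active set")
    Csym = C + C.T
    x = Csym / max(Csym.sum(), 1.0)
    mask = Csym > 0
    c_row = C.sum(axis=1)
    for it in range(max_iter):
        x_row = x.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(x_row > 0, c_row / x_row, 0.0)
        denom = q[:, None] + q[None, :]
        x_new = np.where(mask & (denom > 0), Csym / np.where(denom > 0, denom, 1.0), 0.0)
        x_new /= x_new.sum()
        delta = np.abs(x_new - x).max()
        x = x_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"reversible MLE did not converge in {max_iter} iterations (residual {delta:.2e})"
        )
    x_row = x.sum(axis=1)
    T = x / x_row[:, None]
    pi = x_row / x_row.sum()
    return TransitionModel(
        transition_matrix=T, stationary=pi, lag=lag, active_set=active,
        frame_interval=frame_interval,
    )


class MarkovStateModel(BaseEstimator):
    """Reversible MSM estimator with a scikit-learn interface.

    ``fit`` takes a list of integer microstate trajectories; fitted
    attributes carry the underscore convention.  ``frame_interval`` (ns)
    only affects unit conversions, never the estimate.
    """

    def __init__(self, lag: int = 1, count_mode: str = "sliding",
                 tol: float = 1e-10, max_iter: int = 100_000, frame_interval: float = 1.0):
        self.lag = lag
        self.count_mode = count_mode
        self.tol = tol
        self.max_iter = max_iter
        self.frame_interval = frame_interval

    def fit(self, dtrajs, y=None):
        cm = count_transitions(dtrajs, lag=int(self.lag), mode=self.count_mode)
        model = mle_reversible(cm, tol=self.tol, max_iter=self.max_iter,
                               frame_interval=self.frame_interval)
        self.count_matrix_ = cm
        self.transition_matrix_ = model.transition_matrix
        self.stationary_distribution_ = model.stationary
        self.active_set_ = cm.active_set
        self.eigenvalues_ = model.eigenvalues
        self.model_ = model
        return self

    def timescales(self, n: int | None = None) -> np.ndarray:
        return self.model_.timescales(n)

    @property
    def lag_ns(self) -> float:
        return self.lag * self.frame_interval


@dataclass
class ImpliedTimescales:
    """Implied-timescale scan: one row of timescales per lag (frames)."""

    lags: np.ndarray
    timescales: np.ndarray  # (n_lags, n_timescales), NaN where missing
    failed_lags: list = field(default_factory=list)

    def plateau_lag(self, rtol: float = 0.10) -> int | None:
        """First lag whose timescales all change < ``rtol`` vs the next lag."""
        for i in range(len(self.lags) - 1):
            a, b = self.timescales[i], self.timescales[i + 1]
            ok = np.isfinite(a) & np.isfinite(b)
            if not ok.any():
                continue
            if np.all(np.abs(b[ok] - a[ok]) / np.abs(a[ok]) < rtol):
                return int(self.lags[i])
        return None


def implied_timescales(dtrajs, lags, n_timescales: int = 3) -> ImpliedTimescales:
    """Reversible implied timescales ``-lag / ln(lambda_i)`` per lag.

    A lag with disconnected counts is reported as missing rather than
    fatal; eigenvalues outside (0, 1) yield NaN (or inf when lambda -> 1).
    """
    lags = np.asarray(sorted(int(l) for l in lags))
    out = np.full((len(lags), n_timescales), np.nan)
    failed = []
    for i, lag in enumerate(lags):
        try:
            model = mle_reversible(count_transitions(dtrajs, lag=lag))
            ev = model.eigenvalues[1 : n_timescales + 1]
            for j, lam in enumerate(ev):
                if lam >= 1.0 - 1e-12:
                    out[i, j] = np.inf
                elif lam > 0:
                    out[i, j] = -lag / np.log(lam)
        except (ValueError, RuntimeError):
            failed.append(int(lag))
    return ImpliedTimescales(lags=lags, timescales=out, failed_lags=failed)


def _set_probabilities(T: np.ndarray, pi: np.ndarray, sets: list[np.ndarray]) -> np.ndarray:
    """Stationary-weighted set-to-set transition probabilities."""
    m = len(sets)
    P = np.zeros((m, m))
    for a, A in enumerate(sets):
        wa = pi[A]
        for b, B in enumerate(sets):
            P[a, b] = (wa[:, None] * T[np.ix_(A, B)]).sum() / wa.sum()
    return P


@dataclass
class CKResult:
    """Chapman-Kolmogorov test output: predicted vs estimated per factor."""

    factors: np.ndarray
    predicted: np.ndarray  # (n_factors, m, m)
    estimated: np.ndarray
    estimated_std: np.ndarray | None = None

    def max_deviation(self) -> float:
        return float(np.nanmax(np.abs(self.predicted - self.estimated)))


def ck_test(
    model: TransitionModel,
    dtrajs,
    sets_or_crisp,
    factors=(1, 2, 3, 4, 5),
    n_bayes_samples: int = 0,
    seed: int = 0,
) -> CKResult:
    """Chapman-Kolmogorov test on metastable sets.

    Compares the set-to-set transition probabilities predicted by powering
    the lag-``tau`` model, ``T(tau)^k``, against models re-estimated
    directly at lag ``k tau``.  ``sets_or_crisp`` is either a list of
    microstate index arrays or a crisp microstate -> macrostate map over
    the model's active set.  Optional Bayesian re-sampling at each test
    lag provides standard deviations for the estimated probabilities.
    """
    crisp = np.asarray(sets_or_crisp)
    if crisp.ndim == 1 and len(crisp) == len(model.active_set):
        sets_local = [np.flatnonzero(crisp == a) for a in np.unique(crisp)]
    else:
        # global microstate index sets -> positions within the active set
        pos = {s: i for i, s in enumerate(model.active_set)}
        sets_local = [
            np.asarray([pos[s] for s in S if s in pos], dtype=int) for S in sets_or_crisp
        ]
    sets_local = [S for S in sets_local if len(S)]
    m = len(sets_local)
    factors = np.asarray(sorted(int(k) for k in factors))
    predicted = np.full((len(factors), m, m), np.nan)
    estimated = np.full((len(factors), m, m), np.nan)
    est_std = np.full((len(factors), m, m), np.nan) if n_bayes_samples else None

    sets_global = [model.active_set[S] for S in sets_local]
    for i, k in enumerate(factors):
        Tk = np.linalg.matrix_power(model.transition_matrix, k)
        predicted[i] = _set_probabilities(Tk, model.stationary, sets_local)
        try:
            cm = count_transitions(dtrajs, lag=int(k * model.lag))
            direct = mle_reversible(cm)
        except (ValueError, RuntimeError):
            continue
        pos = {s: j for j, s in enumerate(cm.active_set)}
        sets_direct = [
            np.asarray([pos[s] for s in S if s in pos], dtype=int) for S in sets_global
        ]
        if any(len(S) == 0 for S in sets_direct):
            continue
        estimated[i] = _set_probabilities(direct.transition_matrix, direct.stationary, sets_direct)
        if n_bayes_samples:
            ens = bayesian_ensemble(cm, n_samples=n_bayes_samples, seed=seed + int(k))
            vals = np.array(
                [_set_probabilities(s.transition_matrix, s.stationary, sets_direct)
                 for s in ens.samples]
            )
            est_std[i] = vals.std(axis=0)
    return CKResult(factors=factors, predicted=predicted, estimated=estimated,
                    estimated_std=est_std)


@dataclass
class BayesianEnsemble:
    """Posterior samples of reversible transition models."""

    samples: list
    seed: int
    acceptance_rate: float
    lag: int = 1
    frame_interval: float = 1.0

    def __len__(self) -> int:
        return len(self.samples)


def bayesian_ensemble(
    counts: CountMatrix | np.ndarray,
    n_samples: int = 100,
    seed: int = 0,
    burn_in_sweeps: int = 1000,
    thin_sweeps: int = 10,
    step: float = 0.2,
    frame_interval: float = 1.0,
) -> BayesianEnsemble:
    """Sample reversible transition matrices consistent with the counts.

    Metropolis-within-Gibbs over the symmetric flow parameters ``x_ij``
    with log-scale random-walk proposals (log-uniform flow prior): the
    likelihood ``prod_ij (x_ij / x_i)^{c_ij}`` is scale-invariant, so the
    chain moves on the reversible simplex.  Sliding counts are rescaled by
    ``1 / lag`` to correct for overlapping-window overcounting before
    sampling.  Deterministic under the seed; the default 100 samples match
    the error analysis protocol of the original study.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    if isinstance(counts, CountMatrix):
        C = counts.active_counts().astype(float)
        active = counts.active_set
        lag = counts.lag
        if counts.mode == "sliding" and lag > 1:
            C = C / lag
    else:
        C = np.asarray(counts, dtype=float)
        active = np.arange(C.shape[0])
        lag = 1
    n = C.shape[0]
    rng = np.random.default_rng(seed)

    start = mle_reversible(C)
    x = start.stationary[:, None] * start.transition_matrix
    x = 0.5 * (x + x.T)
    free = [(i, j) for i in range(n) for j in range(i, n) if C[i, j] + C[j, i] > 0 or i == j]
    free = [(i, j) for (i, j) in free if x[i, j] > 0]
    c_row = C.sum(axis=1)
    x_row = x.sum(axis=1)

    accepted = 0
    proposed = 0

    def sweep():
        nonlocal accepted, proposed
        deltas = rng.normal(scale=step, size=len(free))
        logu = np.log(rng.random(len(free)))
        for idx, (i, j) in enumerate(free):
            old = x[i, j]
            new = old * np.exp(deltas[idx])
            d = new - old
            if i == j:
                new_row_i = x_row[i] + d
                dlog = C[i, i] * np.log(new / old) - c_row[i] * np.log(new_row_i / x_row[i])
            else:
                new_row_i = x_row[i] + d
                new_row_j = x_row[j] + d
                dlog = (C[i, j] + C[j, i]) * np.log(new / old)
                dlog -= c_row[i] * np.log(new_row_i / x_row[i])
                dlog -= c_row[j] * np.log(new_row_j / x_row[j])
            proposed += 1
            if logu[idx] < dlog:
                accepted += 1
                x[i, j] = new
                x_row[i] = x_row[i] + d
                if i != j:
                    x[j, i] = new
                    x_row[j] = x_row[j] + d

    for _ in range(burn_in_sweeps):
        sweep()
    samples = []
    while len(samples) < n_samples:
        for _ in range(thin_sweeps):
            sweep()
        T = x / x_row[:, None]
        pi = x_row / x_row.sum()
        samples.append(
            TransitionModel(transition_matrix=T.copy(), stationary=pi.copy(), lag=lag,
                            active_set=active, frame_interval=frame_interval)
        )
    rate = accepted / max(proposed, 1)
    ens = BayesianEnsemble(samples=samples, seed=seed, acceptance_rate=rate, lag=lag,
                           frame_interval=frame_interval)
    if not 0.05 <= rate <= 0.95:
        import warnings

        warnings.warn(
            f"Bayesian sampler acceptance rate {rate:.3f} outside [0.05, 0.95]; "
            "posterior may be poorly mixed",
            RuntimeWarning,
            stacklevel=2,
        )
    return ens
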