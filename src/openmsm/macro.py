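"""PCCA+ coarse-graining, macrostate populations, MFPTs and uncertainties.

PCCA+ clusters the microstates of a reversible transition matrix into
metastable sets by finding, in the space spanned by the dominant right
eigenvectors, the linear transform that maps the sampled data onto a
probability simplex: the simplex vertices are identified greedily (inner
simplex algorithm) and the transform is then refined, subject to the
feasibility constraints (non-negative memberships, rows summing to one),
to maximize the crispness of the assignment.

Macrostate populations are stationary-weighted sums over the crisp
microstate assignment; mean first-passage times come from the exact
linear solve on the microstate matrix with stationary-weighted source
averaging; uncertainties are sample statistics over a Bayesian ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .msm import BayesianEnsemble, TransitionModel


def _dominant_eigenvectors(T: np.ndarray, pi: np.ndarray, m: int) -> np.ndarray:
    """Top-m right eigenvectors of a reversible T, via the symmetric form."""
    sqrt_pi = np.sqrt(pi)
    S = sqrt_pi[:, None] * T / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1][:m]
    X = evecs[:, order] / sqrt_pi[:, None]
    # normalize: first column constant 1
    X[:, 0] = 1.0
    return X


def _fill_A(A: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Project a candidate transform onto the feasible set.

    Rows 1..m-1 are centered so memberships sum to one per microstate;
    row 0 is raised so every membership is non-negative; finally the whole
    transform is rescaled so the row sums equal one exactly.
    """
    A = A.copy()
    m = A.shape[0]
    if m > 1:
        A[1:] -= A[1:].mean(axis=1, keepdims=True)
        A[0] = -np.min(X[:, 1:] @ A[1:], axis=0)
    total = A[0].sum()
    if total <= 0:
        raise ValueError("degenerate PCCA+ transform")
    return A / total


def pcca_plus(
    model: TransitionModel | np.ndarray,
    n_macro: int,
    pi: np.ndarray | None = None,
    optimize_crispness: bool = True,
) -> np.ndarray:
    """Fuzzy memberships (microstates x macrostates) by PCCA+.

    Requires the ``n_macro`` dominant eigenvalues of the (reversible)
    transition matrix to be real; raises otherwise.  Memberships are
    row-stochastic and non-negative; for an exactly block-diagonal matrix
    they are 0/1 indicators of the blocks.
    """
    if isinstance(model, TransitionModel):
        T, pi = model.transition_matrix, model.stationary
    else:
        T = np.asarray(model, dtype=float)
        if pi is None:
            evals, evecs = np.linalg.eig(T.T)
            k = np.argmin(np.abs(evals - 1.0))
            pi = np.abs(evecs[:, k].real)
            pi /= pi.sum()
    n = T.shape[0]
    if n_macro < 1 or n_macro > n:
        raise ValueError("n_macro must be in [1, n_microstates]")
    if n_macro == 1:
        return np.ones((n, 1))
    evals = np.linalg.eigvals(T)
    top = evals[np.argsort(-np.abs(evals))][:n_macro]
    if np.any(np.abs(top.imag) > 1e-8):
        raise ValueError("complex dominant eigenvalues; input is not reversible")

    if pi.min() > 1e-12:
        X = _dominant_eigenvectors(T, pi, n_macro)
    else:
        # disconnected input (e.g. exactly block-diagonal): the stationary
        # vector is not unique, so take the dominant right eigenvectors
        # directly and weight crispness uniformly
        ev, evec = np.linalg.eig(T)
        order = np.argsort(-ev.real)[:n_macro]
        if np.any(np.abs(ev[order].imag) > 1e-8):
            raise ValueError("complex dominant eigenvalues; input is not reversible")
        X = evec[:, order].real
        X[:, 0] = 1.0
        pi = np.full(n, 1.0 / n)

    # inner simplex algorithm: greedy vertex identification
    ortho = X.copy()
    idx = np.zeros(n_macro, dtype=int)
    norms = np.linalg.norm(ortho, axis=1)
    idx[0] = int(np.argmax(norms))
    ortho -= ortho[idx[0]]
    for k in range(1, n_macro):
        norms = np.linalg.norm(ortho, axis=1)
        idx[k] = int(np.argmax(norms))
        v = ortho[idx[k]]
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            raise ValueError(f"n_macro={n_macro} exceeds the numerical rank of the slow subspace")
        v = v / nv
        ortho -= np.outer(ortho @ v, v)

    A = np.linalg.inv(X[idx])
    A = _fill_A(A, X)

    def finalize(B):
        chi = np.clip(X @ B, 0.0, None)
        return chi / chi.sum(axis=1, keepdims=True)

    if optimize_crispness and n_macro > 1:
        # maximize stationary-weighted crispness sum_i pi_i sum_j chi_ij^2
        shape = (n_macro - 1, n_macro)

        def neg_crispness(flat):
            B = A.copy()
            B[1:] = flat.reshape(shape)
            try:
                B = _fill_A(B, X)
            except ValueError:
                return 1e3
            chi = X @ B
            if chi.min() < -1e-9:
                return 1e3
            return -float(pi @ (chi**2).sum(axis=1))

        res = optimize.minimize(
            neg_crispness, A[1:].ravel(), method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if res.fun < neg_crispness(A[1:].ravel()):
            B = A.copy()
            B[1:] = res.x.reshape(shape)
            B = _fill_A(B, X)
            # accept the refinement only if every macrostate keeps at
            # least one microstate under crisp assignment: a pure
            # crispness objective can otherwise sacrifice rare states
            chi_ref = finalize(B)
            crisp_ref = np.argmax(chi_ref, axis=1)
            if len(np.unique(crisp_ref)) == n_macro:
                return chi_ref

    return finalize(A)


def crisp_assignment(memberships: np.ndarray) -> np.ndarray:
    """Crisp microstate -> macrostate map: argmax membership, ties low."""
    return np.argmax(memberships, axis=1)


def macro_populations(model: TransitionModel, crisp_map: np.ndarray) -> np.ndarray:
    """Stationary-weighted macrostate populations (sums to 1)."""
    crisp_map = np.asarray(crisp_map)
    if len(crisp_map) != len(model.stationary):
        raise ValueError("crisp map must cover the active set")
    n_macro = int(crisp_map.max()) + 1
    pops = np.zeros(n_macro)
    np.add.at(pops, crisp_map, model.stationary)
    return pops


def frame_fraction_populations(macro_labels, n_macro: int) -> np.ndarray:
    """Raw frame-fraction macrostate populations.

    Alternative to the stationary-weighted convention: the fraction of
    (labelled) frames in each macrostate.  Frames labelled ``-1`` (outside
    the active set) are excluded.
    """
    lab = np.concatenate(
        [np.asarray(l) for l in (macro_labels if isinstance(macro_labels, list) else [macro_labels])]
    )
    lab = lab[lab >= 0]
    counts = np.bincount(lab, minlength=n_macro).astype(float)
    if counts.sum() == 0:
        raise ValueError("no labelled frames")
    return counts / counts.sum()


def mfpt(
    model: TransitionModel,
    source: int,
    target: int,
    crisp_map: np.ndarray,
) -> float:
    """Mean first-passage time between macrostates, in microseconds.

    Exact linear solve on the microstate matrix: with the target
    microstates absorbing, ``(I - T_restricted) m = lag * 1``; the source
    value is the stationary-weighted average of ``m`` over the source
    microstates.  Physical units come from the model's lag (frames) and
    frame interval (ns).
    """
    if source == target:
        raise ValueError("source and target macrostates must differ")
    crisp_map = np.asarray(crisp_map)
    src = np.flatnonzero(crisp_map == source)
    tgt = np.flatnonzero(crisp_map == target)
    if len(src) == 0 or len(tgt) == 0:
        raise ValueError("empty source or target macrostate")
    T, pi = model.transition_matrix, model.stationary
    n = T.shape[0]
    keep = np.setdiff1d(np.arange(n), tgt)
    A = np.eye(len(keep)) - T[np.ix_(keep, keep)]
    try:
        m = np.linalg.solve(A, np.full(len(keep), float(model.lag)))
    except np.linalg.LinAlgError:
        return np.inf
    m_full = np.zeros(n)
    m_full[keep] = m
    w = pi[src]
    frames = float(np.average(m_full[src], weights=w))
    return frames * model.frame_interval * 1e-3  # ns -> us


def mfpt_matrix(model: TransitionModel, crisp_map: np.ndarray) -> np.ndarray:
    """All-pairs macrostate MFPT matrix in microseconds (zero diagonal)."""
    n_macro = int(np.max(crisp_map)) + 1
    M = np.zeros((n_macro, n_macro))
    for a in range(n_macro):
        for b in range(n_macro):
            if a != b:
                M[a, b] = mfpt(model, a, b, crisp_map)
    return M


def uncertainty(
    ensemble: BayesianEnsemble,
    crisp_map: np.ndarray,
    observable: str = "population",
) -> tuple[np.ndarray, np.ndarray, int]:
    """Posterior mean and standard deviation of a macro observable.

    The crisp map is held fixed across samples.  Samples for which the
    observable is undefined (unreachable target) are excluded and counted;
    returns ``(mean, std, n_excluded)``.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    values = []
    excluded = 0
    for s in ensemble.samples:
        if observable == "population":
            values.append(macro_populations(s, crisp_map))
        elif observable == "mfpt":
            M = mfpt_matrix(s, crisp_map)
            if not np.all(np.isfinite(M)):
                excluded += 1
                continue
            values.append(M)
        else:
            raise ValueError("observable must be 'population' or 'mfpt'")
    arr = np.asarray(values)
    return arr.mean(axis=0), arr.std(axis=0), excluded


@dataclass
class MacroModel:
    """Coarse-grained model: memberships, populations, MFPTs, ordering.

    ``state_order`` lists macrostate indices sorted by ascending mean
    openness (the accessibility observable), the rule that names the
    states Closed < Ic < Io < Eo.
    """

    n_macro: int
    memberships: np.ndarray
    crisp_map: np.ndarray
    macro_stationary: np.ndarray
    mfpt_matrix_us: np.ndarray
    state_order: np.ndarray
    population_std: np.ndarray | None = None
    mfpt_std_us: np.ndarray | None = None

    def ordered_populations(self) -> np.ndarray:
        return self.macro_stationary[self.state_order]

    def ordered_mfpt_matrix(self) -> np.ndarray:
        return self.mfpt_matrix_us[np.ix_(self.state_order, self.state_order)]

    def to_json_dict(self) -> dict:
        d = {
            "n_macro": int(self.n_macro),
            "state_order": [int(i) for i in self.state_order],
            "populations_pct": (100.0 * self.ordered_populations()).tolist(),
            "mfpt_matrix_us": self.ordered_mfpt_matrix().tolist(),
        }
        if self.population_std is not None:
            d["populations_pct_std"] = (100.0 * self.population_std[self.state_order]).tolist()
        if self.mfpt_std_us is not None:
            d["mfpt_matrix_us_std"] = self.mfpt_std_us[
                np.ix_(self.state_order, self.state_order)
            ].tolist()
        return d


def build_macro_model(
    model: TransitionModel,
    n_macro: int,
    openness_by_micro: np.ndarray,
    ensemble: BayesianEnsemble | None = None,
) -> MacroModel:
    """PCCA+ plus bookkeeping: populations, MFPTs and openness ordering.

    ``openness_by_micro`` is the mean openness observable per microstate
    of the active set (e.g. catalytic-site accessibility); macrostates are
    ordered by its population-weighted macro mean.
    """
    chi = pcca_plus(model, n_macro)
    crisp = crisp_assignment(chi)
    pops = macro_populations(model, crisp)
    M = mfpt_matrix(model, crisp)
    openness = np.zeros(n_macro)
    for a in range(n_macro):
        sel = crisp == a
        w = model.stationary[sel]
        openness[a] = np.average(openness_by_micro[sel], weights=w) if sel.any() else np.inf
    order = np.argsort(openness, kind="stable")
    pop_std = mfpt_std = None
    if ensemble is not None and len(ensemble):
        pop_mean, pop_std, _ = uncertainty(ensemble, crisp, "population")
        _, mfpt_std, _ = uncertainty(ensemble, crisp, "mfpt")
    return MacroModel(
        n_macro=n_macro,
        memberships=chi,
        crisp_map=crisp,
        macro_stationary=pops,
        mfpt_matrix_us=M,
        state_order=order,
        population_std=pop_std,
        mfpt_std_us=mfpt_std,
    )
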