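"""Synthetic dynamics and structure fixtures.

Three families of test inputs are generated here:

* :class:`KineticFixture` / :func:`simulate_latent` -- a reversible
  four-macrostate jump process (Closed, Ic, Io, Eo) with state-conditioned
  Gaussian feature emissions.  The stationary distribution encodes the
  macrostate populations measured for the sheddase opening equilibrium in
  pure POPC and in 7:3 POPC:POPS membranes, and the exchange rates are
  fitted so that the exact mean first-passage times reproduce the reported
  microsecond-scale kinetics.  One emission dimension is the catalytic-site
  accessibility observable (Angstrom), strictly increasing with openness.
* :class:`ToyLandscape` / :func:`simulate_brownian` -- overdamped Brownian
  dynamics on a 2D multi-well potential, the stand-in propagator for the
  adaptive-sampling loop.
* :class:`ToyComplexSpec` / :func:`build_toy_complex` -- labelled
  pseudo-atom coordinate frames (protein domains, lipid molecules, Fab
  body, membrane slab) for the structural-observable operations.

Every stochastic operation takes an explicit integer seed; there is no
module-level random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

MACROSTATE_NAMES = ("Closed", "Ic", "Io", "Eo")

# Stationary macrostate populations (percent) for the two membrane systems.
# POPS percentages sum to 99.8 and are renormalised to 1 when used.
_POPULATIONS_PCT = {
    "popc": np.array([19.9, 19.5, 53.2, 7.3]),
    "pops": np.array([0.5, 0.3, 39.8, 59.2]),
}

# Frame interval (ns) at time_scale == 1, chosen so the slowest fixture
# relaxation is a few hundred frames at most while every macro process
# stays well above the AR(1) emission correlation time (see docs/methods.md).
_FRAME_INTERVAL_NS = {"popc": 25.0, "pops": 5.0}

# Directed MFPT anchors in microseconds.  POPC: the three compact states
# exchange within ~3 us and reach Eo in ~20 us.  POPS: Io and Eo exchange
# well below the 0.5 us bound (anchored at 0.25 us), forward transitions
# out of the rare compact states are fast (0.1-1 us) and returns are slow
# (tens to hundreds of us).  Entries carry least-squares weights; the
# populations are held exact and the MFPTs are fitted in log space.
_MFPT_TARGETS_US = {
    "popc": [
        (0, 1, 2.5, 1.0), (1, 0, 2.5, 1.0),
        (0, 2, 2.5, 1.0), (2, 0, 2.5, 1.0),
        (1, 2, 2.5, 1.0), (2, 1, 2.5, 1.0),
        (0, 3, 20.0, 5.0), (1, 3, 20.0, 5.0), (2, 3, 20.0, 5.0),
    ],
    "pops": [
        (2, 3, 0.25, 5.0), (3, 2, 0.25, 5.0),
        (0, 2, 0.1, 2.0), (1, 2, 1.0, 1.0),
        (2, 0, 20.0, 1.0), (3, 0, 20.0, 1.0),
        (2, 1, 300.0, 1.0), (3, 1, 300.0, 1.0),
    ],
}

# State-conditioned emission means (Angstrom).  Row order follows
# MACROSTATE_NAMES; column 0 is the catalytic-site accessibility
# observable with the reported per-state centers, the remaining columns
# are interface-distance style features that open progressively and keep
# all four states pairwise separable (POPS Closed and Ic share the same
# accessibility center, so the interface features carry their separation).
_EMISSION_MEANS = {
    "popc": np.array(
        [
            [20.0, 30.0, 25.0, 35.0, 28.0],
            [27.5, 42.0, 33.0, 44.0, 38.0],
            [65.0, 60.0, 52.0, 58.0, 50.0],
            [100.0, 88.0, 70.0, 80.0, 66.0],
        ]
    ),
    "pops": np.array(
        [
            [20.0, 30.0, 25.0, 35.0, 28.0],
            [20.0, 44.0, 34.0, 45.0, 39.0],
            [50.0, 60.0, 52.0, 57.0, 50.0],
            [75.0, 86.0, 68.0, 78.0, 64.0],
        ]
    ),
}

#: Column of the emission matrix holding the accessibility observable.
ACCESSIBILITY_DIM = 0

_EMISSION_SD_FACTOR = 0.15
_DEFAULT_AR_COEFFICIENT = 0.9


@dataclass
class KineticFixture:
    """Ground-truth reversible macrostate chain with Gaussian emissions.

    ``transition_matrix`` is row-stochastic at the declared
    ``frame_interval`` (ns); ``stationary`` is its exact stationary
    distribution and satisfies detailed balance.  ``emission_means`` /
    ``emission_sds`` are (n_states, n_features) arrays in Angstrom; the
    accessibility observable lives in column ``accessibility_dim`` and its
    means increase strictly with openness.
    """

    name: str
    state_names: tuple
    transition_matrix: np.ndarray
    stationary: np.ndarray
    frame_interval: float
    emission_means: np.ndarray
    emission_sds: np.ndarray
    ar_coefficient: float = _DEFAULT_AR_COEFFICIENT
    accessibility_dim: int = ACCESSIBILITY_DIM
    mfpt_fit_residual: float = 0.0

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.emission_means.shape[1]

    def mfpt_matrix_us(self) -> np.ndarray:
        """Exact macrostate MFPT matrix in microseconds (linear solve)."""
        frames = mfpt_matrix_frames(self.transition_matrix)
        return frames * self.frame_interval * 1e-3

    def implied_timescales_frames(self) -> np.ndarray:
        """Relaxation timescales -1/ln(lambda_i) of the macro chain, in frames."""
        evals = np.sort(np.linalg.eigvals(self.transition_matrix).real)[::-1]
        lam = evals[1:]
        lam = lam[(lam > 0) & (lam < 1)]
        return -1.0 / np.log(lam)

    def to_json_dict(self) -> dict:
        return {
            "name": self.name,
            "state_names": list(self.state_names),
            "transition_matrix": self.transition_matrix.tolist(),
            "stationary": self.stationary.tolist(),
            "frame_interval_ns": self.frame_interval,
            "emission_means": self.emission_means.tolist(),
            "emission_sds": self.emission_sds.tolist(),
            "ar_coefficient": self.ar_coefficient,
            "accessibility_dim": self.accessibility_dim,
        }


@dataclass
class LatentTrajectory:
    """A simulated feature trajectory with its hidden macrostate labels."""

    macrostate_labels: np.ndarray
    features: np.ndarray
    frame_interval: float
    seed: int

    def __post_init__(self):
        if len(self.macrostate_labels) != len(self.features):
            raise ValueError("labels and features must have equal frame counts")


def mfpt_frames(transition_matrix: np.ndarray, source: int, target: int) -> float:
    """Exact mean first-passage time ``source -> target`` in frame units.

    Solves ``(I - T_restricted) m = 1`` over the non-target states.
    """
    T = np.asarray(transition_matrix, dtype=float)
    n = T.shape[0]
    if source == target:
        return 0.0
    keep = [i for i in range(n) if i != target]
    A = np.eye(n - 1) - T[np.ix_(keep, keep)]
    m = np.linalg.solve(A, np.ones(n - 1))
    return float(m[keep.index(source)])


def mfpt_matrix_frames(transition_matrix: np.ndarray) -> np.ndarray:
    """All-pairs MFPT matrix (frames); diagonal zero."""
    T = np.asarray(transition_matrix, dtype=float)
    n = T.shape[0]
    out = np.zeros((n, n))
    for target in range(n):
        keep = [i for i in range(n) if i != target]
        A = np.eye(n - 1) - T[np.ix_(keep, keep)]
        m = np.linalg.solve(A, np.ones(n - 1))
        for row, i in enumerate(keep):
            out[i, target] = m[row]
    return out


def _chain_from_flows(flows: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Row-stochastic reversible chain from symmetric off-diagonal flows.

    ``T_ij = K_ij / pi_i`` for i != j with the diagonal absorbing the
    remainder; stationarity at ``pi`` and detailed balance hold exactly by
    construction provided all diagonals stay non-negative.
    """
    n = len(pi)
    T = flows / pi[:, None]
    np.fill_diagonal(T, 0.0)
    np.fill_diagonal(T, 1.0 - T.sum(axis=1))
    return T


def _fit_reversible_chain(pi: np.ndarray, targets_frames) -> tuple[np.ndarray, float]:
    """Fit symmetric exchange flows so exact MFPTs match the anchors.

    Populations are held exact; the (weighted, log-space) MFPT residual is
    minimised over the 6 free flows of the 4-state reversible chain.
    """
    n = len(pi)
    iu = np.triu_indices(n, k=1)

    def unpack(log_k):
        K = np.zeros((n, n))
        K[iu] = np.exp(log_k)
        K += K.T
        return K

    def residuals(log_k):
        K = unpack(log_k)
        T = _chain_from_flows(K, pi)
        res = []
        # soft barrier keeping every diagonal comfortably positive
        diag = np.diag(T)
        res.extend(np.maximum(0.0, 0.05 - diag) * 1e3)
        M = mfpt_matrix_frames(T) if np.all(diag > 0) else None
        for i, j, tgt, w in targets_frames:
            if M is None:
                res.append(10.0 * w)
            else:
                res.append(w * np.log(max(M[i, j], 1e-12) / tgt))
        return np.asarray(res)

    # crude two-state initial guess for each flow
    k0 = np.zeros(len(iu[0]))
    mean_target = np.exp(np.mean([np.log(t) for _, _, t, _ in targets_frames]))
    for idx, (i, j) in enumerate(zip(*iu)):
        t_ij = next((t for a, b, t, _ in targets_frames if (a, b) == (i, j)), mean_target)
        k0[idx] = np.log(max(min(pi[i], pi[j]) / t_ij, 1e-12))
    sol = optimize.least_squares(residuals, k0, method="lm", max_nfev=20000)
    K = unpack(sol.x)
    T = _chain_from_flows(K, pi)
    mfpt_res = residuals(sol.x)[n:]
    return T, float(np.sqrt(np.mean(mfpt_res**2)))


@lru_cache(maxsize=None)
def _fitted_chain(name: str) -> tuple:
    pct = _POPULATIONS_PCT[name]
    pi = pct / pct.sum()
    interval = _FRAME_INTERVAL_NS[name]
    targets = [
        (i, j, us * 1e3 / interval, w) for i, j, us, w in _MFPT_TARGETS_US[name]
    ]
    T, residual = _fit_reversible_chain(pi, targets)
    T.setflags(write=False)
    pi.setflags(write=False)
    return T, pi, residual


def build_fixture(name: str, time_scale: float = 1.0) -> KineticFixture:
    """Construct the ground-truth kinetic fixture for a membrane system.

    Parameters
    ----------
    name
        ``"popc"`` (pure POPC membrane) or ``"pops"`` (7:3 POPC:POPS).
    time_scale
        Multiplies the physical frame interval, and hence every MFPT, by
        this factor.  The per-frame transition probabilities are invariant,
        so the chain itself does not change.

    The stationary vector equals the reported macrostate percentages
    (POPS renormalised from a 99.8% total); exchange flows are the cached
    least-squares fit to the MFPT anchors with populations held exact.
    """
    if name not in _POPULATIONS_PCT:
        raise ValueError(f"unknown fixture name {name!r}; expected 'popc' or 'pops'")
    if not time_scale > 0:
        raise ValueError("time_scale must be positive")
    T, pi, residual = _fitted_chain(name)
    means = _EMISSION_MEANS[name]
    # per-dimension emission scale: 0.15 x mean adjacent-state gap
    gaps = np.abs(np.diff(means, axis=0)).mean(axis=0)
    sds = np.tile(np.maximum(_EMISSION_SD_FACTOR * gaps, 1e-6), (len(pi), 1))
    return KineticFixture(
        name=name,
        state_names=MACROSTATE_NAMES,
        transition_matrix=T.copy(),
        stationary=pi.copy(),
        frame_interval=_FRAME_INTERVAL_NS[name] * time_scale,
        emission_means=means.copy(),
        emission_sds=sds,
        mfpt_fit_residual=residual,
    )


def simulate_latent(
    fixture: KineticFixture,
    n_frames: int,
    n_traj: int,
    seed: int,
    feature_dim: int | None = None,
) -> list[LatentTrajectory]:
    """Sample hidden-state trajectories with autocorrelated Gaussian emissions.

    The hidden chain advances with the fixture transition matrix, initial
    states drawn from the stationary distribution.  Emissions are
    state-conditioned Gaussians whose noise follows a stationary AR(1)
    process (coefficient ``fixture.ar_coefficient``), so features are
    correlated within a state visit.  Identical arguments reproduce
    identical output bit-for-bit.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    d_full = fixture.n_features
    d = d_full if feature_dim is None else int(feature_dim)
    if not 2 <= d <= d_full:
        raise ValueError(f"feature_dim must be in [2, {d_full}]")

    rng = np.random.default_rng(seed)
    cum = np.cumsum(fixture.transition_matrix, axis=1)
    means = fixture.emission_means[:, :d]
    sds = fixture.emission_sds[:, :d]
    a = fixture.ar_coefficient
    innov = np.sqrt(1.0 - a * a)

    states = np.empty((n_frames, n_traj), dtype=np.int32)
    states[0] = rng.choice(fixture.n_states, size=n_traj, p=fixture.stationary)
    noise = np.empty((n_frames, n_traj, d))
    noise[0] = rng.standard_normal((n_traj, d))
    for t in range(1, n_frames):
        u = rng.random(n_traj)
        states[t] = (u[:, None] > cum[states[t - 1]]).sum(axis=1)
        noise[t] = a * noise[t - 1] + innov * rng.standard_normal((n_traj, d))

    out = []
    for k in range(n_traj):
        lab = states[:, k].copy()
        feats = means[lab] + sds[lab] * noise[:, k, :]
        out.append(
            LatentTrajectory(
                macrostate_labels=lab,
                features=feats,
                frame_interval=fixture.frame_interval,
                seed=seed,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Toy continuous dynamics for the adaptive-sampling loop
# ---------------------------------------------------------------------------


@dataclass
class ToyLandscape:
    """2D potential as a sum of inverted Gaussian wells.

    ``U(x) = -sum_k depth_k * exp(-|x - c_k|^2 / (2 w_k^2))`` with depths in
    units of the reference thermal energy.  Near the bottom of well ``k``
    the stiffness is ``depth_k / w_k^2`` per coordinate.
    """

    well_centers: np.ndarray
    well_depths: np.ndarray
    barrier_widths: np.ndarray
    diffusion_coefficient: float = 1.0
    timestep: float = 1e-3

    def __post_init__(self):
        self.well_centers = np.atleast_2d(np.asarray(self.well_centers, dtype=float))
        self.well_depths = np.atleast_1d(np.asarray(self.well_depths, dtype=float))
        self.barrier_widths = np.atleast_1d(np.asarray(self.barrier_widths, dtype=float))
        if len(self.well_centers) < 2:
            raise ValueError("a landscape needs at least two wells")
        if np.any(self.well_depths <= 0):
            raise ValueError("well depths must be positive")

    def potential(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        diff = x[:, None, :] - self.well_centers[None, :, :]
        r2 = (diff**2).sum(axis=2)
        return -(self.well_depths * np.exp(-r2 / (2 * self.barrier_widths**2))).sum(axis=1)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        diff = x[:, None, :] - self.well_centers[None, :, :]
        r2 = (diff**2).sum(axis=2)
        w2 = self.barrier_widths**2
        g = self.well_depths * np.exp(-r2 / (2 * w2)) / w2
        return (g[:, :, None] * diff).sum(axis=1)

    def stiffness(self, well: int) -> float:
        """Curvature of well ``well`` at its bottom (per coordinate)."""
        return float(self.well_depths[well] / self.barrier_widths[well] ** 2)


def simulate_brownian(
    landscape: ToyLandscape,
    n_steps: int,
    kT: float,
    seed: int,
    start: Sequence[float],
) -> np.ndarray:
    """Overdamped Euler-Maruyama trajectory on a toy landscape.

    Update: ``dx = -mu grad(U) dt + sqrt(2 mu kT dt) xi`` with mobility
    ``mu = diffusion_coefficient`` (the diffusion constant at unit thermal
    energy), so the stationary density is ``exp(-U / kT)``.  ``kT = 0``
    gives noiseless gradient descent.  Returns positions of shape
    ``(n_steps + 1, 2)`` including the start.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    mu = landscape.diffusion_coefficient
    dt = landscape.timestep
    # drift sanity check: steepest gradient of a Gaussian well is at one
    # width from the center, |grad| = depth * exp(-1/2) / width
    max_grad = float(np.max(landscape.well_depths * np.exp(-0.5) / landscape.barrier_widths))
    if mu * max_grad * dt >= float(np.min(landscape.barrier_widths)):
        raise ValueError("timestep too large: drift per step exceeds the barrier width")

    rng = np.random.default_rng(seed)
    x = np.asarray(start, dtype=float).reshape(1, 2)
    out = np.empty((n_steps + 1, 2))
    out[0] = x[0]
    sigma = np.sqrt(2.0 * mu * max(kT, 0.0) * dt)
    for t in range(1, n_steps + 1):
        drift = -mu * landscape.gradient(x) * dt
        x = x + drift
        if sigma > 0:
            x = x + sigma * rng.standard_normal((1, 2))
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(
                f"Brownian integration diverged at step {t}: position {x.ravel()}"
            )
        out[t] = x[0]
    return out


def kramers_escape_time(landscape: ToyLandscape, well: int, kT: float) -> float:
    """Kramers high-barrier estimate of the escape time from a well.

    ``tau = 2 pi / (mu sqrt(k_well * k_barrier)) * exp(dU / kT)`` with the
    barrier curvature approximated by the well curvature; an
    order-of-magnitude oracle for the toy double well.
    """
    k = landscape.stiffness(well)
    dU = float(landscape.well_depths[well])
    mu = landscape.diffusion_coefficient
    return 2.0 * np.pi / (mu * k) * np.exp(dU / kT)


# ---------------------------------------------------------------------------
# Toy coordinate fixtures for the structural observables
# ---------------------------------------------------------------------------

PROTEIN_DOMAINS = ("MpD", "DD", "CrD", "StD", "TmD", "IcD")
LIPID_SPECIES = ("POPC", "POPS")
FAB_CLASSES = ("FabH", "FabL")


@dataclass
class StructureFrame:
    """Labelled pseudo-atom coordinates with membrane-slab geometry.

    ``coords`` are (N, 3) Angstrom positions; per-atom label arrays give
    the residue id/name, the molecule id (each lipid molecule and the Fab
    chains have their own ids) and the molecule class: a protein domain
    name, a lipid species, or a Fab chain class.  ``membrane_slab`` is the
    (z_lo, z_hi) interval of the bilayer with its lateral half-extent.
    """

    coords: np.ndarray
    residue_id: np.ndarray
    residue_name: np.ndarray
    molecule_id: np.ndarray
    molecule_class: np.ndarray
    membrane_slab: tuple = (0.0, 40.0, 100.0)
    masses: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.coords)
        for name in ("residue_id", "molecule_id"):
            setattr(self, name, np.asarray(getattr(self, name)))
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.molecule_class = np.asarray(self.molecule_class, dtype=object)
        for name in ("residue_id", "residue_name", "molecule_id", "molecule_class"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per atom")
        z_lo, z_hi = self.membrane_slab[0], self.membrane_slab[1]
        if not z_lo < z_hi:
            raise ValueError("membrane slab must satisfy z_lo < z_hi")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def select(self, molecule_class=None, residue_ids=None) -> np.ndarray:
        """Boolean mask over atoms by molecule class(es) and/or residue ids."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if molecule_class is not None:
            if isinstance(molecule_class, str):
                molecule_class = (molecule_class,)
            mask &= np.isin(self.molecule_class.astype(str), list(molecule_class))
        if residue_ids is not None:
            mask &= np.isin(self.residue_id, np.asarray(list(residue_ids)))
        return mask

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureFrame":
        return StructureFrame(
            coords=self.coords @ rotation.T + translation,
            residue_id=self.residue_id.copy(),
            residue_name=self.residue_name.copy(),
            molecule_id=self.molecule_id.copy(),
            molecule_class=self.molecule_class.copy(),
            membrane_slab=self.membrane_slab,
            masses=None if self.masses is None else self.masses.copy(),
        )


@dataclass
class ToyComplexSpec:
    """Geometry parameters for :func:`build_toy_complex`.

    Protein domains are placed as compact blobs stacked above the membrane
    slab; lipids sit with head pseudo-atoms at the upper slab face and tail
    atoms inside the slab; an optional Fab body is placed at ``fab_offset``
    relative to the DD centroid.  ``explicit_lipids`` pins individual lipid
    molecules at given head positions (species, (x, y, z)).
    """

    domain_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"MpD": 24, "DD": 16, "CrD": 16, "StD": 10, "TmD": 8, "IcD": 6}
    )
    domain_radius: float = 7.0
    lipid_counts: Mapping[str, int] = field(default_factory=lambda: {"POPC": 28, "POPS": 12})
    explicit_lipids: Sequence[tuple] = ()
    atoms_per_lipid: int = 3
    slab: tuple = (0.0, 40.0)
    lateral_extent: float = 80.0
    fab_size: int = 0
    fab_offset: Sequence[float] = (0.0, 0.0, 45.0)
    residues_per_domain_atom: int = 1


def build_toy_complex(spec: ToyComplexSpec, seed: int) -> StructureFrame:
    """Deterministically generate a labelled pseudo-atom complex.

    Domains are stacked bottom-up (TmD spans the slab, then StD, CrD, DD,
    MpD above it); each domain is a Gaussian blob of pseudo-atoms with one
    residue per atom, numbered consecutively across the protein.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    rng = np.random.default_rng(seed)
    z_lo, z_hi = spec.slab
    coords, res_id, res_name, mol_id, mol_class = [], [], [], [], []
    next_mol = 0
    next_res = 1

    stack_order = [d for d in ("IcD", "TmD", "StD", "CrD", "DD", "MpD") if d in spec.domain_sizes]
    z_cursor = {"IcD": z_lo - 10.0, "TmD": 0.5 * (z_lo + z_hi)}
    z = z_hi + 6.0
    for dom in stack_order:
        n = spec.domain_sizes[dom]
        if dom in z_cursor:
            center = np.array([0.0, 0.0, z_cursor[dom]])
        else:
            center = np.array([0.0, 0.0, z + spec.domain_radius])
            z += 2.0 * spec.domain_radius + 2.0
        pts = center + rng.normal(scale=spec.domain_radius / 2.0, size=(n, 3))
        coords.append(pts)
        res_id.extend(range(next_res, next_res + n))
        next_res += n
        res_name.extend([dom[:3].upper()] * n)
        mol_id.extend([next_mol] * n)
        mol_class.extend([dom] * n)
    next_mol += 1

    def add_lipid(species, head):
        nonlocal next_mol, next_res
        head = np.asarray(head, dtype=float)
        pts = [head]
        for k in range(1, spec.atoms_per_lipid):
            pts.append(head + np.array([0.0, 0.0, -4.0 * k]))
        coords.append(np.asarray(pts))
        res_id.extend([next_res] * len(pts))
        res_name.extend([species] * len(pts))
        mol_id.extend([next_mol] * len(pts))
        mol_class.extend([species] * len(pts))
        next_res += 1
        next_mol += 1

    for species, head in spec.explicit_lipids:
        if species not in LIPID_SPECIES:
            raise ValueError(f"unknown lipid species {species!r}")
        add_lipid(species, head)
    for species, count in spec.lipid_counts.items():
        if species not in LIPID_SPECIES:
            raise ValueError(f"unknown lipid species {species!r}")
        for _ in range(count):
            xy = rng.uniform(-spec.lateral_extent / 2, spec.lateral_extent / 2, size=2)
            head = np.array([xy[0], xy[1], z_hi + rng.normal(scale=0.5)])
            add_lipid(species, head)

    if spec.fab_size > 0:
        dd_mask = np.array([c == "DD" for c in mol_class])
        all_coords = np.concatenate(coords)
        dd_center = (
            all_coords[dd_mask].mean(axis=0) if dd_mask.any() else np.array([0.0, 0.0, z_hi + 20.0])
        )
        for chain in FAB_CLASSES:
            n = max(spec.fab_size // 2, 1)
            center = dd_center + np.asarray(spec.fab_offset, dtype=float)
            pts = center + rng.normal(scale=4.0, size=(n, 3))
            coords.append(pts)
            res_id.extend(range(next_res, next_res + n))
            next_res += n
            res_name.extend([chain] * n)
            mol_id.extend([next_mol] * n)
            mol_class.extend([chain] * n)
            next_mol += 1

    mol_id = np.asarray(mol_id)
    if len(np.unique(mol_id)) != next_mol:
        raise ValueError("molecule ids do not partition the atoms")
    return StructureFrame(
        coords=np.concatenate(coords),
        residue_id=np.asarray(res_id),
        residue_name=np.asarray(res_name, dtype=object),
        molecule_id=mol_id,
        molecule_class=np.asarray(mol_class, dtype=object),
        membrane_slab=(z_lo, z_hi, spec.lateral_extent),
    )
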