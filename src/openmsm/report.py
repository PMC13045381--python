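"""Free-energy surfaces, reference projections and per-state histograms.

Surfaces are ``F = -ln(p / p_max)`` in units of kT on the (IC1, IC2)
plane, with optional MSM stationary reweighting (frame weight equal to
the stationary probability of its microstate divided by the frames in
that microstate) so the landscape reflects the estimated equilibrium
rather than the adaptive-sampling measure.  Undefined (empty) bins are
masked, never reported as zero free energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .featurize import DistancePairSet, pairwise_distances
from .tica import TICA


@dataclass
class FreeEnergySurface:
    """2D free-energy grid in kT; the minimum over defined bins is 0."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray
    mask: np.ndarray  # True where defined

    def defined_values(self) -> np.ndarray:
        return self.free_energy[self.mask]

    def to_arrays(self):
        grid = np.where(self.mask, self.free_energy, np.nan)
        return self.x_edges, self.y_edges, grid


def free_energy_surface(
    projections,
    weights=None,
    bins=(100, 100),
    padding: float = 0.05,
) -> FreeEnergySurface:
    """Histogram-based 2D free-energy surface on the first two columns.

    ``weights`` are optional per-frame weights (e.g. MSM stationary
    reweighting); bins span the data extent padded by ``padding`` on each
    side.  Raises a warning-level error only for a fully degenerate axis.
    """
    arrs = projections if isinstance(projections, list) else [projections]
    pooled = np.concatenate([np.atleast_2d(a.T).T for a in arrs], axis=0)[:, :2]
    if len(pooled) < 2:
        raise ValueError("at least 2 frames are required")
    w = None
    if weights is not None:
        w = np.concatenate([np.asarray(x, dtype=float) for x in (
            weights if isinstance(weights, list) else [weights]
        )])
        if len(w) != len(pooled):
            raise ValueError("one weight per frame required")
    ranges = []
    for d in range(2):
        lo, hi = pooled[:, d].min(), pooled[:, d].max()
        if hi - lo <= 0:
            import warnings

            warnings.warn(f"degenerate axis {d}: all frames in one bin", RuntimeWarning,
                          stacklevel=2)
            hi = lo + 1e-9
        pad = padding * (hi - lo)
        ranges.append((lo - pad, hi + pad))
    H, xe, ye = np.histogram2d(pooled[:, 0], pooled[:, 1], bins=bins, range=ranges, weights=w)
    mask = H > 0
    F = np.zeros_like(H)
    F[mask] = -np.log(H[mask] / H.max())
    return FreeEnergySurface(x_edges=xe, y_edges=ye, free_energy=F, mask=mask)


def msm_frame_weights(dtrajs, stationary: np.ndarray, active_set: np.ndarray):
    """Per-frame stationary reweighting: pi(microstate) / frames-in-microstate.

    Frames whose microstate is outside the active set get weight 0.
    Returns a list matching ``dtrajs``.
    """
    dtrajs = dtrajs if isinstance(dtrajs, list) else [dtrajs]
    n = max(int(d.max()) for d in dtrajs) + 1
    pi_full = np.zeros(n)
    pi_full[active_set] = stationary
    counts = np.zeros(n)
    for d in dtrajs:
        counts += np.bincount(d, minlength=n)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_state = np.where(counts > 0, pi_full / np.maximum(counts, 1), 0.0)
    return [per_state[d] for d in dtrajs]


def project_references(
    reference_frames,
    pairs: DistancePairSet,
    tica_model: TICA,
) -> np.ndarray:
    """Project reference structures into the fitted IC space (no refit).

    The projection is affine in the features, so e.g. a frame whose
    features are the midpoint of two others projects to the midpoint of
    their projections.
    """
    feats = pairwise_distances(reference_frames, pairs)
    return tica_model.transform(feats.values)


def state_histograms(
    observable,
    macro_labels,
    bins=50,
    density: bool = True,
    label_names=None,
) -> dict:
    """One histogram of an observable per macrostate.

    Frames labelled ``-1`` (outside the active set) are skipped; raw
    counts over all returned histograms conserve the number of labelled
    frames.  Returns ``{label: (hist, bin_edges)}``.
    """
    obs = np.concatenate([np.asarray(o, dtype=float) for o in (
        observable if isinstance(observable, list) else [observable]
    )])
    lab = np.concatenate([np.asarray(l) for l in (
        macro_labels if isinstance(macro_labels, list) else [macro_labels]
    )])
    if len(obs) != len(lab):
        raise ValueError("observable and labels must have equal lengths")
    valid = lab >= 0
    edges = np.histogram_bin_edges(obs[valid], bins=bins)
    out = {}
    for a in np.unique(lab[valid]):
        sel = lab == a
        hist, _ = np.histogram(obs[sel], bins=edges, density=density)
        key = a if label_names is None else label_names[a]
        out[key] = (hist, edges)
    return out


def state_means(observable, macro_labels) -> dict:
    """Mean of an observable over the frames of each macrostate."""
    obs = np.concatenate([np.asarray(o, dtype=float) for o in (
        observable if isinstance(observable, list) else [observable]
    )])
    lab = np.concatenate([np.asarray(l) for l in (
        macro_labels if isinstance(macro_labels, list) else [macro_labels]
    )])
    return {int(a): float(obs[lab == a].mean()) for a in np.unique(lab[lab >= 0])}
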