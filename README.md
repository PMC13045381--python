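# openmsm

Markov state model (MSM) and adaptive-sampling analysis of
membrane-protein opening transitions, built around the question of how
anionic phosphatidylserine (PS) lipids shift the conformational
equilibrium of the sheddase ADAM10 from closed toward open, catalytically
accessible states.

## Who this is for

Computational structural biologists who want a compact, fully tested
re-implementation of the standard conformational-dynamics analysis chain
— FAST-style adaptive sampling, time-lagged independent component
analysis (tICA), microstate clustering, reversible/Bayesian MSM
estimation with validation, PCCA+ coarse-graining, and membrane-specific
structural observables — that runs end-to-end on synthetic dynamics, with
every estimator checked against closed forms or independent oracles.

## The model

A trajectory of feature vectors **x**(t) (here: interdomain distances in
Å, including a catalytic-site accessibility distance) is reduced by tICA,
which solves the generalized eigenproblem

    C(τ) v = λ C(0) v

for the symmetrized time-lagged covariance C(τ); the leading components
IC1, IC2 are the slowest linear collective coordinates and the
eigenvalues map to relaxation timescales t_i = −τ/ln λ_i. Frames are
discretized by k-means into microstates, and a reversible transition
matrix T(τ) is estimated by maximum likelihood under detailed balance
π_i T_ij = π_j T_ji. Validation uses implied-timescale plateaus and the
Chapman-Kolmogorov test T(kτ) ≈ T(τ)^k on metastable sets. PCCA+ lumps
microstates into four macrostates — Closed, intermediate-closed (Ic),
intermediate-open (Io), expanded-open (Eo), ordered by the openness
observable — giving stationary populations π(A) = Σ_{i∈A} π_i and mean
first-passage times from the exact linear solve
(I − T_restricted) m = τ·1, with uncertainties from a Bayesian posterior
over reversible transition matrices (n = 100 samples).

Because the original 64 µs of all-atom MD is not reproducible on a desk,
the package ships a synthetic-dynamics module: a reversible four-state
jump process whose stationary distribution and MFPTs encode the reported
thermodynamics/kinetics of both membrane systems, with state-conditioned
autocorrelated Gaussian feature emissions. Every pipeline stage is tested
by recovering these known ground truths.

## Worked example

```python
import numpy as np
from openmsm import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(fixture="popc", n_traj=50,
                                  n_frames=20_000, seed=1,
                                  k_microstates=50))
print(np.round(res.ordered_populations_pct(), 2))
print(np.round(res.ordered_mfpt_us()[0, 3], 2))
print(round(res.accessibility_means[3], 1))
```

prints

```
[19.95 19.05 53.63  7.37]
19.87
100.0
```

— the recovered Closed/Ic/Io/Eo stationary populations (percent, summing
to 100), the Closed→Eo mean first-passage time in µs, and the mean
catalytic-site accessibility (Å) of the most-open state. For the
PS-containing fixture (`fixture="pops"`) the same call returns
populations of roughly (0.5, 0.2, 39.6, 59.7) % — the near-complete
depletion of closed states that PS induces — with Io↔Eo exchange below
0.5 µs.

The CLI exposes the same stages (`openmsm simulate | featurize | tica |
cluster | msm | macro | fast | report | run-all`); try
`openmsm fast --generations 16 --swarm-size 20` for the adaptive-sampling
campaign bookkeeping (320 segments, 32 µs).

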