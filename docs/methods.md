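# Methods

This note documents the models, defaults and numerical choices behind
`openmsm`, in the order the pipeline runs them, together with what the
synthetic fixtures do and do not emulate.

## Synthetic kinetic fixtures

The object of study is the opening equilibrium of a membrane-anchored
sheddase over four macrostates — Closed, intermediate-closed (Ic),
intermediate-open (Io), expanded-open (Eo) — in two membrane
environments: pure POPC and a 7:3 POPC:POPS mixture in which anionic PS
lipids shift the equilibrium open. Each fixture is a reversible
discrete-time Markov chain over the four macrostates, constructed as
follows.

**Populations are exact.** The stationary vector equals the reported
percentages: (19.9, 19.5, 53.2, 7.3) % for POPC and
(0.5, 0.3, 39.8, 59.2) % for POPC:POPS. As printed these sum to 99.9 %
and 99.8 % respectively; both are renormalized to 1.

**MFPTs are a least-squares fit.** A 4-state reversible chain has 6 free
exchange flows once the stationary vector is fixed (T_ij = K_ij/π_i with
K symmetric), so it cannot match 12 directed mean first-passage times
exactly. Anchor MFPTs are fitted in log space by Levenberg-Marquardt with
the populations held exact. Anchors for POPC: 2.5 µs for every directed
pair among {Closed, Ic, Io} (the reported exchanges are "rapid", all
≤ 4.1 µs) and 20 µs into Eo from each of the three (weight 5). For
POPC:POPS: 0.25 µs for Io↔Eo in both directions (half of the reported
< 0.5 µs bound, weight 5), 0.1 µs Closed→Io, 1 µs Ic→Io, 20 µs back into
Closed and 300 µs back into Ic. The fitted chains reproduce the anchors
to a few percent (weighted log-RMS residual ≈ 0.22 for POPC, ≈ 0.47 for
POPC:POPS, dominated by the deliberately over-determined pairs); the
exact MFPT oracle — the linear solve (I − T_restricted) m = 1 — is always
the ground truth, never the anchors themselves.

**Time mapping.** The declared frame interval is 25 ns (POPC) and 5 ns
(POPC:POPS) so that the slowest relaxation of either chain is a few
hundred frames (59.8/38.0/17.1 frames for POPC; 186/24.6/18.6 for
POPC:POPS) while all physical MFPTs remain in the microsecond range
reported for the real system. A `time_scale` factor rescales the frame
interval (and hence all physical times) without changing the chain. The
per-criterion problem size — 50 trajectories of 20,000 frames — then
covers hundreds of slow relaxations, which is what makes ±1.5-point
population recovery feasible on one CPU in under a minute per system.

**Emissions.** Each frame emits a 5-dimensional feature vector: column 0
is the catalytic-site accessibility (Å), with per-state means
(20, 27.5, 65, 100) for POPC and (20, 20, 50, 75) for POPC:POPS —
centers of the reported per-state distributions — and columns 1–4 are
interface-distance-like features that open progressively and keep all
four states pairwise separable (necessary for POPC:POPS, where Closed
and Ic share the same accessibility center). Per-dimension emission
standard deviation is 0.15 × the mean adjacent-state gap, giving
overlapping-but-separable states (adjacent separations of roughly 4–8
combined σ). Noise is a stationary AR(1) process with coefficient 0.9
(≈ 9.5-frame correlation time), shared across the state switch so that
features are autocorrelated within and across visits — the feature of
real trajectories that most stresses MSM estimation at short lags.

**What the generator does not emulate:** anharmonic within-state
landscapes, state-dependent noise anisotropy, slow lipid rearrangement,
projection nonlinearity, or any coupling between the openness features
and the lipid-contact observables. Passing recovery tests therefore
demonstrates correctness of the estimators under Markovian state
dynamics with correlated Gaussian emissions, not robustness to every
pathology of atomistic data.

## tICA

Reversible (symmetrized) covariance estimation over all trajectories
pooled, mean-removed using the all-frame pooled mean (so projections of
the training data are exactly mean-free; any common centre keeps the
symmetrized eigenvalues inside [−1, 1]); the
generalized eigenproblem is solved after projecting out feature
directions whose variance is below 1e-10 × the largest (relative
eigenvalue floor). Eigenvalues are asserted to lie in [−1, 1] (violations
indicate conditioning bugs, not physics). Components are normalized to
unit variance under C(0); no kinetic-map scaling is applied — the
free-energy surfaces are invariant to per-axis scaling after binning.
Default lag: 5 frames, long enough that state processes dominate the
AR(1) emission noise in the spectrum, short relative to every fixture
relaxation.

## Component screening and the clustering space

Following the single-Gaussian screening rule, a component is discarded
when a one-component Gaussian fit beats a two-component mixture by
ΔBIC ≥ 10 (strong-evidence convention; the fits use an evenly strided
subsample of ≤ 100,000 frames). The slowest two retained components
define the (IC1, IC2) plane used for landscapes and reference
projections.

Clustering, however, runs on the *non-Gaussian* component subspace:
components whose pooled marginal has |excess kurtosis| > 0.1. Rationale:
a state that occupies 0.3 % of the data contributes almost no variance
and, with a short dwell time, no resolvable slow eigenvalue — its
separation can live in a component that the 1-vs-2 mixture test cannot
retain (satellites on opposite sides of the bulk). But any component
that only carries AR emission noise is Gaussian to high precision at
these sample sizes (kurtosis standard error ≈ 0.005 at 10⁶ frames),
while state-structured components are either strongly platykurtic
(multimodal) or leptokurtic (rare satellites). The kurtosis rule
therefore selects exactly the state-bearing subspace in both fixtures;
clustering on fewer components merges rare states, and clustering on all
components lets noise dimensions produce non-Markovian microstates that
bias MFPTs downward by up to 3× at short lags.

## Microstates

Seeded k-means (k-means++ D² initialization from an explicit generator,
Lloyd iterations, ties to the lowest center index, empty clusters
re-seeded to the farthest point), fully deterministic under its seed.
k = 200 is the full-scale default; recovery runs use k = 50, which the
desk-scale datasets support comfortably (the rare POPS states still
receive dedicated centers). The pipeline caps Lloyd at 60 iterations —
center drift beyond that point is far below the microstate size and has
no measurable effect on the MSM.

## MSM estimation and validation

Sliding-window transition counts; the active set is the largest strongly
connected component of the count graph. Reversible maximum likelihood
uses the classical self-consistent fixed point on symmetric flows,
converged to 1e-10 in the flow matrix. The estimation lag is chosen by
the implied-timescale plateau rule: the first lag in
(1, 2, 3, 5, 8, 12, 16, 20, 25, 30) at which all reported timescales
change by < 10 % versus the next lag. Chapman-Kolmogorov validation
compares T(kτ)-predictions against models re-estimated at lag kτ on the
PCCA+ metastable sets, with optional Bayesian error bands.

Bayesian uncertainty uses Metropolis-within-Gibbs sampling over the
symmetric flows with multiplicative (log-scale) proposals of step 0.2 —
a log-uniform prior on flows; the likelihood is scale-invariant so the
chain moves on the reversible simplex. Burn-in 1000 sweeps, thinning
every 10 sweeps, n = 100 samples by default. Sliding counts are divided
by the lag before sampling, the standard correction for
overlapping-window overcounting that would otherwise make posteriors
overconfident. The count mode and prior are choices of this package; the
reference analysis left both unspecified.

## PCCA+ and macrostate observables

Dominant right eigenvectors are computed through the symmetric
similarity transform (exactly real for reversible inputs). Simplex
vertices are found greedily (inner simplex algorithm); the feasible
linear transform is then refined by Nelder-Mead to maximize the
stationary-weighted crispness Σ_i π_i Σ_j χ_ij², under the feasibility
projection (rows of A beyond the first centered, row 0 raised to enforce
non-negativity, global normalization). The refined transform is accepted
only if every macrostate retains at least one microstate under crisp
argmax assignment — a pure crispness objective can otherwise sacrifice
rare macrostates entirely — else the ISA solution is kept.

Macrostate identity is assigned by ascending mean openness
(accessibility), the convention that names the states
Closed < Ic < Io < Eo; PCCA+ output order is arbitrary. Populations are
stationary-weighted sums over the crisp map (a raw frame-fraction mode
exists behind a flag). MFPTs use the exact linear solve on the
microstate matrix with the source average weighted by the stationary
distribution restricted to the source macrostate; values convert to µs
through the model lag and frame interval.

## Adaptive sampling

The campaign loop follows the FAST pattern: swarms of short segments,
k-means on all accumulated frames each generation, cluster ranking by
α·normalized(mean reward) + (1−α)·normalized(1/(1+visits)), seeds drawn
uniformly (seeded) from the chosen clusters — from cluster *members*, so
seeds are always valid simulator states. α defaults to 1 (pure directed
ranking); k_gen defaults to 100. The reference bookkeeping — 16
generations × 20 segments of 50 ns, all extended to 100 ns — gives 320
segments and 32 µs, which `plan_campaign` reproduces exactly without
dynamics. The reward trace records the running maximum over accumulated
frames (the convergence diagnostic), which is non-decreasing by
construction.

The efficacy testbed is a 2D double well (Gaussian wells of depth 6 kT,
width 0.45, at x = ±1) under overdamped Euler-Maruyama dynamics with
mobility 1 and dt = 5e-4; the Kramers estimate puts the spontaneous
escape time near 1.7 × 10⁵ steps, ~70× a campaign segment, so uniform
restarts rarely cross while reward-ranked seeding ratchets over the
barrier within ten generations.

## Structural observables

Lipid contacts count distinct lipid *molecules* with any atom within
4.0 Å (inclusive) of any atom of the domain — molecule counting matches
the magnitude of the reported per-frame contact distributions (~10–15);
an atom-pair mode exists behind a flag, and a per-residue mode supports
contact-frequency profiles. Centroid (catalytic-site accessibility)
distances default to uniform weights — pseudo-atoms carry no mass — with
mass weighting available for real PDB input. Superposition is the Kabsch
SVD solution restricted to proper rotations. Membrane clash requires at
least one body atom deeper than 1 Å inside the slab, avoiding
grazing-contact false positives; both the slab and the threshold are
configurable.

## Free-energy surfaces and histograms

F = −ln(p/p_max) in kT on a 100 × 100 grid spanning the data extent
padded by 5 %; empty bins are masked, never zero. Surfaces are
MSM-reweighted by default (frame weight = π of its microstate / frames
in that microstate) so they represent the estimated equilibrium rather
than the adaptive-sampling measure; a raw-histogram mode exists.

## Known limitations

- Linear (tICA) coordinates cannot isolate rare-state kinetics as slow
  eigenvalues when the state's variance contribution is far below the
  emission noise; the kurtosis-selected clustering space works around
  this for discretization, but implied timescales of such processes
  remain underestimated at practical lags (the 186-frame POPS process
  reads ~130–160 frames at lags 16–40).
- MFPTs estimated at lag τ carry an O(τ) discretization bias; on the
  POPS fixture this inflates the sub-µs Io↔Eo times by ~20–30 % at the
  plateau lag, still well inside the reported bound.
- The Bayesian flow sampler is a simple random-walk scheme; for very
  deep counts its mixing is slow and the acceptance-rate diagnostic
  should be heeded.
- PDB support covers coordinates and labels only (no connectivity,
  occupancy or element-specific handling beyond masses for weighting).
- With AR(1) emission noise, the tICA IC1 timescale at short lags mixes
  state and noise autocorrelation and reads low; it approaches the true
  slowest relaxation only at lags past the noise memory (~2-3x the
  AR correlation time).
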