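# Methods

This note records the models, conventions, and numerical choices behind
pmfpath, and what its synthetic validation does and does not demonstrate.

## Physical setting and units

The package analyses umbrella-sampling data over one or two collective
variables — ion axial positions in a channel pore, in nm. Energies are in
kJ/mol; k_B T = 2.577 kJ/mol at the default 310 K (computed from
scipy.constants, never hard-coded). The harmonic bias convention is
U_bias(z) = Σ_d ½ k_d (z_d − z⁰_d)², with the same force constant applied
to every CV of a window (k = 1000 kJ/mol/nm² by default). The sampler and
WHAM share this convention by construction.

## Synthetic landscapes (`landscapes`)

Surfaces are Gaussian mixtures F(z) = baseline + Σ a_i exp(−Σ_d
(z_d−c_id)²/2w_id²), normalized so the global minimum is exactly 0.
Stationary points are located by multi-start L-BFGS (minima) and Powell
hybrid root-finding on the analytic gradient (saddles), classified by
Hessian signature, de-duplicated at 2×10⁻³ nm, and stored as ground truth.
Points with |Hessian eigenvalue| < 10⁻⁵ are discarded as flat tail
artifacts.

Window sampling is Metropolis Monte Carlo targeting
exp(−[F + U_bias]/k_BT), not Langevin dynamics: only the stationary
distribution matters for WHAM, and a Markov chain with pregenerated
per-window random streams is exactly seedable. Window i of a batch uses
generator seed `root + i`, so any subset of windows reproduces
bit-identically regardless of batch composition. Burn-in defaults to 10%
of the requested samples (mirroring the discarded first tenth of a
production window run). The default proposal scale is 0.05 nm.

Adaptive window planning expands breadth-first from a start center and
admits a neighboring grid center iff the *true* surface value there is
below the cutoff. This is a planning heuristic for synthetic surfaces
only; for real data the surface is unknown and the full regular grid is
the supported path.

What the generator emulates: the window grid geometry, harmonic biasing,
Boltzmann statistics at 310 K, and barrier heights in the 5–50 kJ/mol
range of permeation problems. What it does not emulate: time-correlated
MD dynamics (Metropolis correlation is short-ranged and tunable),
anisotropic and multimodal window distributions caused by orthogonal slow
degrees of freedom, and force-field error. Passing tests therefore
validate the *estimators*, not the convergence of any particular MD
study.

## WHAM (`wham`)

Bins are uniform over the span of window centers padded by half the median
center spacing (not the data extent), so repeated runs share a grid; 100
bins per CV by default; half-open bins with the last bin closed (numpy
convention). The self-consistent equations are solved in log space
(logsumexp over windows × sampled bins). Because the WHAM fixed point
minimizes a convex negative log-likelihood in the window offsets, the
solver first runs L-BFGS on that likelihood with its analytic gradient,
then polishes by direct iteration until max |Δf_k| < tolerance (default
10⁻⁶ kJ/mol) — the reported convergence metric, usually reached within a
couple of polish iterations. Unsampled bins carry NaN, never an
interpolated value. Windows whose sampled bins share no support are
detected by union-find and flagged (`reliable_offsets=False`): their
relative offsets are arbitrary. Pooling replicate runs of the same window
grid is supported by listing them as separate windows — the statistically
correct treatment — and is used in the end-to-end validation.

A property of chained 1D WHAM worth knowing: window-offset errors
accumulate like a random walk along the chain, so the recovered PMF can
carry a smooth seed-dependent tilt of order 0.3–1 kJ/mol across 23 windows
at 5000 samples each, while *local* barrier differences converge much
faster. Rate calculations depend on the local differences.

## Interpolation, minima, basins (`surface_tools`)

The PMF grid is interpolated bicubically (FITPACK, s=0): values at bin
centers are reproduced to 10⁻⁹ and gradients are analytic. Queries whose
4×4 spline support touches an unsampled bin raise a masked-region error.
For *estimated* PMFs an optional smoothing spline is provided; the
`"auto"` level targets three times the independent-error χ² estimate
Σ_b (k_BT)²/n_b, the factor 3 accounting for the spatial correlation of
WHAM errors (shared offsets), which the independent estimate undercounts.
Exact interpolation remains the default.

Minimum detection uses the strict 8-neighbor inequality (plateaus and
exact ties yield nothing — documented convention), refines candidates by
bounded L-BFGS on the interpolant, merges survivors closer than
min_separation (default 0.1 nm, one umbrella interval) keeping the lower,
and sorts by energy. On histogram-noise surfaces the strict test fires on
every dimple, so an optional topological-persistence filter
(`min_persistence`, kJ/mol) floods the grid ascending with union-find and
keeps only minima whose basin depth below their lowest connecting saddle
reaches the threshold; 2 kJ/mol (≈ noise amplitude) is the pipeline
default, 0 (off) the library default.

Basin assignment runs 50 normalized gradient-descent steps of 0.02 nm from
each sample and assigns the nearest minimum of the endpoint, so a sample
just past a saddle joins the basin it would relax into rather than the
Euclidean-nearest minimum. Representative snapshots are the basin members
closest to the basin centroid (ties: lowest index).

## MFEP (`mfep`)

NEB uses 32 images per snippet, spring constant 500 kJ/mol/nm², improved
(upwinded) tangents, and a climbing image on the highest interior node
during the final quarter of the iteration budget (entered early on
convergence of the regular phase). The optimizer is FIRE rather than plain
steepest descent: on smoothing-spline surfaces steepest descent stalls
above any useful force tolerance, while FIRE reaches it on both analytic
and estimated PMFs at equal cost. Convergence requires the maximum
perpendicular force (and the climbing-image force) below the tolerance,
0.5 kJ/mol/nm by default; for WHAM-estimated surfaces a tolerance of the
gradient-noise scale (≈ 3 kJ/mol/nm at the validation sampling depth) is
the appropriate setting and is what the pipeline configuration uses. Bands
whose straight seed leaves the sampled region are re-seeded through the
minimax corridor of sampled bins (Dijkstra with max-energy cost).

The snippet graph connects minima pairs closer than 3× the median
nearest-neighbor distance. Converged snippets that relax through a third
minimum's basin (interior node within 0.15 nm of another minimum) are
excluded — they merely duplicate a multi-hop route and would corrupt
joined profiles with hidden intermediate states. Simple start→end routes
are joined and re-relaxed as one band ("further minimized"); a single-edge
route reuses its already-relaxed snippet, and a failed joint re-relaxation
falls back to the concatenated converged snippets with a log line. Ranking
is by lowest path maximum — the quantity that controls rates — quantized
to 0.1 kJ/mol so that physically equivalent routes tie and fall through to
the tie-break, the path action ∫F dλ. An unrelaxed (`relax=False`) mode is
available.

Projection to 1D takes λ as cumulative Euclidean arc length, re-interpolates
node energies with a cubic spline on 1024 points, marks interior extrema at
derivative sign changes, treats both endpoints as valleys, and removes
wiggles below a prominence threshold (default 0.5 kJ/mol) until the marker
sequence alternates strictly; a non-alternating remainder is an error, not
a silent fix.

`barrier(profile, i, j)` is the maximum of F on the directed segment minus
F(state i). When j precedes i, the profile is continued cyclically
*without* energy shift: in a finite simulation box the first and last
states are distinct configurations of the same system, so re-entry over
the periodic boundary costs the full net drop of the profile on top of the
maximum preceding the target state. This is the only reading under which a
profile with a 25 kJ/mol net drop and a 5 kJ/mol pre-first-state maximum
yields a 30 kJ/mol re-entry barrier while a 51 kJ/mol-drop profile yields
51 kJ/mol — the published decomposition pattern.

## Rates (`rates`)

Curvatures come from least-squares cubic fits of F(λ) within ±window of
each extremum (default: 0.05 nm or 3.5 grid steps, whichever is larger;
build_chain widens the window ×2 and ×4 before giving up). The fit's own
stationary point must stay inside the window; its second derivative gives
ω = √|F″| and, by sign, the extremum class. One-sided windows (profile
endpoints) underdetermine a cubic, so there the fit degree drops to a
quadratic — markedly more stable on noisy profiles. Curvature estimates
are the least robust link of the chain: their sensitivity to the window
should be checked (the fit residual is reported on each `Extremum`), and
ratios between similarly shaped systems are far more reliable than
absolute prefactors.

The Kramers prefactor pairs the starting valley's ω with the intervening
*peak's* ω (standard overdamped form); the literal valley–valley pairing is
available behind `convention="valley"`. All rates are computed and stored
in log space; γ ≡ 1, so rates carry friction-scaled units and only ratios
across systems are physical.

The chain master equation (absorbing last state, hops between neighbors
only) is integrated with LSODA at rtol 10⁻¹⁰, with the mean first-passage
time accumulated by the integrator itself as ∫(1−p_n)dt plus an
exponential tail correction from the terminal survival slope; the horizon
grows tenfold until p_n > 1 − 10⁻⁶. Against the closed-form birth–death
MFPT the relative error is below 10⁻⁴ on random 3–8 state chains. If the
chain's rates span more than 15 decades, the solve refuses
(`ChainOverflowError`) and the caller falls back to the rate-limiting
bound — the single-step Kramers rate over the highest forward barrier,
flagged as an upper bound; the flag propagates through `relative_rate` as
a "≤". TST conversions default to 298 K (literature-estimate convention)
while everything tied to sampling defaults to 310 K; both are arguments.

## Pipeline defaults and validation scale

The `run_pipeline` configuration applies: auto smoothing, persistence 2
kJ/mol, and endpoint selection as the most distant connected minima pair
unless states are given. Validation problem sizes were chosen to finish a
full run in minutes on one core: the 1D double-well recovery uses 23
windows × 5000 samples; the five-well two-CV landscape uses the full
506-window grid (0.1 nm spacing over −0.35..1.85 × −1.55..0.55 nm) at 2000
samples per window, recovering all five minima within 0.05 nm and hop
barriers within 1.5 kJ/mol; the end-to-end relative-rate check uses two
two-well systems differing by a wide +4 kJ/mol saddle bump, two pooled
8000-sample replicas per window each, and recovers the analytic Kramers
ratio to well within 25%. The wide bump keeps the curvature factor near
unity so the comparison stresses the barrier difference, which is the
quantity such relative-rate analyses rest on.

## Known limitations

- No autocorrelation weighting or MBAR: window samples are treated as
  independent, so error bars are not estimated and correlated samplers
  are down-weighted only by their actual information content.
- Curvature fitting assumes a locally smooth profile; heavily
  under-sampled PMFs can defeat the widened-window retries.
- Basin assignment is a coarse descent, exact on smooth test surfaces but
  not a substitute for steepest-descent integration on rugged ones.
- 2D saddles are never located directly; barriers always come from the 1D
  projection of the MFEP, as in the analysis this package reproduces.
- The rate chain assumes the MFEP dominates conduction (no parallel-path
  fluxes) and strictly nearest-neighbor hopping.
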