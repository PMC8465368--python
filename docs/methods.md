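# Methods

## Problem setting

A time-series Hi-C experiment yields one symmetric `n × n` intrachromosomal
contact map per sampled time τ. `hic4d` models the chromosome as `n` beads
whose 3D positions evolve over a discretized time interval: `g` equally
spaced *grid times* (the granularity) spanning the first to the last
observed time. Every observed time must coincide with a grid time — times
are snapped to the nearest grid point, and snapping that would move a time
by more than 25% of the grid spacing is a hard error, because silently
relocating an observation would distort the interpolation weights.
Granularity defaults to the number of observed maps (one grid point per
map); larger values insert unobserved frames between observations, which is
what makes interpolation at unsampled times possible.

## Restraints

Contacts and distances follow the inverse power law used throughout the 3D
genome-modeling literature: a pair with interaction frequency `IF > 0`
receives the target distance `D = IF^(-γ)`; extraction inverts it as
`IF = d^(-1/γ)` so the two conversions are exact inverses. γ is stored as
the positive magnitude, default **0.6**. Pairs with `IF = 0` carry no
restraint (absent data contributes nothing to the likelihood, rather than
an infinite distance), the diagonal is never restrained, and bins that are
empty at *every* time point are excluded everywhere. All target distances
share a single global rescaling so the largest equals 1: the optimizer
starts from coordinates uniform in the unit cube, and targets must live on
a commensurate scale. The factor is recorded on the `RestraintSet`, so
distances can be reported on either scale. Raw and normalized (ICE/KR)
counts are both accepted; the power law is applied agnostically.

## Likelihood

Observed restraints are modeled as Gaussian around the model distances,
with an unknown per-time spread σ_t. Writing `SSR_t = Σ_i (H_it − D_it)²`
over the `n_t` restraints active at grid time `t`, profiling σ_t out at its
maximum-likelihood value `σ_t² = SSR_t / n_t` turns the per-time negative
log-likelihood (up to an additive constant) into

    L_t = (n_t / 2) · log(SSR_t / n_t)

The `n_t/2` coefficient matters in practice and not only formally: it sets
the relative magnitude of the data gradient against the motion penalty and
the fixed initial step size, and without it the default optimizer budget
does not converge on realistic scales. A config toggle
(`FitConfig.half_n_weighting=False`) exposes the unweighted `log(SSR/n)`
variant for experimentation; the public `data_loss` helper reports the
unweighted value by default since that is the cleaner unit for tests.

An unobserved grid time `t` strictly between observed times `a1 < t < a2`
contributes the convex combination `w1·L(a1-targets) + w2·L(a2-targets)`
evaluated on frame `t`'s coordinates, with `w1 = (t − a2)/(a1 − a2)` and
`w2 = 1 − w1` (`interp_mode="blend_losses"`, the default). The alternative
`"blend_targets"` fits frame `t` against the entrywise `w`-weighted average
of the two neighbouring restraint sets instead. The two differ in
principle: blending the *losses* rewards exact satisfaction of either
neighbour unboundedly (the log diverges to −∞ at SSR = 0), which on
perfectly embeddable noiseless data can let an unobserved frame collapse
onto one neighbour instead of compromising; blending the *targets* has a
unique bounded optimum. On real (noisy, non-embeddable) data and on the
packaged synthetic system both behave equivalently; both are tested.
Endpoint grid times are observed by construction, so every unobserved frame
is flanked.

## Smoothness

The likelihood constrains distances, not orientation: without coupling,
consecutive frames could satisfy their restraints in arbitrarily rotated
poses and the rendered trajectory would be choppy. The penalty
`D_moves = Σ_t Σ_i Σ_c (S_i,c(t) − S_i,c(t+1))²` — the summed squared
per-bead displacement between consecutive frames — weighted by **η = 1000**
suppresses this. Since all frames start from the same initial conformation,
`D_moves` starts at exactly 0 and motion is introduced only where the data
demand it.

## Optimization

Coordinates initialize i.i.d. uniform on (0, 1), one draw per bead shared
across all frames (a single "unfolded structure"; independent per-frame
initialization is available via `FitConfig.shared_init=False` but leaves
the motion penalty to reconcile unrelated random poses). The objective
`Σ_t L_t + η·D_moves` is minimized for **400 epochs** by Gauss–Seidel
block-coordinate gradient descent: each epoch sweeps the frames in order
and takes one gradient step per frame, with a per-frame step size that
starts at the learning rate **λ = 1e-4**, is halved whenever the proposed
step would raise that frame's share of the objective (its data terms plus
the motion penalty against its current neighbours), and grows by ×1.25 on
acceptance. Because every accepted step lowers the total objective, the
recorded loss trace is non-increasing by construction; the per-frame step
adaptation is what lets early-converging frames (whose log-loss gradients
blow up near exact satisfaction) coexist with frames still far from their
restraints. A plain global fixed step fails in exactly this way: once one
frame nears its optimum the shared step must shrink and the remaining
frames starve. The analytic gradient is validated against central finite
differences (`gradient_check`, tolerance 1e-4 relative on small random
instances). Non-finite losses raise a divergence error naming the epoch;
an exactly-zero SSR is guarded by a 1e-300 floor inside the log only.

## Extraction and the naive baseline

A synthetic map at time `t` is computed from the frame at the nearest grid
time: `IF = d^(-1/γ)` off-diagonal, zero diagonal, masked bins zeroed.
Values stay on the model's internal distance scale — absolute Hi-C counts
are not recoverable from a structure — so downstream comparisons use rank
(Spearman) and Pearson statistics, which are scale-free/affine-robust. The
baseline for interpolation experiments is entrywise linear interpolation of
the two flanking real maps with the same convex weights; "beats the
baseline" is decided on Spearman correlation with ties awarded to the
baseline (the conservative choice).

## Feature calls

**Compartments.** Observed-over-expected normalization divides each entry
by the mean contact frequency at its genomic separation (computed over
unmasked pairs; separations with zero expected value stay 0). The Pearson
correlation matrix of the O/E rows is decomposed by PCA and each bin takes
the sign of its PC1 score: positive = A, negative = B. PCA sign is
arbitrary, so profiles are oriented to correlate positively with the
per-bin total O/E signal, and cross-profile comparisons should additionally
consider |PCC|. Compartment *trajectories* run PCA on the stacked ±1 sign
vectors of a series and keep two components per time point. A `factor`-bin
PC1 averaging helper supports coarser re-binned comparisons.

**TADs.** The directionality index contrasts each bin's contact sums into
the upstream window A and downstream window B (default 2 Mb each, truncated
at the chromosome ends so the track keeps length `n`):
`DI = sign(B−A)·((A−E)²/E + (B−E)²/E)` with `E = (A+B)/2`, and `DI = 0`
when `A = B` (the symmetric resolution of the 0/0 case). A 3-state Gaussian
HMM (upstream-bias / none / downstream-bias) with means initialized at
(−s, 0, +s) for s = std(DI), shared (tied) variance and uniform initial
transitions is fitted by EM and decoded by Viterbi; a border is placed at
every transition *into* a downstream-biased run — the conventional
signature of a domain start. EM non-convergence returns the best-so-far
decoding with a `converged=False` flag. Border sets are compared as the
percentage of one set's borders with a counterpart within 3 bins (150 kb at
50 kb resolution) — an asymmetric quantity when counts differ.

**Structure comparison.** Matched-time frames are compared by the
correlation of their pairwise-distance vectors (rigid-motion invariant) and
by Procrustes disparity M²: both point sets centered, scaled to unit trace
norm, optimally rotated with reflections allowed (chirality is
unidentifiable from distances), then the residual sum of squares, in
[0, 2]. The superposition is delegated to `scipy.spatial.procrustes`.
Coarsening a structure averages the coordinates of every `factor`
consecutive bins, with a trailing partial group.

## The synthetic system

The test bed is a deterministic 11-bin, 50 kb chromosome observed on days
0–5. Day 0 is a closed loop (a regular 11-gon of unit bonds — bins 0 and 10
in contact); day 5 is the fully elongated straight chain. Each frame is
generated from per-vertex turning angles of a unit-bond planar chain, so
consecutive-bin bond lengths are exactly 1 in every frame (inextensible
chain). Two variants share those endpoints:

- **unravel** — the loop is pulled open from both ends. Arm vertices
  straighten quadratically in time while the mid-loop hinge at bin 5 folds
  into a tight hairpin (per-day hinge angles 0.571, 1.366, 1.725, 1.725,
  1.52, 0 rad), keeping bins 4 and 6 within contact range through days 1–4
  with the tightest approach around days 2–3. The tabulated schedule was
  chosen so the end-to-end distance grows strictly monotonically (the ends
  are being pulled apart) and every pair distance changes smoothly between
  adjacent days — the property that makes intermediate days genuinely
  predictable from their neighbours.
- **swing** — the hinge releases cubically, so bins 4 and 6 separate from
  day 1 onward and the chain swings open with no transient mid-loop
  contact.

"Contact" is operationalized as a pair distance within **1.5 median bond
lengths** (scale-free, so it applies to fitted models whose absolute scale
is arbitrary). Simulated Hi-C applies `IF = d^(-1/γ)` per frame, optionally
followed by symmetrized Poisson resampling of counts at a stated scale
(default noiseless). What this emulates — and what it does not: the maps
are exact, fully dense, noise-free transforms of a planar, excluded-volume-
free chain at a single consensus conformation per day. Passing the
end-to-end tests therefore demonstrates the correctness of the
restraint/likelihood/optimization machinery, not robustness to sequencing
noise, population heterogeneity, normalization artifacts or sparse
coverage, which real data exhibit.

## Problem sizes and defaults

The packaged experiments run the full defaults — γ = 0.6, λ = 1e-4,
η = 1000, 400 epochs, seed 0 — on the 11-bin, 6-frame system (55 restrained
pairs per observed time), the scale at which the toy system is defined;
each fit takes well under a second. Granularity-stability checks compare
g = 6 against g = 11 on the same series; gradient validation uses random
instances with n ≤ 8, g ≤ 5 across 20 seeds.

## Known limitations

- A single consensus trajectory is fitted; ensemble variability of bulk
  Hi-C populations is out of scope, as are polymer-physics constraints
  (excluded volume, persistence length) and simulated-annealing or
  molecular-dynamics refinement.
- The model's absolute spatial scale is arbitrary; only relative geometry
  (ranks, correlations, Procrustes-aligned residuals) is meaningful.
- Inter-chromosomal maps, matrix balancing, and mixing resolutions within
  one series are not supported.
- The blended-log interpolation loss can in principle prefer one flanking
  restraint set on perfectly embeddable noiseless input (see Likelihood);
  `interp_mode="blend_targets"` is the remedy if that regime is suspected.
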