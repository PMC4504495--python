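# Methods

## The physical picture

A hydrophobic constriction in a channel pore behaves as a two-sided switch:
water in the 1.9-nm gate is either evaporated (dry, ~2 stray molecules) or
condensed into a connected column (wet, ~15 molecules), with rare, long
excursions to a stably superhydrated state (~22 molecules) in which the
pore has dilated.  Ion permeation is controlled by the hydration state: the
free-energy barrier for moving a hexahydrated divalent cation through the
gate falls roughly linearly with the gate water count.  The package
quantifies each layer of this picture — per-frame hydration metrics,
dwell-time kinetics of the wet/dry switch, pore geometry, umbrella-sampling
free-energy profiles, and the linear hydration–barrier model — and ships a
generator that produces synthetic ensembles with exactly this statistical
structure so that every estimator can be validated against known truth.

Units throughout: lengths nm, time ns (rates reported in 1/s), energies
kcal/mol, temperatures K.  k_B = 0.0019872 kcal/mol/K.

## Hydration metrics

`z_gap` is the largest distance between consecutive water-oxygen axial
positions inside the gate region, after inserting anchor entries at both
region ends.  The anchors implement "end-to-end" connectivity: a column
that does not reach both ends of the region leaves a large terminal gap.
A frame is wet when `z_gap <= 0.38 nm`, inclusive — the span of a
water–water hydrogen-bonded contact.  A frame with no waters has
`z_gap = region length`, not a missing value.

`N_wat` counts water oxygens in a closed cylinder: axial bounds of the
region and a lateral radius of 0.8 nm by default.  The lateral cutoff is a
design choice (slightly above the hexahydrated-Mg radius, wide enough to
include waters in transient lateral packing defects); it is configurable
and recorded in outputs.

The wetted-count table counts trajectories whose wet-frame percentage
passes each threshold (strictly positive for the ">0" row, inclusive
otherwise) and reports between-condition count ratios rounded half-even to
one decimal — half-even because it is the convention consistent with all
printed reference ratios (13/4 = 3.25 prints as 3.2).

SSH classification is a two-threshold rule: at least 20% of frames wet AND
at least 20% of frames with `N_wat` strictly above 20.  The dividing line
is a judgment call in the source analysis; both percentages are parameters
and are echoed in output metadata.

## Dwell-time kinetics

Episodes are maximal constant-state runs of the frame-sampled wet flag;
duration = run length × frame spacing.  The first and last runs carry
censoring flags.  Our convention: trajectories are initiated in a known
state at t = 0, so a first episode is a *fresh* dwell whose termination, if
observed, is an event; only right-censoring (the trajectory ends first)
suppresses the event.  For exponential dwell times this convention is
unbiased either way by memorylessness, but treating first episodes as
non-events would discard nearly every wetting transition in ensembles
where most trajectories wet at most once, biasing the wetting rate
severely (we measured −85% on synthetic truth).

The default survival estimator is Kaplan–Meier (lifelines implementation)
with right-censored episodes entered as censored observations; the naive
estimator S(t) = fraction of fully observed episodes with duration ≥ t is
the cross-check, represented as an exact right-continuous step function
with paired grid points at each event.  The two agree everywhere except at
the jump points, where they use ≥ versus > conventions.

Survival curves are fit by least squares to
S(t) = A·exp(−t/τ₁) + (1−A)·exp(−t/τ₂) on a 200-point log-spaced dwell
grid spanning the first positive grid time to the last observed event,
with linear interpolation between curve points (pure step lookup biases
the lifetime upward by about half a step).  A single-exponential fit
provides the starting values; τ₁ ≤ τ₂ is enforced to remove label
switching, and A is parameterized logistically.  The biexponential
solution is accepted only if it reduces the sum of squares below 0.2× the
single-exponential value; otherwise the fit collapses to one time
constant and is flagged.  The guard matters under heavy censoring (a
~122-ns dry lifetime observed through 35-ns windows): the second time
constant is then unidentifiable and an unguarded biexponential integral
can be arbitrarily wrong, while genuinely biexponential curves reduce the
SSE by far more than 5×.

The mean lifetime is the integral of the fitted form,
τ = A·τ₁ + (1−A)·τ₂; the first-order rate is k = 1/τ (wetting rate from
dry dwells, dewetting rate from wet dwells).  The half-life solves
S(t) = 1/2 by bracketing.  State free-energy differences use
ΔG = −k_B·T·ln(I_a/I_b), computed as a log difference so antisymmetry is
exact.  Temperature is a required parameter (default 310 K) and is echoed
in every free-energy output.

Uncertainties are split-half: the ensemble is divided into first/second
index halves (odd sizes give the larger first half, recorded), the
estimator applied to each, and the sd (ddof = 1) of the two values
reported.  A two-point sd has one degree of freedom, so a confidence
interval built from it must use the Student-t quantile at 1 df
(t₀.₉₇₅ = 12.706 on the sd of the mean); a naive ±1-sd interval from a
two-way split covers the truth only ~61% of the time
(P(|Z₁+Z₂|/√2 ≤ |Z₁−Z₂|) for independent normals is a Cauchy-ratio
probability, (2/π)·arctan√2), which is why the recovery studies report
coverage of the 95% t-interval.

## Pore geometry

The diameter algorithm is slice-based minimal radial clearance: at each
grid z, d_pore = 2·min over atoms within an axial slab (half-width 0.1 nm
by default) of (distance of the atom center from the pore axis − its van
der Waals radius), floored at zero.  Radii come from a Bondi-style table.
The pore axis is fixed to the laboratory z-axis through the gate backbone
center of mass — frames must be pre-aligned; no curved-axis tracing is
attempted.  Empty slabs inherit the nearest non-empty value and are
flagged.

Helix axes are first principal components of Cα runs, oriented along the
pore direction.  Tilt decomposition at a helix centroid off the axis: the
radial plane contains the pore axis and the outward radial direction, the
tangential plane the pore axis and the right-handed tangential direction;
the radial (lateral) tilt is the signed angle between the pore axis and
the helix-axis projection into the radial (tangential) plane.  The
radial/lateral plane definitions are a documented choice — the magnitudes
are the primary outputs, and all angle operations are invariant under
rigid motions applied consistently to points and reference frame.

## Umbrella sampling and WHAM

Windows are harmonic restraints U_i(z) = k_i(z − z_i⁰)²/2 on the ion's
axial position, spaced every 0.05 nm over −8 ≤ z ≤ 5 nm (261 windows).
Standard self-consistent discrete WHAM iterates

    p_b = Σ_i H_ib / Σ_i N_i exp((f_i − U_i(z_b))/kT),
    exp(−f_i/kT) = Σ_b ⟨exp(−U_i/kT)⟩_b p_b

until max |Δf_i| < 10⁻⁷ kcal/mol (max 10⁵ iterations; non-convergence
returns a flagged partial result).  Two numerical choices matter:

- **Bin-averaged bias kernels.**  ⟨exp(−U_i/kT)⟩_b is averaged over each
  bin by 7-point midpoint quadrature rather than evaluated at the bin
  center.  With stiff springs the biased distributions are not much wider
  than a bin and center evaluation introduces a systematic profile bias.
- **Bin width must resolve the profile.**  Discrete WHAM assumes the
  unbiased density is flat within a bin.  For a 45-kcal/mol Gaussian
  barrier (width 0.35 nm) the profile changes ~4 kcal/mol across a
  0.05-nm bin and that assumption fails badly — we measured a ~20% barrier
  underestimate accumulating along the steep flanks.  The default bin
  width is therefore 0.01 nm, and the stiffest study uses 0.005 nm.

Window free energies are initialized by stitching: for neighboring
windows, f_j − f_i = kT·ln(p̂_j(b)/p̂_i(b)) + U_j(b) − U_i(b) averaged over
jointly occupied bins with count weights, chained across the window order.
This initialization is typically within ~0.5 kcal/mol of the fixed point
and cuts the iteration count by orders of magnitude.  Histogram overlap
between neighboring windows is checked and a missing overlap raises a
diagnostic naming the gap.

Profiles are zeroed on a bulk reference interval, default (−8, −6) nm
(the flat cytosolic approach); the gate barrier is the maximum of G over
the gate interval (default (−1, 1) nm) minus the bulk mean, invariant
under constant shifts.  Per-bin uncertainties come from an optional
bootstrap that resamples each window's samples.  The equilibration-block
analysis re-runs WHAM on [t_eq, t_eq + production) sample slices and
reports the barrier per discard; for a stationary sampler it is
discard-invariant, which is the test of convergence.

Spring constants for the recovery studies are matched to profile
stiffness: every window must sample its neighborhood unimodally, which
requires k exceeding the maximum curvature |G''| = H/σ² of a barrier of
height H and width σ (≈ 8.2·H for σ = 0.35 nm), while softer springs give
better neighbor overlap and a smaller window-to-window random walk in the
recovered f_i.  The studies use k = 150/500/1000 kcal/mol/nm² for
H = 5/25/45 kcal/mol and k = 30 for the flat null.

## The gating model

Ordinary least squares gives ΔG‡ = a − b·N_wat and d̄ = c + m·N_wat.
Integer reporting conventions: the open-state hydration a/b is truncated
(floor), which reproduces both reference extrapolations (46/0.82 → 56,
92/1.82 → 50); barrier predictions round to the nearest integer; diameter
values round half-away-from-zero at the printed precision, with a
10-decimal snap first so that accumulated float fuzz (0.70499999…) does
not flip a printed 0.705 → 0.71.  The model is deliberately linear and the
code computes its arithmetic only; nothing here claims the linear
extrapolation identifies the true open state.

## What the generator emulates — and what it does not

`simulate_wetting_ensemble` draws exact event-driven realizations of a
continuous-time Markov chain (dry ⇌ wet, optionally ⇌ SSH), samples the
state at frame times (point sampling, as MD frames are snapshots), draws
`N_wat` per frame from state-conditional distributions — Poisson(2) for
dry, rounded N(15, 3) for wet, a right-skewed skew-normal around 22 (σ 4)
for SSH, all truncated at zero — and couples the mean gate diameter as
d̄ = 0.37 + 0.0067·N_wat + N(0, 0.01) nm.  Axial water positions are
placed uniformly with connectivity repair: wet frames are repaired until
the anchored gap is ≤ 0.38 nm (relocating the most redundant water into
the widest gap), dry frames carve out a dehydrated window wider than the
threshold.  Default study conditions: 700 trajectories × 35 ns, wetting
rate 8.2×10⁶ 1/s, dewetting rate fixed by ~1% stationary wet occupancy;
frame spacing 0.02 ns (point-sampling bias on apparent dwell times scales
as (k_wet + k_dewet)·dt/2, under 1% at this spacing).  All generators are
bit-reproducible under a fixed seed.

The generator reproduces the *statistical* structure the estimators
assume, which is exactly what makes recovery tests meaningful — and what
limits them.  Real trajectories have correlated frames, non-exponential
(conformation-coupled) dwell times, slowly relaxing channel conformations,
waters entering through lateral packing defects, and diameter dynamics
with memory; none of these are modeled.  Passing recovery tests shows the
estimators are correct on clean two-state data at study scale, not that
real CorA kinetics are two-state.  Likewise the umbrella sampler draws
i.i.d. Boltzmann-exact samples (inverse-CDF on a 0.002-nm grid), so WHAM
recovery tests measure estimator bias and Monte-Carlo noise, not MD
autocorrelation effects; a decorrelation-subsampling option is the hook
for real data.

The generator's free-energy gap between dry and wet,
−kT·ln(occ/(1−occ)) ≈ 2.8 kcal/mol at 1% occupancy and 310 K, follows
from the prescribed rates; it is reported alongside — and is distinct
from — the 4.2 kcal/mol value that follows from the reference survival
integral ratio of 1.1×10⁻³, which the free-energy formula reproduces
directly.

## Problem sizes and runtime

The shipped studies are sized for a single CPU: the kinetics recovery runs
50 seeded repeats of the 700 × 35 ns ensemble (~20 s total); the WHAM
studies sample 261 windows × 10–30 k samples per profile (~1–2 min for
all four).  Both the test suite and the acceptance script run everything
at these sizes.

## Known limitations

- Degenerate biexponential fits near A → 0 or 1 report τ₁ ≈ τ₂; the
  amplitude itself is then not meaningful (the integral is).
- Kaplan–Meier assumes censoring is independent of dwell length; trajectory
  windows of fixed length satisfy this only approximately for dwells
  comparable to the window.
- WHAM uncertainties by window bootstrap ignore cross-window correlation of
  the reference zeroing; they are per-bin spreads, not a full covariance.
- The diameter profiler reports the clearance around a straight axis;
  strongly kinked pores need a curved-axis method.
- `hydration_for_diameter` inverts a fitted line; far outside the fitted
  hydration range the conversion is extrapolation, as is the open-state
  water count itself.
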