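# poregate

Analysis of hydrophobic gating in ion-channel pores, built around the CorA
magnesium channel: a narrow hydrophobic constriction (the "MM stretch", a
1.9-nm stretch of the pore lined by M291, L294, A298 and M302) that is dry
in the closed channel and must condense a connected water column before an
ion can pass.  The package is written for structural-MD analysts who have
ensembles of short trajectories (or umbrella-sampling windows) and want the
quantitative gating picture: how often the gate wets, how fast, and what
that does to the ion-permeation barrier.

## What it computes

**Hydration metrics** (`poregate.hydration`).  Per frame, the water count
in the gate region, `N_wat`, and the largest axial distance between
consecutive water oxygens, `z_gap`, computed with anchor points at the
region ends so "wet" means an end-to-end connected column:
`wet ⇔ z_gap ≤ 0.38 nm` (a water–water contact).  On top of these:
ensemble wetting-fraction time courses P(t), tables counting simulations
wetted for at least a given percentage of frames (with between-condition
ratios), normalized `N_wat`/`z_gap` distributions, and classification of
stably superhydrated (SSH) trajectories (`N_wat > 20` for a sustained
fraction of frames).

**Wetting kinetics** (`poregate.kinetics`).  Maximal wet/dry dwell episodes
with censoring flags, survival curves S(t) (Kaplan–Meier or naive), fits to
a double-exponential decay `S(t) = A·exp(−t/τ₁) + (1−A)·exp(−t/τ₂)`, mean
lifetimes τ = A·τ₁ + (1−A)·τ₂, first-order rates k = 1/τ, split-half
uncertainties, and state free-energy differences
`ΔG = −k_B T ln(I_a/I_b)` from ratios of survival integrals.

**Pore geometry** (`poregate.geometry`).  Slice-clearance pore-diameter
profiles d_pore(z), region-averaged diameters, helix principal axes with
radial/lateral tilt decomposition, bend angles, and the Pearson/OLS
statistics linking geometry to hydration (e.g. the dilation law
`d̄_pore = 0.37 + 0.0067·N_wat` nm).

**Free-energy profiles** (`poregate.pmf`).  Self-consistent discrete-
histogram WHAM over harmonic umbrella windows, with bin-averaged bias
kernels, stitched initialization, window-overlap diagnostics, bootstrap
uncertainties, equilibration-block convergence analysis, and gate-barrier
extraction ΔG‡ = max G over the gate minus the bulk reference.

**The gating model** (`poregate.gating`).  The linear hydration–barrier
relations `ΔG‡ = 46 − 0.82·N_wat(t₀)` and `ΔG‡ = 92 − 1.82·N_wat(US)`
kcal/mol and their arithmetic consequences: the extrapolated open-state
hydration (56 and 50 waters), barrier predictions at stated hydration
levels, and hydration↔diameter conversions against the 0.68-nm diameter of
hexahydrated Mg²⁺.

**Synthetic ensembles** (`poregate.synthetic`).  A first-class generator of
study-scale test data: two/three-state continuous-time Markov wetting
dynamics with state-conditional water counts (dry ≈ 2; wet ~ N(15, 3);
SSH skewed around 22), hydration-coupled pore diameters, axial water
placements with controlled connectivity, Boltzmann-exact umbrella samples
for any prescribed 1-D profile, and ring-atom pore fixtures of analytically
known diameter.

## Worked example

```python
import numpy as np
from poregate import gating, kinetics, synthetic

# fit the barrier model to points on the published line and extrapolate
n = np.arange(10, 45, 5)
model = gating.GatingModel(
    barrier_fit=gating.fit_barrier_model(n, 46.0 - 0.82 * n),
    diameter_fit=gating.fit_barrier_model(n, 0.37 + 0.0067 * n))
print("open-state N_wat:", gating.open_state_hydration(model))
print("barrier at N_wat=32:", round(gating.predict_barrier(model, 32)), "kcal/mol")
print("diameter at N_wat=56: %.2f nm" % gating.diameter_for_hydration(model, 56))

# recover the wetting rate from a massively repeated synthetic ensemble
wm = synthetic.default_wetting_model()          # 8.2e6 1/s, ~1% wet occupancy
ens = synthetic.simulate_wetting_ensemble(wm, n_traj=700, duration=35.0,
                                          dt=0.02, seed=42)
est = kinetics.ensemble_rates(ens, state="dry")  # wetting = escape from dry
print(f"wetting rate: {est.rate:.2e} +/- {est.uncertainty:.1e} 1/s")
print(f"mean dry lifetime: {est.fit.mean_lifetime:.0f} ns")
```

prints

```
open-state N_wat: 56
barrier at N_wat=32: 20 kcal/mol
diameter at N_wat=56: 0.75 nm
wetting rate: 7.55e+06 +/- 2.8e+05 1/s
mean dry lifetime: 133 ns
```

The extrapolations say: a channel whose gate holds 32 waters still presents
a 20 kcal/mol barrier (closed), and the barrier vanishes around 56 waters,
i.e. a mean gate diameter of 0.75 nm — slightly wider than hexahydrated
Mg²⁺.  The recovered wetting rate sits within 10% of the generator's true
8.2×10⁶ s⁻¹ (a ~120-ns mean dry lifetime, measured from 35-ns windows via
Kaplan–Meier survival of dry dwells).

The same stages are scriptable from a shell:

```
poregate simulate --n-traj 700 --duration 35 --dt 0.02 --seed 1 --out traces/
poregate hydration traces/ --out series/
poregate kinetics series/ --out kinetics.json
poregate gate-model --coefficients 46,0.82 --predict-at 32,50 --out gate.json
poregate run --config demo.yaml --out results/
```

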