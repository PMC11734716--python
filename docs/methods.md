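# Methods

## The growth model

Development is modeled as quarter-power ontogenetic growth
(West–Brown–Enquist form, as used by Gillooly and colleagues for
temperature scaling):

    dm/dt = a(T) · m^z · [1 − (m/M)^(1−z)],    z = 3/4,

with asymptotic mass `M` and a rate coefficient `a` whose temperature
dependence is a Boltzmann factor `exp(−E/(K·Tk))` with activation energy
`E` (eV), Boltzmann constant `K = 8.617×10⁻⁵ eV/K` and absolute
temperature `Tk`. Expanding about the water freezing point `Ta = 273 K`
and writing `T` for temperature in °C,

    a(T)/a(0 °C) = exp[ E/(K·Ta²) · T/(1 + T/Ta) ] ≈ exp[ E/(K·Ta²) · T ].

The linearized form is the package default because the empirical scaling
factors are defined against it; the exact form is kept for quantifying the
approximation (the relative exponent error is `T/(Ta+T)`, ≈10% at 32 °C).

Integrating the growth law in the small-mass regime (`m ≪ M`) and assuming
eclosion at a temperature-independent mass gives two exponential
fold-change laws relative to the reference temperature `T0 = 25 °C`:

    t/t0 = exp[−α·(T − T0)],          α = E/(K·Ta²)       (developmental time)
    n/n0 = exp[−β·(T − T0)],          β = 4·ΔE/(K·Ta²)    (synaptic partners)

where the brain grows with its own activation energy `E′ = E − ΔE < E` but
for the body-set duration. With the fitted factors `α = 0.128 /°C` and
`β = 0.133 /°C` this yields `E = 0.822 eV`, `ΔE = 0.214 eV`,
`E′ = 0.61 eV`. At a matched fraction of ontogenesis the brain state of a
cold-reared fly is ahead by exactly the connectivity fold change,
independent of the fraction — the model-side content of the staging
comparison.

### Numerical treatment of the ODE

`solve_growth` integrates in the substituted coordinate
`u = (m/M)^(1−z)`, in which the dynamics are the linear relaxation
`du/dt = k·(1−u)` with `k = (1−z)·a·M^(z−1)`. The substitution removes the
non-Lipschitz fixed point at `m = 0` (the model's initial condition after
metamorphic pruning), which no integrator working in the raw mass
coordinate can leave. The solve remains numerical (`solve_ivp`, RK45,
rtol 10⁻⁸, max step `t_end/20`); the closed-form sigmoid
`(m/M)^(1/4) = 1 − e^(−a·t/(4·M^(1/4)))` is used only as a regression
oracle in the tests. Output masses are clipped to `[0, M]` and projected
onto their monotone envelope to absorb solver roundoff (~10⁻⁹).
Developmental time is operationalized as the ODE time-to-target event for a
target mass of `10⁻³·M`, small enough that the exponential law holds to
10⁻⁴ across 12–31 °C.

## Temperature cycles

For a symmetric two-level cycle with mean `T̄` and half amplitude `ΔT`,
splitting the integrated growth between the two levels gives

    t̃/t̄ = 1/cosh(α·ΔT),        ñ/n̄ = [cosh(γ·ΔT)/cosh(α·ΔT)]⁴,

with `γ = α − β/4`. Since `γ < α`, every nonzero amplitude yields fewer
connections than constant development at the mean: the warm phase
dominates the integrated development.

The general integrator handles arbitrary periodic waveforms (e.g. the
experimental 8-h hold / 4-h linear ramp protocol). Because development
spans many cycles, each quantity depends on the waveform only through the
period averages of the relative rates `exp[s·(T(τ)−T̄)]` for `s ∈ {α, γ}`;
the implementation computes these averages with a per-segment closed form
(the integrand is exponential in time on every linear segment), which is
exact for piecewise-linear waveforms including discontinuous steps. This
is why the square-wave route agrees with the cosh laws to machine
precision rather than to quadrature error. Callers integrating short
developments can pass the number of elapsed periods; below 20 periods a
warning flags that phase dependence may not have averaged out. The
minimum-temperature dwell of the protocol is assumed symmetric to the
maximum dwell (8-h hold, 4-h ramp), since only the max-to-min transition
is specified by the protocol text.

## Fitting the scaling factors

Observations are normalized by the **mean** value at the reference
temperature, and `s` in `fold = exp(−s·ΔT)` is estimated by least squares
on the fold-change scale (default) or on the log scale (cross-check). The
one-parameter least-squares problem is solved by bounded Brent
minimization (`|s| ≤ 3 /°C`, xatol 10⁻¹²), which matches an exhaustive
grid search to 10⁻⁴ and is fast enough for ~2×10⁵ refits in the
bootstrap/recovery loops.

Uncertainty: nonparametric bootstrap resampling individuals with
replacement within each temperature group, renormalizing and refitting per
replicate (default 1000 replicates, seeded). Because within-group
resampling underestimates sampling variance when groups are tiny, the
bootstrap SE is inflated by `√(N/(N−G))` (`N` individuals, `G` groups) and
the 95% interval is a t interval with `N−G` degrees of freedom. At the
study design (20–38 per temperature) the correction is negligible (~2%);
at 2 per temperature it is what keeps empirical coverage near nominal.

The recovery experiment simulates full datasets from the generators below,
refits each, and reports bias, RMSE and CI coverage. The approximation
check generates noise-free times from the exact Arrhenius exponent and
fits the linearized law; over {12, 18, 25, 31} °C the discrepancy is ≈12%,
consistent with the ~10% figure quoted for this approximation.

## Connectome reduction

Glomeruli are assigned by k-means on 3D synapse coordinates (seeded,
10 restarts); no algorithm is canonical for this step, and centroid
clustering suffices for the blob-like geometry of glomeruli. Partner
allocation applies, in order: (i) drop pre→post connections with <3
synapses from a single ORN, (ii) sum per postsynaptic neuron, (iii) drop
partners with <10 total synapses, (iv) normalize, (v) rank by descending
count with ties broken by post id. Normalization is over synapses
surviving both filters, so retained fractions sum to 1 and are comparable
across glomeruli; normalization over the pre-filter total is available via
a flag, since the text defining the procedure does not fix this choice.
The reporting-threshold estimator returns the smallest integer `s` such
that at most the observed number of partners exceeds `s` synapses — the
logic used to conclude that an anterograde tracer reports partners above
roughly 10 synapses. The innervation symmetry index is
`100·(L−R)/(2·(L+R))`, antisymmetric and bounded in [−50, 50].

## Behavioral metrics

Treadmill responses: per trial, mean speed in the 2 s after odor onset
minus the mean over the 3 s before; flies with session-average basal speed
below 2 mm/s are excluded from the per-fly mean (exclusion is per fly, not
per trial). Free-walking occupancy: the fraction of flies within 5 cm of
the source per frame, integrated by trapezoid over the first 7 min and
normalized by the window, so 1 means every fly spent the whole window at
the source. Walking speed is computed from positions by central
differences at the native frame rate (20 fps).

The pooled speed distribution is summarized as a probability-mass
histogram (1 mm/s bins): the mass below 1 mm/s is the inactive peak (the
cut is configurable; no canonical boundary exists), and a Gaussian
`a·exp[−((x−b)/c)²]` is least-squares fitted to the bins above the cut.
On the probability-mass scale the amplitude `a` is a probability in
(0, 1] and tracks activity level; `b` is the mean active speed (mm/s) and
`c` the width. Parameter CIs come from the fit covariance. Degenerate
inputs (no active samples, identical speeds) raise a fit error rather
than returning meaningless parameters.

## Synthetic data

The generators are pure functions of their configuration (seeded numpy
Generators per stream) and emulate the study conditions:

- **Partner counts** — negative binomial around `n0·e^(−β·(T−T0))`
  (β = 0.133, T0 = 25 °C) at {12, 18, 25, 31} °C with group sizes
  {25, 30, 38, 20}, inside the reported 20–38 hemibrains per temperature.
  Dispersion 20 gives variance ≈ mean·(1 + mean/20), a moderate
  overdispersion; the source data show spread but state no distribution.
- **Developmental times** — lognormal around `t0·e^(−α·(T−T0))`
  (α = 0.128) with CV 0.08. The absolute scales `n0 = 20` partners and
  `t0 = 10` days are placeholders: the real values appear only in figures
  and every downstream statistic uses fold changes, which are invariant
  to them.
- **Synapse tables** — planted (pre, post, count) structure per
  glomerulus, coordinates from isotropic Gaussian blobs; running the table
  through allocation with filters disabled reproduces the plant exactly.
- **Trajectories** — stop/go two-state Markov chain (rates 0.1/0.2 per s,
  giving one-third inactive time), bout-constant speeds from the Gaussian
  density with b = 8 mm/s, c = 3 mm/s, heading diffusion 0.7 rad/√s
  (decorrelation over ~2 s, as for walking flies), optional heading bias
  toward the source, reflecting walls. Speeds are constant within a bout
  because a finite-difference speed estimate can only recover bout-level
  speeds; per-frame white-noise speeds would be averaged down by any
  realistic tracker.

What the generators do **not** emulate: thigmotaxis and wall-following,
inter-fly interactions, odor-plume structure, temperature-dependent
locomotor changes, or any anatomical realism beyond blob geometry. Tests
passing on these data therefore validate the estimators' correctness and
calibration under the assumed noise models, not their behavior on real
recordings.

## Problem sizes

Defaults were chosen so a full test run and the analysis scripts complete
on a laptop-class single core: 200 replicates × 1000 bootstrap refits for
the recovery experiment, 10⁴-sample distributional checks, 15–40 flies ×
15–20 min of simulated tracking. All are configuration parameters.

## Known limitations

- The exponential developmental-time law is known to fail above ~30 °C;
  no saturation term is implemented, so predictions at the hottest cycle
  extremes (34 °C) inherit that bias.
- The step-cycle closed forms assume equal dwell at the two levels;
  asymmetric duty cycles must go through the general integrator.
- Bootstrap calibration was verified for the negative-binomial and
  lognormal noise models only.
- k-means glomerulus assignment assumes roughly isotropic, comparably
  sized glomeruli; strongly elongated or nested neuropils would need a
  different clusterer.
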