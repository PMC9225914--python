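# Methods

## The model

Mild moxibustion holds the glowing end of a moxa stick a few centimetres
above the skin; the skin is heated almost entirely by thermal radiation,
and the therapeutic question is how deep the heat penetrates.  The package
models one treatment as three coupled pieces.

**Tissue.**  A cylindrical block of three strata — skin (2.2 mm), fat
(12.4 mm), muscle (10.4 mm); lateral radius 50 mm — obeying the Pennes
bioheat equation

    ρc ∂T/∂t = ∇·(k∇T) + ω_b C_b (T_b − T) + q_m + q_r ,

with ρ, c, k per stratum (skin 1109 kg m⁻³ / 3391 J kg⁻¹K⁻¹ /
0.37 W m⁻¹K⁻¹; fat 911 / 2348 / 0.21; muscle 1090 / 3421 / 0.49), blood
specific heat C_b = 3617 J kg⁻¹K⁻¹ at T_b = 37 °C, metabolic heats
q_m = 368 / 180 / 420 W m⁻³, and perfusion rates ω_b discussed below.
Boundary conditions: Dirichlet core temperature (37 °C) at the bottom,
zero flux on the axis and the lateral wall, radiative exchange on the top.
The moxibustion point is the surface point on the stick axis; the
*reference point* sits 5 mm beneath it and is the thermal-penetration
indicator throughout.

**Source.**  The burning end is a sphere of the stick radius whose
temperature follows a slow cosine envelope
T_a(t) = (T_max − A) + A·cos(2πt/P) with amplitude A = 200 °C and default
period P = 500 min, interrupted once per minute by 5 s ash-cleaning
windows at 50 °C.  Two readings of the printed burning-curve constant
(P = 500 s, or a 60 s cycle locked to cleaning) were implemented and
rejected quantitatively: an oscillating ember with a 400 °C swing forces
multi-degree skin-temperature swings that no physical parameter choice can
reconcile with the measured series (best attainable max deviation ≈ 14%
under either reading), whereas the slow-envelope reading matches both the
measured trajectory and the reference simulation's monotone
rise-then-plateau shape.  The period remains a configuration knob.
Cleaning windows are open intervals starting just after the whole-minute
tick, so samples taken exactly on the minute (the validation cadence) are
pre-cleaning values.

**Radiative coupling.**  Each surface element exchanges with the sphere
(view factor F = R²H/(H² + r²)^{3/2}, the exact closed form for a sphere
wholly above the element's plane) and with the surroundings at ambient
temperature (view factor 1 − F).  Irradiation
G = F·ε_src·e_b(T_a) + (1−F)·e_b(T_amb) with e_b = n²σT⁴, and the skin
absorbs q_r = ε_skin(G − e_b(T_skin)).  Skin reflection (ρ_d = 0.02) is
not returned to the source (single bounce; the correction is below 0.1%).
Defaults ε_src = 0.90 (glowing ember), ε_skin = 0.98; both are exposed to
calibration.  Temperatures are Celsius everywhere except inside the
radiation formulas.

## Two-regime perfusion

Perfusion is the one genuinely unmeasured, strongly temperature-dependent
parameter.  Two printed observations are incompatible with a single
constant perfusion: the pre-treatment surface temperature (34.3 °C
disk average) is the signature of *resting* skin (ω_b ≈ 0.5 kg m⁻³s⁻¹),
while the flat ≈ 44 °C plateau the measured series reaches within three
minutes requires roughly tenfold stronger perfusion — which is exactly
what local heating to 42–44 °C produces physiologically (near-maximal
cutaneous vasodilation).  The package therefore uses a two-regime model:

- `initial_state` solves the no-source steady state with *rest-state*
  perfusion, obtained by scaling the scenario's rates so the 5 mm
  disk-average surface temperature matches the measured baseline (within
  0.05 °C; a bracketed scalar root-find).
- The treatment transient runs at the scenario's *treatment-state* rates,
  which `calibrate` fits within bounds spanning resting to hyperemic
  values (skin 0.2–12, fat 0.05–5, muscle 0.2–8 kg m⁻³ s⁻¹).

A smooth temperature-dependent ω_b(T) would be the refined version; the
two-state form is the minimal model that captures the vasodilation step
and keeps the equation linear within each solve.

## Discretization and numerics

Axisymmetric (r, z) vertex-centred finite volumes on a nonuniform tensor
grid; the 3-D scenario is rotationally symmetric, so this is exact
physics at a fraction of the cost.  Default spacing 0.5 mm, refined to
0.25 mm within the 5 mm-radius surface disk and the top 5 mm of tissue;
layer interfaces and the 5 mm reference plane are grid vertices.
Conductances are assembled interval-by-interval, so control volumes
straddling an interface carry the exact series (harmonic-mean)
conductance and piecewise-linear steady profiles are reproduced to
round-off.  Time integration is a one-step θ scheme (backward Euler,
θ = 1, dt = 0.5 s by default) with the sparse operator factorized once
(SuperLU) and reused across the run.  The T⁴ surface flux is lagged in a
Picard loop on the surface temperature (tolerance 1e-6 relative, ≤ 10
iterations; it converges in 2–3 because the radiative conductance,
~6 W m⁻²K⁻¹, is tiny against the surface-cell thermal mass per step).
Probes are recorded every 30 s.  Halving dr, dz and dt moves the
standard run's reference-point temperature by less than 0.1 °C (asserted
in the suite).

Degenerate inputs: cleaning with zero duration disables the windows; a
single-level sweep reduces to one run; an empty calibration free set
returns the base scenario; constant DOE responses give all-zero ranges
and sums of squares (F ratios undefined, reported as NaN).

## Calibration and validation

The validation scenario (18 mm stick, 4 cm distance, 15 min, ambient
25 °C, baseline 34.3 °C) is compared with the measured series at its 31
half-minute timepoints; the deviation convention is
100·(simulated − experimental)/simulated, the convention under which the
published deviation rows reproduce.  `calibrate` minimizes the maximum
absolute percent deviation over the free parameters (default: the three
treatment-state perfusion rates and the source emissivity) with bounded
Nelder–Mead, started from the bound midpoints with a seeded initial
simplex (deterministic per seed), ≤ 60 objective evaluations of roughly
4 s each.  Failure to reach the 5% bound is reported, never hidden.

## The orthogonal experiment

Four factors at three levels — A: peak burning temperature 600/625/650 °C,
B: stick diameter 12/15/18 mm, C: distance 25/30/35 mm, D: ambient
17/25/32 °C — on the standard L9(3⁴) array; the response is the final
reference-point temperature.  Range analysis: level means K_l (printed as
K), the level-sum/9 variant K̄, R = max K_l − min K_l, optimal level per
factor by argmax, factors ranked by descending R (ties broken by name
order with a warning).  ANOVA: SS = 3·Σ_l(K_l − grand mean)², 2 df per
factor; the design is saturated (zero residual df), so the error mean
square is pooled — the mean of the four factor mean squares by default, or
the smallest factor's mean square under `pool-smallest-factor` — and the
significance stars are a display convention keyed to the F ranking, not
an inferential claim.  Display rounding is half-up to 2 decimals; full
precision is kept on the result objects.

## Synthetic data

`SyntheticDoeSpec` plants an additive model (grand mean + zero-sum
per-factor level effects + Gaussian noise, seeded) on the L9 design; it
emulates the statistical structure the orthogonal analysis assumes and
nothing else — no curvature, no factor interactions, no heteroscedastic
measurement error.  Recovery tests on it show the analysis machinery is
correct, not that real moxibustion responses are additive.  The analytic
conduction problems (uniform perfused equilibrium, semi-infinite constant
flux, two-slab steady state, pointwise perfusion relaxation) are
closed-form limits of the bioheat equation used as independent solver
oracles; tolerances are 2% (semi-infinite, early times), 0.5% (two-slab,
met to round-off), 1% (relaxation) and solver tolerance (equilibrium).

## Problem sizes

Default runs use the 111 × 61 node grid (6771 unknowns) and 1800 implicit
steps per 15-minute treatment (~4 s per run); the grid-convergence check
runs one treatment at 221 × 116 nodes and 3600 steps.  The DOE recovery
test uses 200 seeded replicates; the view-factor oracle uses 6 × 10⁶ rays
per geometry.

## Known limitations

- Constant material properties; no temperature-dependent conductivity or
  a continuous ω_b(T) (the two-regime form is a step approximation).
- No convective or evaporative surface loss (radiation only), consistent
  with the modelled scenario but not with ventilated rooms or sweating.
- The burning end is a full sphere; a spherical cap with an ash-shadowed
  upper half would change the view factor by a geometry-dependent factor
  absorbed here into ε_src.
- No tissue damage (Arrhenius) model; the therapeutic-window statements
  are purely thermal.
- The saturated L9 ANOVA cannot produce honest p-values; only factor
  ordering is meaningful.
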