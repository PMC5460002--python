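# Methods

## Groundwater model

Each spring is treated as the outlet of a one-dimensional, homogeneous,
isotropic aquifer of slope α resting on an impermeable base, extending from
the spring (x = 0) to the watershed divide at `Bx = B/cos α` measured along
the base. The water table η(x, t) obeys the linearized Boussinesq equation

    n_e ∂η/∂t = k₀ η₀ cos α ∂²η/∂x² + k₀ sin α ∂η/∂x + R(t)

with a Dirichlet condition at the outlet (η = 0, the linearization datum —
the exact outlet head is not identifiable within the linearization and only
shifts the datum) and zero flux `k₀η₀cos α ∂η/∂x + k₀ sin α η = 0` at the
divide. The linearization replaces the saturated thickness with η₀ = pD,
p = 0.3, D = 100 m by default. Recharge enters per unit length of aquifer
base, so the steady outlet discharge per unit width is exactly `q = R·Bx`
and the steady total flow is `Q = A·q/B = R·A/cos α` (exactly `R·A` for a
flat aquifer — 1 mm/y over 1 km² sustains precisely 1,000 m³/y).

In dimensionless form (x* = x/Bx, t* = t·D*/Bx², D* = k₀η₀cos α/n_e) the
problem has one shape parameter, the slope number

    Hi = Bx · tan α / η₀ ,

the ratio of gravity-driven drainage to diffusive relaxation.

Three closed-form solutions are implemented in `boussinesq`:

* **Sudden-cessation recession.** After recharge steps from R₀ to a floor
  R_f at t = 0, the discharge is `q(t) = R_f·Bx + (R₀−R_f)·Bx·g(t*)` with
  g an eigenfunction series over the positive roots of `tan z = −2z/Hi`
  (decay rates `z_n² + Hi²/4`). Coefficients are the eigen-projections of
  the steady profile, evaluated in closed form; the eigencondition is used
  to simplify the antiderivatives. Truncation is adaptive: terms are added
  until the exact flux-sum identity Σĉ = 1 is met within 1.5×10⁻³ (0.1× the
  1% tolerance adopted for persistence metrics), capped at 500 terms; the
  residual mass is carried as a smooth tail term decaying at the first
  omitted rate, which keeps g(0) = 1 exact and g monotone.
* **Periodic response.** For `R(t) = R_av + R_amp sin ωt` the dynamically
  steady response (transients excluded) is `q = R_av·Bx +
  R_amp·Bx·Im[G e^{iωt}]` with a complex transfer function G obtained from
  a two-point boundary-value problem; |G| ≤ 1 is the attenuation and
  −arg(G)/ω the lag. The two-point solve uses per-root scaled exponential
  bases so it is stable for any Hi and any frequency.
* **Steady state.** `η_s(x*) = r[(Hi+1)/Hi²(1−e^{−Hi x*}) − x*/Hi]` (flat
  limit `r(x* − x*²/2)`), maximum at `x* = ln(1+Hi)/Hi`. The maximum head is
  exactly linear in R, so the largest recharge consistent with the water
  table staying below the surface (taken as the saturated-thickness cap
  η* ≤ D) has a closed form; `refine_recharge` applies it directly rather
  than by iteration.

### Numerical evaluation across slope numbers

The recession eigenseries carries coefficients of magnitude ~e^(Hi/2) with
alternating signs. Beyond Hi ≈ 20 the float64 cancellation and the slowing
tail convergence make it unusable, so for Hi ∈ (20, 200] the identical
solution is evaluated through its closed-form Laplace transform
(`ĝ(s) = 1/s + v′(0)` with v the solution of a constant-forcing Helmholtz
problem) inverted by the fixed-Talbot rule (M = 32). The two routes agree to
~10⁻¹⁰ at moderate Hi, and the Talbot route matches fine-grid
finite-difference solutions to <0.2% across Hi ∈ [20, 200] down to
g ~ 10⁻⁸. A negligibility cutoff (slowest-mode bound
e^{Hi/2 − λ₁t} < 10⁻²⁰ ⇒ g = 0) suppresses inversion noise at extremely
late times. Above Hi = 200 the transform values in the left half-plane
exceed what the float64 contour can cancel, and the recession raises an
informative error: with η₀ = 30 m, Hi = 200 corresponds to ~6 km of relief
along a single flow path, beyond any real aquifer.

### Persistence metrics

`persistence_sudden` returns τ = inf{t : Q(t) < threshold} by bisection in
log-time (0 if the initial steady flow is already below threshold; capped
at 10⁶ y, reported as capped, when the floor alone sustains the threshold).
`persistence_periodic` exploits that the cycle minimum of Q is
non-increasing in the period P (longer cycles let the aquifer equilibrate
to the dry phase) and bisects P on [1, 23 000] y; 23 000 y (capped) marks a
spring persistent through a precessional cycle. The default threshold,
1,000 m³/y, decomposes into ~750 m³/y of animal drinking water (~2,000
l/day) plus a ~100 m² wetland transpiring 2,500 mm/y (250 m³/y). The default
dry-phase floor is 1 mm/y, a conservative arid-zone recharge; a 0 mm/y
variant is available.

The groundwater response time GRT = B²/D_h, with sloping-aquifer hydraulic
diffusivity D_h = T/(n_e cos α), uses transmissivity T = k₀η₀ = k₀pD,
consistent with the linearization. The alternative convention T = k₀D would
scale every GRT down by exactly 1/p ≈ 3.3 and every persistence time with
it; because GRT is a power-law in all parameters, the choice shifts
populations rigidly on a log axis and does not affect ordering, curve
shapes, or the regression of recession time on GRT. The ±25% one-at-a-time
sensitivity table (`oat_sensitivity`) exposes the D-dependence directly
(GRT ∝ 1/D).

## Uncertainty propagation

Parameters are perturbed as independent truncated normals (rejection at the
physical bounds, counts logged): 10% of the mean for the mapped quantities
B, A, α; 25% for D; and externally supplied SDs for the hydraulic
properties k₀ and n_e, whose uncertainty would in reality come from a
global hydraulic-property atlas — the default 20% of the mean is a
documented stand-in. The Monte Carlo ensemble propagates uncertainty
through GRT (cheap, and persistence is strongly GRT-correlated) rather
than through the full persistence solution; a full-persistence ensemble
(`mce_persistence`) exists for small populations. The ensemble summary is
the half-width of the envelope of per-realization population CDFs of GRT,
in percentage points, with the location of the maximum (the steepest part
of the curve) reported.

## Population surveys

`persistence_curve` reports the fraction of springs still active at the
driest point of a climate change per timescale (25 log-spaced points, 1 y
to 23 ky), for both transition end members: gradual (cycle minimum of the
periodic response) and sudden (flow at t = timescale into the recession).
Monotone decline is asserted on every call. `persistence_vs_recharge_cdf`
compares the recharge distributions of all springs, of the springs active
at a given period, and of the regional recharge field below a 60 mm/y
cut-off; a persistent-spring CDF shifted toward drier catchments indicates
that hydrogeology, not modern climate, controls persistence. The
GRT–recession regression defaults to log10–log10 (both quantities span
orders of magnitude); a linear-scale option is retained.
`subsample_representativeness` resamples the population without
replacement and reports the RMSE of the subsample GRT CDF against the
full-set CDF per sampling fraction.

## Dispersal model

Movement is continuous-position on a 1-km raster: per step an agent turns
by U(−θ, +θ) (θ = 20° default), advances one cell length, and pays the
entered cell's cost from its energy quota (150 units by default; 120 and
180 are the standard alternatives). Cost is 1 + Naismith penalty — one
extra flat-km equivalent per 120 m of ascent within a km (so 600 m of
ascent costs 6) — from the slope layer directly, or from min–max-normalized
roughness mapped onto 0–600 m/km of equivalent ascent. Flat terrain costs
exactly 1, making flat reach exactly 150 cells. Journeys end by arrival at
a non-natal water patch (checked before exhaustion, so arriving with
exactly zero energy counts), return to the natal patch after having left
it, energy ≤ 0, or leaving the grid (death by default; reflection behind a
flag). Lethality is a per-cell capacity, zero by default — agents get the
maximum chance to disperse, making isolation findings conservative.
Agents hatch evenly across patches (remainder randomized) on patch
perimeter cells, heading outward from the patch centroid. 4,000 agents per
tick for 100 ticks gives 400,000 attempted journeys; the status ledger
(arrived + dead + returned) always sums to the attempts, and per-agent
energy bookkeeping is exact.

Scenario assembly follows a nested wet-to-dry ladder: the wettest run keeps
every feature class; drier runs drop seasonal features, then perennial
streams; the driest keeps only springs persistent through a precessional
cycle, geothermal springs, fresh lakes, and rivers with flow > 5 km³/y
(saline lakes excluded as unpotable). Patch ids are preserved so node sets
nest. Networks are undirected (a successful journey either way links two
refugia for gene-flow purposes; directed matrices are preserved in output);
the component count, largest-component fraction and degree statistics are
the connectivity metrics — a deliberately minimal graph-native replacement
for external landscape-metrics software.

## Synthetic data

The spring generator draws log-uniform k₀ (specified in m/s, converted to
m/y), n_e, B, uniform α, area A = c·B² with lognormal scatter, and a
recharge field with a latent spatial gradient clipped to [0, 250] mm/y
around a semi-arid mean of 49 mm/y. Two constraints keep draws physical:
α is capped so that B·tan α ≤ 3,000 m (rift-flank-scale relief; jointly
extreme B and α would otherwise imply tens of kilometres of relief and
unsupported slope numbers), and the generated GRTs must span ≥4 orders of
magnitude (asserted; one widened redraw attempted). The wide documented
default ranges produce a heavy-tailed, mostly-persistent population; the
calibrated `EASTAFRICA_LIKE` configuration (B ∈ [0.5, 15] km,
k₀ ∈ [10⁻⁷, 10⁻⁴] m/s, A = 0.06·B², i.e. strip-like catchments a few
hundred metres wide) reproduces the qualitative rift regime: a ~5–7-order
GRT span, roughly half of springs outlasting century droughts and roughly
a third persisting through a full precessional cycle at a 1 mm/y floor.

Landscapes are spectrally synthesized fractal terrain (power-law spectrum,
exponent 1.8, relief 600 m by default); roughness is the 3×3 local standard
deviation of elevation and slope the finite-difference gradient. Water
features are placed in clusters (springs as cells, lakes as disks, perennial
wetlands adjoining lakes, rivers as down-gradient walks); wet-phase
expansion classes (seasonal springs/wetlands/streams and perennial streams)
are placed along inter-cluster corridors, the hydrologically expected
pattern when a drainage network expands, which is what makes wetter
scenarios act as stepping-stone-connected networks.

Two-sinusoid forcing objects reduce an observed rainfall series to a mean
plus two sinusoids; by linearity the spring's response is the superposition
of the two single-component responses, which is asserted in tests.

What the synthetic data do **not** emulate: real geography (no spatial
correlation between terrain and spring hydraulics; persistence flags are
assigned to landscape spring patches by index, not by a spatial join),
correlated parameter uncertainty, heterogeneity or anisotropy within an
aquifer, and any correspondence to the deposited spring dataset's values.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative regime, not quantitative regional predictions.

## Verification

An independent Crank–Nicolson finite-difference solver of the same
linearized equation (kept in the test suite, never used by the package)
is the primary oracle: steady profiles agree to <1%, recessions and
periodic amplitude/lag to <2% on randomized catchments (slope numbers ≤ 5
for the 50-node oracle grid, where the central-difference scheme is
well-resolved; larger Hi validated separately on fine grids). Other
oracles: plain bisection for the eigenvalue roots, quadrature for the
series coefficients, dense grid search for the water-table maximum and the
recharge cap, exhaustive enumeration for the two-spring subsample RMSE,
Dijkstra on the cell graph for the energy-reach bound, and union–find for
network components.

## Problem sizes

Default verification sizes: 20 randomized catchments for oracle
equivalence; a 500-spring population for persistence-curve and
series-convergence checks; 2,000 Monte Carlo draws (the full 10,000-draw
ensemble is a one-line change and scales linearly); the full
4,000 × 100-tick dispersal ledger on a 100 × 100 grid; and ten repetitions
of the four-scenario ladder (400 agents × 25 ticks on a fixed 160 × 160
landscape) for the network-component trend.

## Known limitations

One-dimensional uniform flow only: no heterogeneity, anisotropy, fracture
networks, or convergent/divergent flow-geometry corrections to GRT (real
convergent catchments respond more slowly, so modelled persistence is
conservative). The periodic solution is the dynamic equilibrium; spin-up
transients after abrupt regime changes are represented only by the sudden
end member. Recession evaluation is limited to slope numbers Hi ≤ 200
(documented error above). The movement model has no behaviour beyond
water-seeking (no foraging, grouping, or memory), and the turn/step
discretization is one concrete reconstruction of a bounded-turn walk —
conclusions are tested for robustness across turn angles and travel
distances rather than tied to one discretization.
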