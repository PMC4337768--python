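# Methods

This note records the models implemented in `rangewalk`, the assumptions
behind them, the defaults that matter, and the numerical and design
choices made where more than one reasonable option existed.

## 1. Confining potentials and the home-range length

Potentials are stored as the dimensionless ratio `U(x)/D` because every
stationary quantity in the framework depends on `U` and the diffusivity
`D` only through that ratio; `D` enters separately only in the dynamical
modules. All built-in families are even with their minimum at the
origin:

| family | `U/D` | notes |
|---|---|---|
| `harmonic` | `x²/L²` | Gaussian steady state, variance `L²/2` |
| `logarithmic` | `ln(1 + x²/L²)` | Cauchy steady state; heavy tails |
| `box_erf` | `-ln{erf[a(x/L+½)] - erf[a(x/L-½)]}`, `a = √(6π/11)` | box of width `L` blurred by a Gaussian |
| `hard_box` | 0 on `(-a/2, a/2)`, ∞ outside | integrals truncated to the support |
| `multi_harmonic` | piecewise quadratic, C¹-matched at a crossover radius | a *reconstruction* of a two-stiffness well; the inner curvature is `1/L²`, the outer is `outer_ratio/L²` |
| tabulated / custom | two-column text or a callable | linear interpolation inside the table, quadratic value-matched growth outside |

The logarithmic family deserves a remark: it is defined here as the
potential whose windowed steady-state MSD is exactly the arctan closed
form used by the inversion (see §2). Its Boltzmann state is a Cauchy
density, so its second moment diverges and `home_range_length` raises
`DivergentMomentError` for it; the saturation curve, which only ever
integrates over the finite window, remains perfectly well defined.

The intrinsic home-range length is the functional
`L = sqrt(2∫₀^∞ x² w dx / ∫₀^∞ w dx)` with `w = exp(-U/D)`; an
equivalent reciprocal-space form (curvature of the Fourier transform of
`w` at `k = 0`) is provided as `home_range_length_kspace` and the two
agree to 1e-6 relative for every family with finite second moment (this
is a test). The functional returns exactly the stored `L` for the
harmonic family and `a/√6` for a hard box.

Infinite-range quadratures use `scipy.integrate.quad` with explicit
splitting at the integrand's peaks; integrability is guarded by a
cutoff-doubling probe (the integral from `1000L` to `4000L` must be
below 1e-3 of the total) so flat potentials and divergent moments fail
loudly rather than silently.

## 2. Saturation MSD through a trapping window and its inversion

With burrow centres uniform on the terrain, the steady-state
capture-recapture MSD observed through a 1d window of side `G` reduces
to

    ⟨Δx²⟩_ss = ∫₀^G y²(G-y) f(y) dy / ∫₀^G (G-y) f(y) dy,

where `f` is the self-convolution of the Boltzmann weight. Normalised
by `G²/6` (the value for two independent uniform points on the window,
i.e. the flat-potential/`ζ→∞` limit) it is a monotone sigmoid in
`ζ = L/G`. For a 2d window the two axes contribute additively and the
normaliser doubles, so the *normalised* curve is the same; rectangular
windows and different per-axis potentials are supported by summing the
per-axis values.

Numerical notes for the harmonic closed form: the sinh and the
`exp·erf` term share an overflowing factor `e^{1/(4ζ²)}` which is
cancelled analytically before evaluation, and beyond `ζ = 30` the
evaluation switches to the series `1 - (7/15)b + (44/315)b²` with
`b = 1/(4ζ²)` (derived by expanding the closed form), because the direct
expression loses the plateau to catastrophic cancellation. With this,
curve inversion round-trips to 1e-6 relative across `ζ ∈ [0.01, 100]`.

Inversion is a bisection/Brent root-find in `log ζ` (monotonicity makes
the root unique). Observed saturation values outside `(0, 1)` after
normalisation raise an explicit out-of-range error; error bands that
cross the ends of the sigmoid are clamped to the curve's ζ-range,
producing honest one-sided intervals.

**From fixes to a saturation value.** All capture-recapture pairs with
lag above a user-chosen *stationarity lag* are pooled with equal weight
(the alternative — per-animal means first — is noted but not the
default). Pairs sharing an animal are strongly correlated, so the 95%
interval on the pooled MSD comes from a delete-one-animal jackknife on
the log scale (squared displacements are right-skewed) with a Student-t
critical value at (animals − 1) degrees of freedom. The interval on `L`
is obtained by inverting the two MSD bounds, and is asymmetric.

## 3. Territorial random walk model

Walkers hop between nearest-neighbour sites of a periodic lattice in
discrete sweeps: each sweep, every walker attempts one hop in freshly
shuffled random order, so one sweep is one hop time `τ̄`. (The
underlying picture is continuous-time; discrete sweeps give identical
long-time statistics and exact reproducibility under a seed.) Every
visited site receives/refreshes the visitor's mark; a mark is *active*
for `T_A` sweeps after deposition. Only the occupied site is refreshed.

Encounter semantics are configurable because the discrete model admits
two natural conventions:

* `respond_on="land"` (default): the walker lands on the marked site,
  and the response applies from its next hop, with `p(τ)` evaluated at
  the age the mark had at landing. In full exclusion the deposit claims
  the site (erasing other owners' marks there), which keeps actively
  marked areas pairwise disjoint at every instant.
* `respond_on="target"`: the target site is checked before hopping and
  an active foreign mark vetoes the hop (the walker retreats instead).
  Foreign territory is never claimed by intrusion — sites change hands
  only after their marks expire.

The two conventions agree on utilization statistics at moderate
competition but differ for *boundary* dynamics: claiming-on-landing lets
each contact displace the interface, which makes edges diffuse almost
freely, whereas the veto convention reproduces the expected behaviour of
edges that move only when marks expire. The interface analyses
(`boundary_msd_1d` and the edge-mobility-vs-`T_A` relation) should
therefore be run with `respond_on="target"`; tests do so.

Full retreat chooses uniformly among neighbour sites free of active
foreign marks and stays put when there are none. The graded
(`alpha_family`) response biases the next hop toward the centroid of the
walker's own active marks with `p(τ) = ½[1+√(1-(τ/T_A)^α)]` (`α → ∞`
recovers the step response of full retreat; `α → 0` makes walkers
scent-blind). The centroid on the periodic lattice is the arithmetic
mean of minimal-image offsets relative to the walker's current position
— a convention, since the torus has no unique centroid; κ is 0 when the
walker sits on its centroid. Lattice diffusivity is the standard
nearest-neighbour value `D = a²/(4τ̄)` (2d) or `a²/(2τ̄)` (1d), making
`Z = 4DρT_A` reproducible; 16 walkers on 25×25 with `T_A = 1250` give
`Z = 32`.

Utilization distributions are accumulated by default over the trailing
2.5 `T_A` of the run. Territory edges in 1d are located per snapshot as
the midpoint between the forward-most active mark of one owner and the
rearmost active mark of the next owner around the ring (robust to
expiry holes inside a territory); snapshots in which an owner holds no
active marks (collapse) are flagged and excluded from the MSD windows.
The hot loops are compiled with numba; all randomness is pre-drawn from
a single `numpy` Generator so runs are bit-reproducible under their
seed.

## 4. Persistent walker in a fixed territory

The interior walker follows a generalized master equation with the
exponential memory `φ(t) = (v²/D) e^{-t/T}`, `D = v²T`, and no-flux
boundary conditions on a rectangle. The MSD with a uniform start is the
odd-mode eigenseries whose mode amplitudes decay as `(2n-1)^{-4}` and
whose mode frequencies are `Θ_m = (2T)^{-1}√(4m²π²ζ_z²-1)` with mode
number `m = 2n-1` and `ζ_z = vT/λ_z`. (Writing the frequency with the
raw summation index instead of the odd mode number breaks both the
diffusive limit — reflecting-box rates `(2n-1)²π²D/λ²` — and the
short-time ballistic limit `v²t²` per axis, so the odd-mode indexing is
the one implemented; both limits are verified against independent
oracles in the tests.) Negative radicands are continued analytically to
cosh/sinh and assembled from decaying exponentials only, so no overflow
and no complex arithmetic is exposed. The series is truncated when the
`(2n-1)^{-4}` envelope falls below 1e-12 of the total.

The slowest mode turns oscillatory exactly at `ζ_z = 1/(2π)`; humps in
the MSD above the `(λ_x²+λ_y²)/6` plateau appear for `ζ_z` above the
threshold. Note the overshoot grows continuously from zero, so a finite
detection level (0.1% above the plateau in the tests) needs `ζ_z`
slightly above `1/(2π)` before it triggers.

The matching generator (`generate_persistent`) uses independent
per-axis telegraph velocities with direction-reversal rate `1/(2T)`:
reversals at rate μ give velocity autocorrelation `e^{-2μt}`, so the
rate must be `1/(2T)` — not `1/T` — for the autocorrelation `e^{-t/T}`
assumed by the series ("persistence time `T`" here names the
correlation decay time; the mean time between reversals is `2T`).

The circular-arena summary statistic is the effective persistence
`ξ = -ℒ/[R ln⟨cos θ⟩]`: 0 for uniform turning (Brownian), +∞ reported
(not raised) in the ballistic limit `⟨cos θ⟩ → 1`.

## 5. Boundary dynamics

In the strong-competition (adiabatic) regime the edges of a focal
territory are modelled as a spring-tethered pair: each edge has
diffusivity `Kφ(t)` and drift `∓Kφ(t)(γ/2)(L₂-L₁-L̄)`. Centroid and
separation decouple: the centroid MSD is `K∫₀ᵗφ(s)ds` and the
separation is an Ornstein-Uhlenbeck process with stationary mean `L̄`
and variance `2/γ` (independent of `K` — both are tested). Integration
is Euler-Maruyama with a step-size guard `dt ≤ 0.5/(Kγφ(0))`; edge
order is preserved by reflecting the separation at zero. The modulation
`φ(t)` is `1` (diffusive), `∝(t+1)^{-1/2}` (so `∫φ ∼ √t`, the 1d
single-file scaling) or `1/ln(e+t)` (so `∫φ ∼ t/ln t`, the 2d lattice
scaling); amplitudes are free parameters. These modulated processes
*age*: the sublinear law holds for the ensemble MSD from the start of
the run, while the time-averaged MSD of a single long record is linear
in the lag — the tests use ensemble averages for exactly this reason.

`compose_occupation` implements the adiabatic product ansatz: the fast
walker equilibrates to a uniform density between the instantaneous
edges, so the occupation map is a Monte-Carlo average of normalised box
indicators over the sampled edge history (frozen edges recover the
fixed-territory result exactly; larger `K/γ` monotonically fattens the
tails beyond the mean edges).

`k_from_ta` encodes the first-passage argument for edge rigidity: an
edge stays put if the resident returns to it before the marks expire,
and the non-return probability is dominated by the slowest first-passage
mode, giving `K ∝ exp(-π²DT_A/4L²)`. The full eigenmode survival series
is available as the brute-force reference. The same exponential
dependence emerges from the 1d lattice simulations: measured edge
mobility versus `T_A` is log-linear with Pearson r ≈ -1 (tested).

## 6. Trajectory statistics

Displacement moments pool every same-animal pair at the requested lag
with equal weight; regularly sampled trajectories use an O(F) shifted
difference, irregular ones an all-pairs search. Empty lag bins are
reported (NaN with zero count), never dropped. Hurst exponents use the
exact two-lag log-ratio; it is exact only under pure power-law scaling,
so the estimator reports bootstrap bands (resampling animals) and flags
multifractality only when no constant `H` fits inside all bands.
Finite observation windows bias high-q moments; the estimator does not
correct for this, but `windowed_gaussian_moment` evaluates the
special case that is explicitly computable (Gaussian displacements,
square window, uniform start) so the size of the suppression can be
gauged, and `msd_ss_nonuniform` (experimental) quantifies the effect of
a known non-uniform burrow density on the saturation value by direct
triple quadrature.
For *aging* walks (time-dependent diffusivity), the scaling law applies
to displacements referenced to the start of the walk, not to pooled
stationary pairs; the tests subsample fixes accordingly.

The steady-state potential fit maximises the Boltzmann likelihood of
(thinned) fixes over `(L, centre)` for the chosen family — closed form
for the harmonic case (Gaussian MLE), Nelder-Mead otherwise. Only the
shape `U/D` is identified; splitting the ratio needs an independent
measurement of `D`, which is what the transition-likelihood fit
provides.

`SmoluchowskiMLE` fits harmonic tethered diffusion by its exact
Ornstein-Uhlenbeck transition likelihood (relaxation rate `2D/L²`,
stationary per-axis variance `L²/2`), maximised with Nelder-Mead from a
moment-based start (variance → `L`, lag-1 autocorrelation → `D`), with
optional jittered restarts. Bootstrap intervals default to a *two-stage*
resampling scheme — animals with replacement, then the conditionally
independent transition pairs within each chosen animal — which captures
both between-animal and within-animal sampling variation; fixes are
serially dependent, so resampling raw fixes (which would destroy the
transition structure the likelihood is built on) is deliberately not
offered. Single-stage transition resampling (`resample="transitions"`)
and whole-animal blocks (`resample="animals"`) are available; in
synthetic calibration the two-stage scheme was the best calibrated
(~97% observed coverage of nominal 95% intervals, versus ~92% for
single-stage and ~88% for blocks at 12-16 animals). Percentile
intervals at `B = 200` are the default.

## 7. Synthetic data: what it emulates, and what it does not

The generators emulate the study designs the estimators expect:
burrow-tethered overdamped walkers with burrows uniform on a square
extent (default extent 10 windows so edge effects on the uniform-burrow
assumption stay ≲1%), mark-recapture sampling through a centred window,
persistent walks in boxes and circular arenas, and free / ballistic /
time-modulated Gaussian walks. Euler-Maruyama integration uses
`dt = (L²/2D)/dt_divisor` (default divisor 100) with a 20-relaxation
warm-up before the first fix; the divisor is exposed because the O(dt)
discretisation bias (~2% in recovered `D` at the default) matters for
bias-sensitive calibration experiments, which use divisor 400.

What the generators do **not** emulate: measurement error on fixes,
irregular/missing sampling, landscape heterogeneity, behavioural
switching, and inter-individual parameter variability. Passing recovery
tests therefore demonstrate the estimators' correctness and calibration
under the model's own assumptions, not robustness to the many ways real
telemetry deviates from them.

## 8. Problem sizes used in the test suite

The statistical tests use desk-scale designs chosen for adequate power:
home-range recovery uses 800 animals on a 100×100 extent with a 10×10
window over 50 replicates; likelihood coverage uses 12 animals × 80
fixes over 30 replicates with `B = 100`; the 1d interface-scaling run
uses a 400-site ring, 20 walkers, `T_A = 400` (Z = 40) for 6×10⁵ sweeps
averaged over four seeds, fitted over lags 4×10³–4×10⁴. Larger designs
sharpen the same conclusions.

## 9. Known limitations

* Only separable 2d potentials; no time-dependent potentials.
* The multi-harmonic family is a plausible reconstruction, not a unique
  functional form.
* `compose_occupation` and the `trw_adiabatic` likelihood use the
  long-time uniform interior profile; short-time interior transients
  inside a moving territory are not composed.
* The five-parameter territorial likelihood identifies the stationary
  geometry (`L̄`, γ, centre) from independent fixes; `v`, `T` and `K`
  require trajectory-level (not just positional) information and are
  estimated separately (speed/turning statistics, edge tracking).
* Curve inversion close to the saturation plateau is intrinsically
  ill-conditioned: at `ζ = 100` a 1e-10 error in the normalised MSD
  moves `ζ` by ~4e-6 relative; beyond `ζ ≈ 100` point estimates should
  be reported as lower bounds.
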