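# rangewalk

Simulators and estimators for animal movement in confined space: how home
ranges and territories emerge from interacting random walks, and how to
measure them from relocation data.

`rangewalk` is aimed at movement ecologists and quantitative biologists
who work with mark-recapture or telemetry fixes of animals that are
confined — by attachment to a burrow or den, or by scent-marked
territorial boundaries — and want mechanistic, parameter-level answers
rather than descriptive occupancy contours.

## What is in the box

**Home ranges from saturating MSD.** An animal tethered to a burrow by a
confining potential `U(x)` with diffusivity `D` has the Boltzmann
stationary density `∝ exp(-U(x)/D)` with intrinsic home-range length
`L = sqrt(2⟨x²⟩)`. When relocations are collected inside a trapping
window of side `G`, the steady-state mean-square displacement between
capture and recapture saturates at a value set jointly by `L` and `G`:

    ⟨Δx²⟩_ss / (G²/6) = S(ζ),   ζ = L/G,

a monotone sigmoid rising from 0 to 1, with closed forms for the harmonic
(`U/D = x²/L²`, sinh/erf) and logarithmic (Cauchy steady state, arctan)
families and a quadrature pipeline for any other even potential
(`rangewalk.homerange`). Inverting the sigmoid at the observed saturation
value gives `L = ζ·G` with error propagation
(`HomeRangeEstimator`).

**Territorial random walkers.** A lattice model of scent-mediated
exclusion (`rangewalk.trw`): walkers deposit marks that stay *active* for
a time `T_A` and either fully retreat from active foreign marks or
respond gradually with bias `p(τ) = ½[1 + √(1-(τ/T_A)^α)]` toward the
centroid of their own marked area. The spatial competition parameter
`Z = 4DρT_A` controls how rigid the emergent territories are. Outputs:
trajectories, territory snapshots, utilization distributions, and the
sub-diffusive motion of territory edges in 1d.

**Confined persistent walkers.** Closed-form MSD of a correlated
(telegrapher-memory) walker inside a fixed rectangular territory,
including the damped oscillations that appear when the relative
persistence `ζ_z = vT/λ_z` exceeds `1/(2π)` (`rangewalk.confined`).

**Boundary dynamics.** Spring-tethered stochastic edges (adiabatic
mean-field picture of neighbouring territories), the composed
occupation map of a walker inside fluctuating edges, and the exponential
first-passage relation `K ∝ exp(-π²DT_A/4L²)` between edge mobility and
the active-scent time (`rangewalk.boundaries`).

**Trajectory statistics.** q-th displacement moments, multifractal Hurst
spectra `H(q) = ln[m_q(t₁)/m_q(t₂)]/(q ln(t₁/t₂))`, steady-state
potential fits, and maximum-likelihood estimation of `(D, L, centre)`
with bootstrap intervals (`rangewalk.trajstats`), plus seeded generators
for every synthetic input (`rangewalk.synthetic`).

The inference components are scikit-learn-style estimators (`fit`,
fitted attributes with trailing underscores, `get_params`/`set_params`)
and compose with sklearn tooling; the simulators are plain configured
classes.

## Worked example

Estimate a home-range length from synthetic mark-recapture data with a
known answer:

```python
import rangewalk as rw
from rangewalk import synthetic

L_true, G, D = 5.0, 10.0, 100.0          # metres, metres, m²/day
tau = L_true**2 / (2 * D)                # home-range relaxation time

spec = synthetic.PopulationSpec(
    n_animals=800, potential=rw.HarmonicPotential(L_true), D=D,
    extent=10 * G, fix_interval=2.5 * tau, n_fixes=16, seed=101)
traj = synthetic.generate_tethered(spec)

est = rw.HomeRangeEstimator(G=G, family="harmonic", dimension=2,
                            stationarity_lag=5 * tau).fit(traj)
print(f"L = {est.L_:.2f} m  [{est.interval_[0]:.2f}, {est.interval_[1]:.2f}]"
      f"  (zeta = {est.zeta_:.3f})")
```

which prints

```
L = 4.49 m  [3.26, 8.37]  (zeta = 0.449)
```

— the walkers were generated with `L = 5` m; the estimator reads the
saturated MSD of all in-window capture pairs off the harmonic sigmoid and
reports a 95% interval that covers the truth. The same estimator accepts
real fixes as a CSV with columns `id,t,x,y` through
`rangewalk.read_trajectories` or the CLI:

```sh
rangewalk estimate-homerange --traps 10 --potential harmonic \
    --trajectories fixes.csv --stationarity-lag 0.6
```

Other subcommands: `generate`, `simulate-trw`, `simulate-boundaries`,
`confined-msd`, `hurst`, `fit` (run `rangewalk --help`).

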