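# Methods

## Forward model

The gel is treated as a finite slab: a cylinder of radius R = 3.25 mm
and height L = 5 mm whose transport is one-dimensional along the axis
(isotropic axially, null radially), so the radius enters only through
the cross-sectional area πR² in the mass balance. The solute obeys
Fick's second law with constant effective diffusivity D_eff, a uniform
initial concentration C_initial, a zero-flux (sealed) base, and a Robin
condition at the release surface. The surface condition is implemented
in flux form, −D_eff ∂C/∂z|_L = k (C|_L − C_eq): the literature
formulation this model derives from writes ∂C/∂z|_L = k (C|_L − C_eq),
which is dimensionally inconsistent for k in m/s; the flux form
preserves units and reduces to the perfect-sink boundary as k → ∞. The
pseudo-equilibrium concentration C_eq models electrostatic
solute–alginate binding; at long times the gel equilibrates uniformly
at C_eq, so cumulative release plateaus at 100·(1 − C_eq/C_initial)
percent (`plateau_percent`).

Released mass is M_t = M∞ − πR²·∫₀ᴸ C dz with the integral evaluated
by the trapezoidal rule on the solver grid and M∞ = C_initial πR²L.

### Assumptions

- Monolithic dispersion below saturation; no erosion, swelling, or
  concentration-dependent diffusivity.
- The nanoparticle-in-gel system is described by the same single-D
  framework (the two-step NP-to-gel transport appears only as a lower
  effective D_eff).
- No convective term: flow experiments are reduced empirically, not
  modelled mechanistically.

## Numerics

Space: uniform grid of `n_nodes` nodes (default 31, so Δz = L/30 ≈
0.1667 mm); boundary conditions enter through second-order ghost-node
closures, preserving overall second-order spatial accuracy. Time:
Crank–Nicolson (θ = 1/2) with Δt = 300 s by default, one tridiagonal
solve per step (`scipy.linalg.solve_banded`; inside `solve_release`
the constant one-step propagator is formed once and applied as a dense
matrix–vector product for speed).

The uniform initial state is incompatible with the Robin surface
condition, so the exact solution behaves like √t at startup. Plain
Crank–Nicolson handles this badly at coarse steps: its weakly damped
oscillatory modes produce large surface under-shoots (down to about
−0.86·C_initial on the default grid at high Biot number). The first
macro step is therefore integrated as a ramp of 16 geometrically
graded backward-Euler sub-steps (a Rannacher-style damped start that
also resolves the √t region); all subsequent steps are pure
Crank–Nicolson. Measured consequences on the default grid: no negative
concentrations (the solver treats any value below −10⁻¹²·C_initial as
a bug and raises), maximum release-fraction error versus the analytic
series about 2·10⁻⁴ (2·10⁻⁶ at tenfold refinement), and Richardson
ratios ≈ 3.8–4.0 in both space and time.

Degenerate inputs: k = 0 (sealed gel) and C_initial = C_eq are exact
fixed points; C_initial < C_eq simulates uptake (allowed). Observation
times are interpolated linearly between integration steps, both for
cumulative mass and for concentration profiles. A dimensionless step
D·Δt/L² > 0.025 (fewer than ~40 steps per diffusion time) triggers an
accuracy warning — Crank–Nicolson stays stable, but the late-time
oscillatory modes then decay slowly enough that the negativity guard
may fire for perfect-sink-like parameters.

The independent oracle (`analytic_release_fraction`) is the
separation-of-variables series for the same slab: eigenvalues
λₙ tan λₙ = Bi (Biot number Bi = kL/D_eff) found by bisection on each
branch, released fraction 1 − Σ [4 sin λₙ/(2λₙ + sin 2λₙ)]
(sin λₙ/λₙ) exp(−λₙ² D t/L²), truncated when the exponential factor
drops below 10⁻¹².

The mass-balance diagnostic integrates the Robin boundary flux with
the scheme's own θ-weighted surface value, which makes the discrete
balance exact to round-off; the test bounds (0.5% of M∞ at the default
grid) are therefore met with large margin.

## Korsmeyer–Peppas analysis

Ordinary least squares of ln(M_t/M∞) on ln t over (0, 6] h. Points at
t = 0 or with zero release are excluded (their logarithm is
undefined); at least three usable points are required. Natural logs
are used and the intercept back-transformed, so `a` is a fraction per
hⁿ (the data arrive as percent and are divided by 100). Mechanism
thresholds for a cylinder: n ≤ 0.45 Fickian (values below 0.45
indicate diffusion with solute–matrix interactions), 0.45 < n < 0.89
anomalous, n ≥ 0.89 erosion; both boundaries are closed on the side of
the named regime, matching the conventional phrasing. With replicate
curves the fit is per replicate and the exponent reported as
mean ± SD.

## Parameter estimation

Real-coded genetic algorithm in log10 parameter space: tournament
selection (size 3), BLX-α blend crossover (α = 0.5, rate 0.9),
per-gene Gaussian mutation (rate 0.15, σ = 10% of the bound span),
elitism 1, population 60, 80 generations, early stop after 20
stagnant generations. Default bounds: D_eff ∈ [10⁻¹², 10⁻⁸] m²/s,
k ∈ [10⁻⁸, 10⁻³] m/s, C_eq ∈ [10⁻³, 1]·C_initial — two decades of
margin around reported hydrogel values. Because log10(0) is undefined,
an exactly zero C_eq is expressed by fixing the parameter rather than
searching for it. The objective is the sum of squared differences in
cumulative release *percent* (so loadings are comparable) at the
observation times; forward-solver failures are penalized with a large
finite value. A Nelder–Mead simplex polishes the GA best (tolerance
10⁻¹⁰ on the objective) — the GA finds the basin, the simplex supplies
the precision. Everything is deterministic given the seed.

C_eq is estimated jointly by default (a plateau below 100% cannot be
fitted without it) and fixed in recovery experiments where the
generating value is known. Identifiability: at high Biot number the
curve is diffusion-limited and carries almost no information about k;
`profile_objective` flags a direction whose RMS misfit variation
across the scanned grid stays below 0.5 percentage points. Recovery on
noise-free synthetic curves at the 13-point static schedule is
essentially exact (relative errors below 10⁻⁶ for D_eff after polish),
comfortably inside the 5% / 10% acceptance bands.

## Perfusion data reduction

Pump calibration converts collected water mass to volumetric flow via
a degree-4 polynomial fit to a bundled 0–80 °C reference water-density
table (17 points at 5 °C spacing, reproduced by the polynomial to
better than 10⁻⁴ g/mL), averages replicate flows per RPM, and
regresses mean flow on RPM. Fraction-collector series are cumulated
with time stamps at each 2-h bin's right edge. The dead-volume
detection delay is the raw tubing delay (dead volume / flow) rounded
up to the next bin edge, with zero dead volume reporting the first
bin. The default dead-volume fixture is 300 µL, consistent with the
10 h delay observed at 0.5 µL/min; the delays printed at the other
flow rates imply different dead volumes and are not reconciled here —
the parameter is configurable per series. Mass-balance closure sums
the released percent and the four compartment percentages; measured
data outside 100 ± 5 points are flagged with a warning, never
rejected.

## Synthetic data

The static generator runs the forward model at the experimental
schedule (0, 0.5, 1, 2, 4, 6, 8, 24, 48, 72, 120, 144, 168 h),
differences the cumulative masses into per-interval supernatant masses
(the measured quantity under complete supernatant replacement — which
is why noise is placed on interval masses, not cumulative values), and
perturbs each replicate with multiplicative Gaussian noise (default
relative SD 0.05, the magnitude of the reported replicate scatter),
truncated at zero. Replicates draw from independent substreams spawned
from one master seed, so datasets are bit-reproducible. The bundled
reference conditions pair each hydrogel system and loading with its
reported (D_eff, k) and a C_eq back-calculated from that condition's
observed plateau through the plateau relation.

The perfusion generator is phenomenological (no mechanistic
flow-transport model exists to simulate): cumulative release follows
extent·(1 − exp(−rate·(t − t₀))) after the raw dead-volume delay t₀,
binned into 2-h fractions over 120 h. Default extents by flow rate —
0.073, 0.587, 0.925, 0.959 at 0.5, 3, 6.5, 10 µL/min — reproduce the
observed ordering of release with flow; the default rate constant
0.05 h⁻¹ brings the fastest runs to their plateau within roughly the
observed 48–96 h window. The unreleased remainder is split across the
four gel compartments by weights that interpolate, in the released
fraction, between all-in-the-core (no release implies no migration)
and (0.55, 0.20, 0.10, 0.15) for (downstream Alg:M, alginate core,
nanoparticles, upstream Alg:M) — magnitudes chosen to resemble the
reported mid-flow distributions — so closure is exactly 100% by
construction.

What the generators do *not* emulate: fluorescence-quantification
nonlinearity and background, pipetting losses, inter-batch gel
variability, NP encapsulation-efficiency scatter, or convective
transport inside the chamber. Passing recovery tests therefore shows
the estimation machinery is correct and well-conditioned under the
stated noise model, not that the experimental uncertainties of real
curves are captured.

## Problem sizes and runtime

Default solves use 31 nodes and 2,016 time steps (168 h at 300 s),
about 15 ms each; a GA fit evaluates ~5,000 forward solves in well
under a minute on one CPU. The test suite scales statistical
replications to desk scale (e.g. 5 replicate noisy fits for the
median-robustness property, 1,000 replicates for the cheap regression
and noise-calibration checks).

## Known limitations

- Axial-only diffusion; radial transport and 2-D/3-D effects are out
  of scope, as are erosion, swelling, and time-varying diffusivity.
- k is reported but weakly identified whenever Bi ≫ 1; treat fitted k
  above Bi ≈ 10² as a lower-bound-style diagnostic, not a measurement.
- The perfusion generator is a data-shaped stand-in, not a transport
  model; its parameters (extent, rate, dead volume, compartment split)
  are descriptive.
- With C_eq = 0 and very coarse time steps the negativity guard can
  trip at late times (tiny oscillatory residues); the accuracy warning
  fires first.
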