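# gelrelease

Release-kinetics modelling of chemokine (CXCL12) delivery from
alginate-based hydrogels, for researchers characterizing controlled
drug-delivery systems: static release curves, mechanistic transport
parameters, and perfusion-bioreactor (interstitial-fluid-flow-mimicking)
data reduction.

## The model

A cylindrical gel (radius R, height L) releases a solute by
one-dimensional axial diffusion,

    ∂C/∂t = D_eff ∂²C/∂z²,   z ∈ [0, L],  C(z, 0) = C_initial,

with a sealed base, ∂C/∂z|₀ = 0, and an interaction-limited
(Robin) release surface,

    −D_eff ∂C/∂z|_L = k (C|_L − C_eq),

where D_eff (m²/s) is the effective diffusivity, k (m/s) the overall
surface mass-transfer coefficient, and C_eq the pseudo-equilibrium
concentration produced by electrostatic solute–alginate interactions —
it is what makes release plateau below 100%, at
100·(1 − C_eq/C_initial) percent. Released mass is the loading minus
the trapezoidal profile integral, M_t = M∞ − πR² ∫ C dz.

The PDE is solved by Crank–Nicolson finite differences (31 nodes,
300 s step by default) with a damped geometric startup ramp; an
eigenfunction-series solution of the same problem serves as an
independent analytic oracle. The inverse problem — estimating
(D_eff, k, C_eq) from a measured cumulative release curve — is solved
by a seeded real-coded genetic algorithm in log10 space with a
Nelder–Mead polish. The early release window (≤ 6 h) is additionally
summarized by the Korsmeyer–Peppas power law M_t/M∞ = a tⁿ, whose
exponent classifies the transport regime for a cylinder (n ≤ 0.45
Fickian, 0.45 < n < 0.89 anomalous, n ≥ 0.89 erosion).

A perfusion module reduces flow-experiment bookkeeping: pump
calibration (water-density polynomial, flow-vs-RPM regression),
fraction-collector cumulative release, dead-volume detection delays,
and end-of-run mass-balance closure across gel compartments. Seeded
synthetic-data generators reproduce both experiment types so the whole
pipeline runs with no external data.

## Worked example

```python
from gelrelease import (FickianReleaseModel, KorsmeyerPeppas, GAConfig,
                        NoiseModel, cumulative_from_supernatants, generate_static)
from gelrelease.synthetic import REFERENCE_CONDITIONS

truth = REFERENCE_CONDITIONS["alginate-0.4"]          # 0.4 µg/mL loading
ds = generate_static(truth, noise=NoiseModel(0.0), n_replicates=1, seed=11)
curve = cumulative_from_supernatants(ds.replicates[0])

kp = KorsmeyerPeppas(curve).fit()
print(kp.summary())

model = FickianReleaseModel(curve, c_initial=truth.c_initial_ug_ml,
                            geometry=truth.geometry)
results = model.fit(config=GAConfig(seed=11))
print(results.summary())
```

prints

```
Korsmeyer-Peppas power-law fit
========================================
replicates:      1
window:          0-6 h
n (exponent):    0.4470 +/- 0.0000
a [frac/h^n]:    0.1968
R^2 (log-log):   0.9933
mechanism:       fickian

Fickian release model (axial diffusion, Robin surface)
==========================================================
observations:        13
free parameters:     d_eff, k, c_eq
D_eff  [m^2/s]:      1.0400e-09
k      [m/s]:        4.1300e-05
C_eq   [ug/mL]:      2.1572e-01
Biot number kL/D:    199
plateau [% release]: 46.07
SSE [percent^2]:     5.5589e-22
R^2:                 1.0000
objective evals:     5068
GA converged early:  False
seed:                11
```

The Korsmeyer–Peppas exponent near 0.45 indicates Fickian diffusion;
the jointly estimated transport parameters reproduce the generating
truth, and the fitted C_eq/C_initial ratio of 0.539 yields the 46.07%
release plateau of the 400 ng/mL alginate condition.

A CLI mirrors the library: `gelrelease simulate|fit|kpfit|synth|
perfusion-reduce|calibrate-pump|run` (see `gelrelease --help`).

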