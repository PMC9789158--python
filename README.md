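# rotorscan

Quantify physisorption of a fluorescent dye at a glass/solution interface
from confocal microscope z-scans and TCSPC lifetime measurements.

## The problem

Molecular rotors such as 4-daspi are water-soluble fluorophores whose quantum
yield and lifetime report on local viscosity and confinement.  Near a solid
surface a fraction of the dye physisorbs, and that adsorbed sheet fluoresces
with a longer lifetime than the free species.  Measuring *how much* dye sits
on the glass with an ordinary confocal microscope is hard for two reasons:

1. a homogeneous bulk solution degrades the confocal pinhole's optical
   sectioning, so out-of-focus bulk light contaminates the interface signal
   over tens of µm of nominal focus depth;
2. refractive-index mismatch between the coverslip and the solution distorts
   the depth response as the stage moves.

`rotorscan` implements the signal model that separates the two
contributions.  Writing `z_F` for the nominal focus depth (stage readout,
0 at the interface), the detected signal from a surface sheet of density σ
(µm⁻²) over a bulk of number density ρ is governed by the probability
density φ(z, z_F) that a detected photon originates from depth z.  The
normalised sample scan I_N and the homogeneous reference rise H combine to

    U(z_F) = I_N(z_F) / H(z_F) = (φ(0,0)⁻¹ + K·R_th(z_F)) / (φ(0,0)⁻¹ + K)

with `R_th(z_F) = φ(0,z_F)/φ(0,0)` and the surface/bulk brightness ratio

    K = σ ε_S Φ_S / (ρ ε_B Φ_B)        [units of length].

Since φ(z,z_F) ∝ 1/|z−z_F|² at long range, U tends to the asymptote
U∞ = (1 + φ(0,0) K)⁻¹, giving K ≈ (1−U∞)/(φ(0,0) U∞).  The single
non-measurable input, φ(0,0), is computed by Monte Carlo geometric-optics
ray tracing of the instrument (objective NA and magnification, pinhole
size, coverslip and solution refractive indices).  Known photophysics
(ε_S ≈ ε_B, Φ_S from the Förster–Hoffman extrapolation, Φ_B(η) from the
rotor's viscosity calibration) then convert K into the adsorbed density σ
and a monolayer coverage fraction.

The package provides:

- `rotorscan.optics` — Monte Carlo ray tracer for φ(z|z_F), φ(0,0),
  H(z_F) and R_th(z_F) under coverslip/sample index mismatch;
- `rotorscan.zscan` — profile normalisation, the U-ratio, K and σ
  estimation (`SurfaceAdsorptionModel` → `AdsorptionResults`), the lifetime
  data collapse R_τ and the monoexponential R_th/R_τ relation, plus the
  tube-partition and monolayer-coverage arithmetic;
- `rotorscan.lifetime` — Poisson-MLE biexponential TCSPC fits with
  amplitude-averaged lifetime ⟨τ⟩ = (A₁τ₁+A₂τ₂)/(A₁+A₂), Gaussian-IRF
  reconvolution, pulse wrap-around, and the Förster–Hoffman power law
  τ = C η^α with its plateau-intersection (η_I, Φ_I);
- `rotorscan.synthetic` — generators for decay histograms, z-scans and
  glycerol/water property curves with known ground truth;
- `rotorscan.io` / CLI `rotorscan` — plain-text CSV/JSON/YAML formats and
  the subcommands `raytrace`, `fit-decay`, `analyze`, `simulate`,
  `collapse`.

## Worked example

Ray-trace the depth response of a 20x/NA 0.75 dry objective with a 56.6 µm
pinhole over water, simulate a hydrophobic-surface scan with a known
adsorbed density, and analyse it:

```python
import numpy as np
from rotorscan import (MicroscopeConfig, SurfaceAdsorptionModel,
                       trace_depth_response, default_photophysics)
from rotorscan.synthetic import GroundTruth, simulate_zscan

config = MicroscopeConfig()          # the 20x/0.75 dry instrument, water
z_f = np.unique(np.concatenate([np.arange(0.0, 41.0, 1.0), [5.0, 7.0]]))
dr = trace_depth_response(config, z_f_grid=z_f, n_rays=200_000, seed=1)

phot = default_photophysics(1.0)     # pure water: tau_B=0.12 ns, Phi_B~0.011
truth = GroundTruth(sigma_true=3300.0, photophysics=phot, noise_cv=0.01, seed=1)
scan = simulate_zscan(dr, truth)     # intensity + <tau> vs z_F, 1% noise

res = SurfaceAdsorptionModel(scan, depth_response=dr, photophysics=phot).fit()
print(res.summary())
```

prints

```
Surface adsorption from confocal z-scan
===============================================
estimator              corrected (H ray-traced)
depths used (µm)       5, 7, 10, 20, 30
phi(0,0) used (µm⁻¹)   0.2739
bulk density (µm⁻³)    60.22
K  (µm)                762.9 ± 21
U∞                     0.004763
sigma (µm⁻²)           3243 ± 90
monolayer coverage     0.324% (s_mol = 1 nm²)
```

Reading the output: the ray tracer put φ(0,0) at 0.274 µm⁻¹ for this
instrument; the scan's U-ratio at the five analysis depths yields a
surface/bulk brightness ratio K ≈ 763 µm, whose spread over depths gives the
±1 sd error bar; with 10⁻⁷ M dye (60.22 molecules/µm³) and the water
photophysics this converts to σ ≈ 3.2×10³ µm⁻² — within 2% of the injected
3300 µm⁻², about 0.3% of a monolayer at 1 nm² per molecule.

The same analysis from the shell:

```sh
rotorscan simulate --sigma 3300 --wt 0 --seed 1 --out demo/
rotorscan analyze --sample demo/sample.csv --phi00 0.27 \
    --rho 1e-7 --phib 0.011 --out demo/
```

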