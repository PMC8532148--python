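# oliverelax

Proton NMR relaxation and relaxometry analysis of edible oils — in
particular extra virgin olive oil (EVOO), where the ¹H relaxation
fingerprint of the triacylglycerol fraction is a fast, non-destructive
handle for characterization and quality control.

The package is aimed at people analysing time-domain NMR of neat
liquids: it decomposes longitudinal (T₁, inversion recovery) and
transverse (T₂, CPMG / spin echo) magnetization curves into one or two
exponential components, assembles and fits nuclear magnetic relaxation
dispersion (NMRD) profiles from fast-field-cycling data, and compares
relaxation components across sample cohorts. A seeded synthetic-data
generator emulates every input the pipeline consumes.

## The model

Low-field decays of a neat oil are sums of exponentials with free
amplitudes,

```
IR:    M(τ) = Σᵢ aᵢ (1 − 2·η·e^(−τ/T₁ᵢ))        (η = inversion efficiency)
CPMG:  M(t) = Σᵢ aᵢ e^(−t/T₂ᵢ)
```

because rigid protons (glycerol unit, CH near double bonds) and mobile
chain ends relax at different rates. The field dependence of the
spin-lattice rate R₁ = 1/T₁ is modelled as an additive sum of two
rotational Bloembergen–Purcell–Pound terms and a translational
self-diffusion (SD) term:

```
R₁(ν) = Σ_{k=1,2} A_Rot,k [ J(ω) + 4 J(2ω) ]   with J(ω) = τ_k / (1 + ω² τ_k²),
       + a_sd   [ J_t(ω) + 4 J_t(2ω) ]
ω = 2πν
```

where J_t is the force-free hard-sphere translational spectral density
(Torrey / Hwang–Freed / Ayant closed form) with correlation time
τ_D = d²/D; the self-diffusion constant D is held at its independently
measured value (for EVOO, D = 7.7 × 10⁻¹² m²/s from DOSY). BPP1 is the
slow-motion term (tumbling of the whole triacylglycerol), BPP2 the fast
reorientation about the long molecular axis.

## Worked example

Fit a simulated 30-point R₁ dispersion (10 kHz – 400 MHz) with D fixed
(`examples/nmrd_fitting.py`):

```
converged: True, weakly identified: False
BPP1 (slow): A_Rot1 = 1.08e+08 s^-2, tau_1 = 1.5e-08 s
BPP2 (fast): A_Rot2 = 3.15e+09 s^-2, tau_2 = 2.15e-10 s
SD: a_sd = 3e+06 s^-2 (D fixed at 7.7e-12 m^2/s)

per-mechanism R1 (s^-1):
 freq_hz    bpp1  bpp2       sd  total
   1e+04     8.1 3.386    1.824  13.31
   1e+06   7.863 3.386   0.8492   12.1
   1e+08 0.03622  3.19 0.001891  3.228
```

The fit recovers the planted parameters: a slow rotational mode
(τ₁ = 15 ns) that dominates the low-frequency plateau, a fast mode
(τ₂ = 0.215 ns) that carries the residual relaxation above 10 MHz, and
a small translational contribution that disperses around 1 MHz.

Decompose a 2 MHz CPMG decay (`examples/decay_decomposition.py`):

```
chosen model: bi
  component a: T2 =   43.1 ms, amplitude = 1.001
  component b: T2 =  147.1 ms, amplitude = 0.998
amplitude ratio a:b = 1.00
```

The corrected-AIC selector identifies the decay as two-component and
recovers the planted 43/147 ms time constants; the short component
belongs to the more rigid protons, the long one to the mobile chain
ends.

Each script in `examples/` covers one capability (decay decomposition,
NMRD fitting, cohort screening, spectral-region integration). A thin
command line mirrors the same operations:

```
oliverelax fixtures
oliverelax simulate-nmrd --output profile.csv --noise-level 0 --seed 1
oliverelax fit-nmrd --input profile.csv --fix-d 7.7e-12 --output params.json
```

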