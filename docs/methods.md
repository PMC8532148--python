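# Methods

## Signal models

Longitudinal relaxation is measured by inversion recovery (IR),
transverse relaxation by CPMG or spin echo. Both observables are sums
of exponential components with free amplitudes:

- IR: `M(τ) = Σᵢ aᵢ (1 − 2·η·exp(−τ/T₁ᵢ))`, with a single inversion
  efficiency η shared by all components of a curve. η defaults to 1
  for simulation; for measured curves it can be released as a fit
  parameter bounded to [0.7, 1.0], since real inversion pulses are
  imperfect.
- CPMG/spin echo: `M(t) = Σᵢ aᵢ exp(−t/T₂ᵢ)`, where `t` is the
  cumulative echo time `t_n = 2 n τ_echo`.

Amplitudes are deliberately free rather than fixed to proton
stoichiometry: an oil is a mixture of many triacylglycerol species, so
no single molecule's proton count applies. Components are reported
sorted by ascending time constant and labelled "a" (short) / "b"
(long).

## Dispersion model

The spin-lattice rate R₁(ν) is an additive sum of mechanism
contributions:

- Two rotational BPP terms `A_Rot·[J(ω) + 4J(2ω)]`,
  `J(ω) = τ/(1+ω²τ²)`, `ω = 2πν`. The dipolar constant is absorbed
  into the prefactor `A_Rot` (units s⁻²), so the zero-frequency
  plateau of one term is `5·A_Rot·τ`. The slow term (BPP1) represents
  tumbling of the whole molecule, the fast term (BPP2) reorientation
  about its long axis; the convention `τ₁ ≥ τ₂` is enforced by the
  parameterization.
- A translational self-diffusion term built on the force-free
  hard-sphere spectral density. We use the Ayant/Hwang–Freed closed
  form, normalized so `J_t(0) = τ_D` with `τ_D = d²/D`
  (`d` = `jump_distance`, the distance scale of the translational
  process; `D` = self-diffusion constant). The closed form is verified
  against adaptive quadrature of the defining integral to 1e-6
  relative in the test suite. Only `D` is typically known (DOSY);
  the distance scale defaults to d = 1 nm (a molecular diameter scale
  for a triacylglycerol) and is held fixed, while the amplitude `a_sd`
  is a free fit parameter by default and can be frozen via
  `a_sd_fixed`.

All public interfaces take ν in Hz; files store MHz (the customary
reporting unit) and are converted at the boundary.

## Decay fitting

Weighted least squares (weights 1/σ² when per-point noise estimates
exist, else uniform) via Levenberg–Marquardt. Initialisation: a
log-spaced grid of ~40 candidate time constants spanning
[second delay, 10 × last delay]; at each grid point the amplitudes are
solved by linear least squares; the best point seeds the nonlinear
refinement (the best five pairs for two-component fits, a cheap
multi-start against local minima). Bounds: amplitudes and time
constants strictly positive; the two-component fit parameterizes
`T_b = ratio·T_a` with `ratio ≥ 1`, which enforces ordering without a
constraint solver. Degenerate inputs (constant signal, too few points:
fewer than 6 for mono, 10 for bi) and non-convergence return an
explicit failure result with a diagnostic message instead of raising
or returning garbage.

Model order (mono vs bi) is selected by corrected AIC under a Gaussian
likelihood; the bi model must win by more than 2 AICc units, so ties
and near-degenerate two-component solutions fall back to mono. The
residual sum entering AICc is floored at `n·(10⁻¹⁰·max|signal|)²`:
on noiseless synthetic curves both models reach numerically zero
residual, and without the floor the log-likelihood of the
more-parameterized model diverges spuriously.

## Dispersion fitting

Weighted least squares on R₁ in linear space (1/σ² weights when
uncertainties are present). Free parameters
`{A_Rot1, τ₁, A_Rot2, τ₂, a_sd}` with `D` and `d` fixed; internally
the fit works in log₁₀ of each positive parameter, and `τ₂ = τ₁·f`
with `f ∈ (0, 1]` removes label switching between the two BPP terms.
Eight log-uniform random starts (seeded; the seed is recorded in the
result) bracket the correlation times by the observed frequency window
and scale the amplitudes from the low-frequency plateau `R₁ ≈ 5Aτ`.
Preconditions: at least 8 points spanning at least 1.5 decades.
Fits whose recovered correlation times are within a factor of 3 are
flagged `weakly_identified` — such profiles are too narrow to separate
the two rotational mechanisms. Parameter uncertainties are delta-method
transforms of the log-space standard errors.

Profile assembly (`build_dispersion`) takes per-frequency two-component
fits from field-cycling data (R₁ = 1/T₁ of the selected component,
refit independently at every frequency) and supplements them with
high-field points, one per field, equal to the mean R₁ over the CH and
CH₂ assigned peaks; CH₃ peaks are excluded because their fast methyl
rotation decouples them from the chain dynamics the dispersion model
describes. Frequencies with a missing component are collected in a gap
report on the profile rather than silently dropped.

## Synthetic data

The generator emulates the acquisition conditions of the three
instruments behind the analysis: a 2 MHz permanent magnet (IR 1 ms–1 s
in 20 steps; CPMG with 200 µs echo spacing, 1000 echoes), a 100 MHz
magnet (IR 0.2 ms–3 s in 21 steps; spin echo 0.02 ms–2 s in 12 steps)
and a 400 MHz spectrometer (IR 1 ms–10 s in 16 steps). The published
ranges and step counts do not state the spacing; logarithmic spacing is
used, which is the standard choice for relaxation delays. Noise is
Gaussian, additive or relative, at the 1–8 % levels typical of
triplicate reproducibility on these instruments; seeds are mandatory
arguments, never global state, and every generator is bit-reproducible
for a fixed seed. Each generated object records its planted truth in
metadata.

The fixture library collects the reference-sample (at_28) values used
throughout the tests: the composite NMRD fit parameters, the
two-component 2 MHz T₂ (43/147 ms), per-region T₂ at 100 MHz, and the
T₁ tables at 100 and 400 MHz. Two caveats are recorded in the fixture
notes: the 100 MHz T₁ row has five values against ten regions (peak
overlap at that field) and is stored positionally; and the
translational amplitude `a_sd = 3×10⁶ s⁻²` plus the 1 nm distance
scale are synthetic choices — they give the SD mechanism a ~2 s⁻¹
low-frequency contribution comparable to the rotational plateaus, but
no measured values for them exist.

The two-region cohort template plants per-sample time constants from
Gaussian group distributions whose means are anchored to the
reference-sample values and differ between regions by only 2 %, far
less than the 8–10 % within-group spread — reproducing the observed
situation of heavily overlapping regional ranges. Simulated cohorts
default to relative 2 % noise. What the generator does **not** emulate:
temperature dependence, field inhomogeneity and lineshape distortions,
J-coupling modulation in echo trains, radiation damping, instrument
drift, or any compositional difference between cultivars. Passing
tests therefore demonstrate correct recovery under the stated
statistical model, not robustness to every artifact of real
instruments.

## Cohort comparison

Low-field (2 MHz) curves are fitted with two components, high-field
(100 MHz) curves mono-exponentially — at high field the per-region
decays are single-exponential, and the screening quantity is the most
intense spectral region (0–2.5 ppm aliphatic envelope). Group
comparison is deliberately descriptive: per quantity, the overlap
coefficient |intersection|/|union| of the two groups' [min, max]
ranges, with verdict "similar" when every quantity reaches the
threshold (default 0.5). No hypothesis test is applied: the scientific
claim being reproduced is about coinciding ranges, and a significance
test on means would over-claim. Failures of individual fits are
logged per sample and leave gaps, never abort the batch.

## Problem sizes and determinism

The test and acceptance suites use a 30-point dispersion profile
(10 kHz–400 MHz), full-length instrument schedules for decay curves
(up to 1000 CPMG echoes), 50 replicates for noisy amplitude-ratio
statistics, 20 seeds for noisy dispersion recovery, and a 32 + 35
sample cohort — the cohort size of the regional screening study.
All randomness flows through explicit integer seeds; fit multi-starts
record their seed in the result object.

## Known limitations

- The two-BPP + SD decomposition is phenomenological; with narrow
  profiles the terms trade off (hence the weak-identification flag).
- `a_sd` and `d` are degenerate in the plateau (`R₁(0) ∝ a_sd·d²/D`);
  only one should float.
- The IR fitter assumes a single shared inversion efficiency; strongly
  miscalibrated pulses with component-dependent efficiency would bias
  amplitudes.
- File formats are package-defined plain text; proprietary instrument
  files must be converted upstream.
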