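# Methods

## Statistical model

All calculations are in normalized intensities `Z = I/(ε·Σ)`, where `ε` is
the symmetry-dependent expected-intensity factor and `Σ` the expected
intensity, so that `⟨Z⟩ = 1`. Two assumptions define the model:

1. **Wilson prior.** The true normalized intensity follows the Wilson
   distribution: acentric `p(Z) = exp(−Z)`; centric
   `p(Z) = (2πZ)^{−1/2} exp(−Z/2)`. In amplitude terms (`E = Z^{1/2}`) these
   are the Rayleigh-type density `2E·exp(−E²)` and the half-normal
   `(2/π)^{1/2} exp(−E²/2)`; the `Z→E` change of variable removes the
   centric singularity at zero and is used wherever quadrature crosses the
   origin.
2. **Gaussian measurement error.** The observed `Z_O` is the true `Z` plus
   zero-mean Gaussian noise of standard deviation `σ_Z`. `Z_O` may be
   negative; all operations support the whole real line.

The observed-intensity density `p(Z_O)` is the prior–Gaussian convolution.
Closed forms:

* acentric: `p(Z_O) = ½·erfcx(X)·exp(−Z_O²/2σ²)` with
  `X = (σ² − Z_O)/(σ√2)`; for `X < 0` the algebraically identical
  `½·erfc(X)·exp(σ²/2 − Z_O)` avoids `erfcx` overflow.
* centric: `p(Z_O) = (2√(πσ))^{−1}·exp(X_c²/4 − Z_O²/2σ²)·D₋½(X_c)` with
  `X_c = σ/2 − Z_O/σ`. With the scaled function
  `Dx₋½(x) = exp(x·|x|/4)·D₋½(x)` the exponent collapses to
  `−Z_O²/2σ²` for `X_c ≥ 0` and to `σ²/8 − Z_O/2` for `X_c < 0`, removing
  all overflow.

Both forms are pinned by a brute-force convolution oracle
(`obs_density_numeric`) over a 20×20 grid of `(Z_O, σ_Z)`.

## Information gain

The gain of one measurement is the KL divergence of the posterior from the
prior, evaluated in the better-conditioned observation form
`∫ p(Z|Z_O)·log[p(Z_O|Z)/p(Z_O)] dZ`. Reported in bits by default
(`bits = nats/ln 2`); both units are carried in `InfoResult`.

**Acentric (closed form).** The acentric posterior is a normal distribution
with location `Z_O − σ²` and scale `σ`, truncated to `Z ≥ 0`. The KL
divergence therefore reduces to truncated-normal moments (via the normal
hazard function, evaluated through `erfcx` on one branch and `erfc` on the
other) plus the closed-form `log p(Z_O)`. The implementation is vectorized
and handles ~10⁵ reflections per tens of milliseconds.

Beyond `σ_Z ≈ 100` the closed form subtracts `σ²`-scale terms whose
round-off exceeds the true `O(σ⁻⁴)` value, so the ultra-weak branch switches
to the exponential-tilt expansion
`D_KL ≈ (4Z_O² − 16Z_O + 20)/(8σ⁴)` (nats), verified against 50-digit
arithmetic to ~0.1% at the switchover.

**Centric (numeric).** Adaptive quadrature of the posterior-weighted
log-ratio over `E`, with the closed-form centric `log p(Z_O)`. Quadrature
uses relative (not absolute) tolerance 1e−10, because the unnormalized
posterior mass of improbable observations can sit hundreds of orders of
magnitude below unity, and explicit breakpoints at
`E = √(Z_O + kσ)` for `k ∈ {−8,−3,0,3,8}` so the integrator cannot step over
narrow likelihood peaks when `σ_Z` is small.

**Oracle.** `info_gain_numeric` integrates the same KL integral directly in
`Z` using only numerically convolved densities — no closed forms — and is
the reference both analytic paths are tested against (rel. tol. 1e−6
acentric, 1e−5 centric). Its integration window is capped jointly by the
Gaussian reach (`Z_O ± 12σ`) and the prior tail (50 acentric / 90 centric),
whichever is tighter; far outside the representable density range
(`(Z_O/σ)² > ~1200`, density below ~1e−260) it raises rather than returning
noise.

**A note on monotonicity.** Information decreases strictly with `σ_Z`. It
increases with `Z_O` *above* roughly the prior mean, but is not globally
monotone: a strongly negative or near-zero `Z_O` also pins the posterior
(at zero) and thus carries some information, producing a shallow minimum
near `Z_O ≈ 0.5–1`. The property tests assert strict growth for
`Z_O ≥ 1.5`.

## Expected information and the I/σ correspondence

`expected_info_gain(σ_Z)` averages the per-observation gain over the
distribution of observations at fixed `σ_Z`. The average is taken over
**non-negative** observed intensities without renormalization — sub-zero
net intensities contribute zero — which is the convention under which the
published expected-information threshold tables and the I/σ correspondences
hold (mean I/σ = 1 ↔ 0.35 bits; mean I/σ = 2.5 ↔ ~1 bit). The full
real-line average (the textbook mutual information) is about 30% larger
because of the negative-tail contribution described above; the package
deliberately reports the thresholding convention, and the Monte-Carlo
consistency tests score negative draws as zero accordingly. The integral is
evaluated in the scaled variable `u = Z_O/σ` so a single tolerance works for
all `σ`, and beyond `σ_Z = 10³` (≈ 4e−7 bits) the `1/σ²` asymptote is used.

`sigma_for_info` and `sigma_for_expected_info` invert these curves by
bracketed root-finding on `log σ` (Brent, rel. tol. 1e−6), which is how a
bits threshold becomes a single normalized-σ cutoff.

## Likelihood targets

All targets are log-likelihood gains over the Wilson null, so a model with
`σ_A = 0` scores exactly zero.

* `exact_llg` marginalizes the Gaussian intensity likelihood over the model
  error distribution of the true amplitude (Rice for acentric, folded
  normal for centric, both centred on `σ_A·E_C` with variance `1 − σ_A²`)
  by quadrature, minus the closed-form null log density. `σ_A = 1` is the
  perfect-model limit and collapses to a Gaussian log-ratio, which is also
  what makes the identity *information gain (nats) = posterior-averaged
  perfect-model LLG* hold; the test suite verifies it to 1e−4 relative.
* `llg_fw` is the inflated-variance Rice target: the posterior amplitude
  moments (`E_FW`, `σ_FW`; computed by direct numerical integration of the
  posterior rather than the historical lookup-table algorithm — the content
  is the same, and the worked reference values reproduce to ≤ 0.01)
  are treated as an amplitude observation with `2σ_FW²` (acentric) or
  `σ_FW²` (centric) added to the model variance in both the model and null
  denominators.
* `llgi` is the intensity-based approximation: an effective amplitude `E_e`
  and weight `D_obs ∈ [0,1]` are chosen so the effective Rice/folded-normal
  distribution of the true amplitude matches the first two posterior
  moments exactly (solved by bracketed root-finding on `D_obs`; the weight
  is ill-conditioned when the posterior is almost exactly the prior, but
  every near-solution yields the same near-flat target, so the
  ill-conditioning is harmless). `D_obs → 1` recovers the plain Rice
  target; `D_obs → 0` makes the target flat — the observation simply stops
  influencing anything, which is the safe behaviour for junk data.

On the reference curves (`Z_O = 2`, `σ_A = 0.8`, `Z_C ∈ [0,4]`) the
moment-matched target tracks the exact one to < 0.05 nats at every noise
level tested, while the inflated-variance target's error grows from ~0.06
to ~1 nat as the information content falls from 3 bits to 0.01 bits — the
quantitative form of "prune weak data if you must use amplitude targets;
keep everything if you use intensity targets".

`rms_llg_error` is the r.m.s. spread of `llg_fw` across true
amplitudes drawn from the observation's posterior, in the perfect-model
limiting case, in bits. Note it does **not** vanish for exact measurements:
even at `σ_Z → 0` the score across posterior-consistent truths fluctuates
like `(1 − u²)/2` with `u` standard normal, giving a floor of `√½` nats
≈ 1.02 bits. What matters is the *ratio* to the information gain, which
drops below 1 only for observations above ~1 bit.

## Dataset analysis

Reflection tables are pandas DataFrames with canonical columns. The
pipeline `normalize → analyze → prune` never mutates its input.

* **Normalization** divides by `ε·Σ`. If `SIGMA_EXPECTED` is supplied it is
  used exactly (this is the right path whenever anisotropy or tNCS are
  present — those corrections must come from an upstream analysis, and
  skipping them makes systematically strengthened reflections look more
  informative). Otherwise `Σ(s²)` is estimated isotropically as binned
  means of `I/ε` (20 equal-count bins in `1/d²`, log-linear interpolation,
  non-positive bin means clamped), requiring ≥ 50 reflections.
* **Shells** are equal-population in `1/d³` order (the standard convention;
  the shell count, default 20, is a display choice, not part of the model).
* **Pruning** keeps a reflection iff its information is ≥ the threshold
  (strict "less than" exclusion), default 0.01 bits, in either `actual`
  (per-reflection KL) or `expected` (σ-only) mode.

## Synthetic data generator

`simulate()` emulates exactly the statistical structure the method assumes,
not a detector: Miller indices enumerated on one hemisphere of an
orthorhombic grid (default 50×60×70 Å cell, 2.5 Å limit — a typical small
protein crystal); true `Z` drawn from the Wilson prior per centricity
(default centric zone: the h0l plane, the section on which tNCS alternation
is conventionally displayed); expected intensity
`Σ = scale · exp(−B_iso·s²/2) · aniso(ΔB) · tncs(w, t)` with the tNCS proxy
`(1−w) + w(1 + cos 2π h·t)` — the two-copy interference pattern, mean 1,
which alternates intensities with index parity for `t = (0,0,½)`; and
additive Gaussian noise with a constant-σ_I profile by default, at a level
equal to `Σ(d_min)` so the outermost shell sits near `σ_Z ≈ 1` (mean I/σ
≈ 1, where real datasets are typically cut). One integer seed drives all
draws; a fixed seed reproduces the table bit-for-bit.

What it does *not* emulate: photon-counting statistics, partiality,
scaling/merging correlations, twinning, lattice translocation. Passing
tests on this generator demonstrates the statistical machinery, not
robustness to integration artefacts in real data.

Problem sizes used in the test suite (chosen to exercise the asymptotics at
interactive runtimes): 2 000–20 000-reflection datasets, 5×10⁴ draws for
shell averages, 10⁵ draws for Monte-Carlo cross-checks of posterior
moments.

## Numerical choices

* Quadrature: `scipy.integrate.quad` throughout, relative tolerance 1e−10
  (1e−11 for posterior moments), with explicit breakpoints at likelihood
  peaks; upper limits `E ≤ max(6, √(Z_O + 10σ) + 6)`.
* `D₋½` evaluation: scipy's `pbdv` for `|x| ≤ 25`; outside, the scaled
  value is computed from the integral representation rearranged so no
  factor overflows (smooth substitution `t = u²` on the positive axis, a
  unit-width Gaussian centred at `|x|` on the negative axis), valid beyond
  `|x| = 500`.
* Tie-break at the pruning boundary: exactly-at-threshold reflections are
  kept.
* Degenerate inputs: `σ_Z ≤ 0`, negative true intensities, invalid weights
  and malformed tables raise `ValueError` with the offending rows named;
  quadrature failure raises `ArithmeticError` with diagnostics rather than
  returning noise.

## Known limitations

* Centric per-reflection information is ~100× slower than acentric (one
  adaptive quadrature per reflection); datasets dominated by centric zones
  pay for it.
* The isotropic `Σ` estimator is a convenience, not an anisotropy analysis;
  with real anisotropic/tNCS data, supply a corrected `SIGMA_EXPECTED`.
* Twinning and lattice-translocation statistics are out of scope; both
  narrow the prior and would change every formula above.
* The `expected` / `actual` comparison conventions around negative net
  intensities are as described above; users averaging `INFO_BITS` columns
  themselves should be aware the per-reflection values are the exact KL for
  every sign of `Z_O`.
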