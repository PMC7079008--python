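# Methods

## The mechanism and its assumptions

The package models disulfide reduction as four coupled mass-action
reactions in a well-mixed, closed-but-not-sealed vessel:

| step | rate law | constant | units | default role |
|---|---|---|---|---|
| SS + Red → 2SH + Ox | k₁·[SS][Red] | k₁ | L mmol⁻¹ min⁻¹ | always fitted |
| 2SH + O₂ → SS | k₂·[2SH][O₂] | k₂ | L mmol⁻¹ min⁻¹ | opt-in |
| 2SH → precipitate | k₃·[2SH] | k₃ | min⁻¹ | opt-in |
| gas → O₂ | k₄ | k₄ | mmol L⁻¹ min⁻¹ | opt-in |

Assumptions worth stating explicitly:

* **Single effective reduction step.**  TCEP and DTT reductions proceed
  through intermediates (a thiophosphonium adduct, a mixed disulfide), but
  both are represented by one bimolecular constant k₁.  Microscopic
  protonation equilibria and pH dependence are outside scope; k₁ is an
  apparent constant at the buffer pH.
* **Literal reoxidation stoichiometry.** One O₂ is consumed per disulfide
  reformed.  The true chemistry consumes ½ O₂; since the absolute dissolved
  O₂ concentration is never observed, the factor is absorbed into k₂ and
  the (free) initial O₂.
* **Zero-order O₂ ingress.**  Oxygen enters from the gas phase at a
  constant rate k₄ rather than by film transfer k_La([O₂]_sat − [O₂]);
  over the relevant regime (O₂ far below saturation) the two coincide.  An
  optional saturation cap (`o2_cap`, disabled by default) prevents
  unbounded accumulation in long simulations.
* **Precipitation is first order** in the reduced species and irreversible;
  precipitated protein is a separate, non-reactive pool, so "soluble
  total" (ss + sh) can shrink while overall mass is conserved.

Units are fixed package-wide: mmol L⁻¹ and minutes (k₁, k₂ numerically
equal mM⁻¹ min⁻¹ values).

## Numerical choices

* Integration: LSODA with rtol 1e−8, atol 1e−10 mmol L⁻¹.  The state at
  t = 0 is returned exactly.  Negative excursions ≤1e−8 mmol L⁻¹ are
  clipped to zero; anything larger raises, as do protein/reductant pool
  drifts above 1e−6 relative.
* Half-life: t½ = ln(2 − c_SS,0/c_Red,0)/(k₁(c_Red,0 − c_SS,0)).  The same
  expression is used on both sides of c_SS,0 = c_Red,0 — the log argument
  and the denominator change sign together — and it agrees with the
  integrated trajectory's half-crossing time in both regimes (tested to
  0.1 %).  At c_SS,0 = c_Red,0 the removable singularity is replaced by its
  limit 1/(k₁ c_SS,0); at c_SS,0 ≥ 2 c_Red,0 the SS pool's stoichiometric
  floor (c_SS,0 − c_Red,0) is at or above half its start, the crossing time
  diverges, and the half-life is reported as undefined rather than by a
  formula value.
* Fitting: `scipy.optimize.least_squares` (Levenberg–Marquardt) over
  log-transformed parameters, which enforces positivity without bound
  constraints and makes the reported relative SDs scale-free.  Residuals
  are unweighted concentration differences.  Standard errors come from the
  SVD of the Jacobian at the optimum (σ² = SSE/(n−p)); the delta method
  maps them back to the natural scale, and CI half-widths use Student-t
  quantiles with n − p degrees of freedom.  A Jacobian singular value
  below ~1e−12 of the largest marks the parameters loaded on its null
  vector as unidentifiable: they are flagged and reported with infinite
  SE/CI instead of a misleading finite number (e.g. k₁ requested with no
  reductant present).  Multi-start fitting (`n_starts`) spreads
  initializations over ±2 orders of magnitude and reports the relative
  spread of the optima; the test suite requires ≤0.1 %.
* Regressions: the Arrhenius fit (ln k₁ vs 1/T, Ea = −slope·R,
  R = 8.314 J mol⁻¹ K⁻¹) and the length regression (ln t½ vs n) are plain
  OLS via `numpy.linalg.lstsq`; R² is computed in log space, where the
  model is linear.  Both are permutation-invariant and are cross-checked
  against `statsmodels` OLS in the tests.  With zero variance in the
  response and a perfect fit, R² is defined as 1.
* Deconvolution: alternating least squares.  The weights step solves, per
  spectrum, min‖Cw − x‖ subject to w ≥ 0, Σw = 1 *exactly*, by enumerating
  active sets and solving the equality-constrained normal equations on
  each support (exhaustive and exact for the ≤4 components this package
  targets).  The components step is unconstrained least squares per
  wavelength.  Both steps weakly decrease the reconstruction SSE, which is
  asserted at every iteration; convergence is declared when the relative
  SSE drop falls below `tol` (default 1e−8, `max_iter` 1000).
  Initialization is deterministic — the two mutually most distant spectra —
  with an optional seeded perturbation for replicate studies.  Component
  identity is assigned by the helix band: the component more negative near
  222 nm is labelled folded and ordered first.  An input ensemble whose
  rank is below the requested number of components is factorized anyway
  but flagged `degenerate` (the weights are then not unique).
* Signal conversions: the CD mapping uses only the trace shape (it is
  affine-invariant), so the absolute concentration scale must come from an
  external [SS]₀; when no plateau value is supplied, θ∞ is estimated as the
  mean of the final 10 % of points (configurable).  Converted
  concentrations outside [0, [SS]₀] are clipped with a warning count.
  NMR integrals are normalized to the reference standard before the ratio
  is formed — the normalization cancels algebraically but is kept as a
  drift diagnostic.  Negative CPMG rates (intensity above reference, i.e.
  noise) are returned flagged, not truncated, to keep noise statistics
  unbiased.

## The synthetic-data generator

The generator stands in for raw monitoring data, which are not deposited.
Its defaults are the reference experiment's conditions: 0.113 mmol L⁻¹
protein, 18-fold reductant excess, k₁ = 8.03×10⁻⁴ L mmol⁻¹ min⁻¹, 40
log-spaced samples from 1 to 3300 min (log spacing mirrors the practice of
sampling the reduction phase densely), additive Gaussian noise with sd
2 % of [SS]₀.  Noisy concentrations are clipped at zero; at these noise
levels the clipping is immaterial to the estimator (checked: it moves the
median recovered k₁ by <0.01 percentage points).  The NMR forward model
renders integrals proportional to the noisy oxidized/reduced fractions
with a constant reference integral; the CD forward model applies the
affine concentration→ellipticity map (θ₀ = −10, θ∞ = +5 deg cm² dmol⁻¹ at
287 nm by default).  Both invert exactly through the observables module at
zero noise.  Because the reduced-state channel is derived from the same
integrals as the oxidized one, recovery studies fit the oxidized series
alone; feeding both channels into an unweighted fit would double-count
observations and understate the confidence intervals.

The melt generator produces two-state ensembles: a helix-like folded basis
(Gaussian bands: +60 at 193 nm, −32 at 208 nm, −33 at 222 nm, widths
9–10 nm) and a coil-like unfolded basis (−40 at 198 nm, +4 at 218 nm) on a
185–260 nm grid, mixed by a falling logistic folded fraction
f(T) = 1/(1 + e^{s(T − Tm)}).  The default design is 12 variants × 17
temperatures (5–85 °C in 5 °C steps, 204 spectra) with midpoints spread
over 30–74 °C and steepness 0.12 °C⁻¹, a realistic spread for miniprotein
variants of graded stability.

What the generators deliberately do **not** emulate: baseline drift and
wavelength-correlated CD noise, NMR integration errors from peak overlap,
temperature-dependent basis spectra, multiplicative noise, and any
structure in the residuals.  Passing recovery tests therefore demonstrate
estimator correctness and calibration under the stated noise model, not
robustness to systematic instrument error.

## Study-level choices

* The k₁-recovery study (100 seeded replicates) reports the median
  relative bias (<2 % required) and nominal 95 % CI coverage (≥90 %
  required); 40-point series keep each fit under ~50 ms so the full study
  runs in seconds.
* Half-lives computed from tabulated k₁ values with *nominal* initial
  concentrations (1.7 mmol L⁻¹ protein, twofold reductant) agree with the
  tabulated half-lives only to ~3–8 %: the tabulated values derive from
  fitted initial concentrations, so the package asserts a 15 % band and
  documents the gap rather than tuning inputs to match.
* In the TCEP length regression the shortest variant's half-life is
  entered as exactly 1 min (it is only known as "≈1"); this reproduces the
  published regression coefficients.
* The outer-helix length n counts residues N-terminal of the first
  cysteine (17, 9, 3, 0 across the four variants).
* CSD composites use absolute values: reference cage scores are positive
  sums, so deviation signs are dropped (an assumption — the original
  normalization of the cage reference is not restated in the source data).
  Random-coil reference shifts are not embedded; CSDs are consumed
  pre-computed.
* The ensemble deconvolution is a simplified convex factorization without
  a simplex-volume criterion, so published per-spectrum percentages from
  the original analysis are matched qualitatively, not quantitatively;
  quantitative recovery is demonstrated on ground-truth-known synthetic
  ensembles instead.

## Known limitations

* k₂, k₃, k₄ are often weakly identified by reduction-phase data alone
  (the fitter flags them rather than failing); designed experiments
  spanning the reoxidation phase are needed to pin them down.
* No weighting or error model beyond homoscedastic Gaussian residuals; no
  hierarchical multi-experiment fitting; no Bayesian uncertainty.
* The deconvolution assumes a shared wavelength grid, no missing values,
  and a small number of components (the exact simplex solver enumerates
  active sets, which is exponential in the component count).
* Structure-derived inputs (RMSD, CSDs) are taken as given; the package
  computes descriptors from them but does not process coordinates or raw
  spectra.
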