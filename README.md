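# ssredox

Kinetic analysis of disulfide-bond reduction in Trp-cage miniproteins.

Single structural disulfides in small, folded proteins can take hours to
days to reduce even under standard TCEP/DTT protocols, because the ordered
polypeptide around the S–S bond shields it from nucleophilic attack, and
because dissolved O₂ continuously reoxidizes the freed thiols.  `ssredox`
is a library (plus analysis drivers and a CLI) for quantifying this: it
converts spectroscopic monitoring signals (near-UV CD ellipticity traces,
¹H NMR integral ratios) into concentrations, fits a four-reaction
mass-action mechanism to the time courses, and computes the derived
quantities used to compare protein variants — second-order half-lives,
Arrhenius activation energy, the exponential dependence of half-life on
outer-helix length, and composite steric descriptors.  It is aimed at
anyone who needs reduction kinetics of disulfide proteins on a quantitative
footing (protocol design, variant comparison, recombinant-protein QC).

## Model

The soluble protein interconverts between the oxidized (SS) and reduced
(2SH) states inside a coupled redox cycle:

    SS + Red  →(k₁)  2SH + Ox        bimolecular reduction (Sₙ2)
    2SH + O₂  →(k₂)  SS              bimolecular reoxidation
    2SH       →(k₃)  precipitate     first-order loss to the solid phase
    gas       →(k₄)  O₂              zero-order oxygen ingress

with concentrations in mmol L⁻¹ and time in minutes (k₁, k₂ in
L mmol⁻¹ min⁻¹, k₃ in min⁻¹, k₄ in mmol L⁻¹ min⁻¹).  The ODE system is
integrated with a stiff-capable solver; protein (ss + sh + precipitated)
and reductant (red + ox) pools are conserved to ≤1e−6 relative.

Key derived quantities:

* **half-life** of the oxidized species under pure second-order reduction:
  t½ = ln(2 − c_SS,0/c_Red,0) / (k₁ (c_Red,0 − c_SS,0)), with the limit
  1/(k₁ c_SS,0) at equal concentrations; undefined when the protein exceeds
  a twofold excess over the reductant (the SS pool can never halve);
* **Arrhenius analysis**: OLS of ln k₁ on 1/T, Ea = −slope·R;
* **length regression**: ln t½ is linear in the outer-helix length n,
  t½ = a·e^{bn};
* **steric factor**: x = n·RMSD/([ΣCSD_Hα(i)]/i) of the outer helix;
* **signal conversions**: c(t) = (θ∞ − θ(t))/(θ∞ − θ₀)·[SS]₀ for CD traces,
  ss = c_total·Int_OX/(Int_OX + Int_RED) for NMR integrals, and
  R₂ = −ln(I_i/I_ref)/t_CPMG for relaxation data;
* **ensemble deconvolution**: thermal far-UV CD ensembles are factorized
  into pure folded/unfolded component curves and per-spectrum convex
  weights by alternating constrained least squares (weights on the
  probability simplex, solved exactly per spectrum).

Parameters are estimated by Levenberg–Marquardt least squares on
log-transformed rate constants, with standard errors from the Jacobian and
Student-t confidence intervals (n − p degrees of freedom).

## Worked example

Fit the reduction rate constant of a synthetic experiment emulating NMR
monitoring of the longest variant (0.113 mmol L⁻¹ protein, 18-fold TCEP
excess, 40 log-spaced samples to 3300 min, 2 % noise):

```python
import ssredox as sx

rep = sx.generate_time_course(sx.e19_nmr_design(seed=0))
series = sx.ObservedSeries(times=rep.series.times, ss_obs=rep.series.ss_obs,
                           c_red0=rep.series.c_red0, c_ss0=0.113)
fit = sx.fit_mechanism(series, ("k1",), fixed_values={"ss0": 0.113})
print(fit.report())
hl = sx.half_life(fit.estimates["k1"], 0.113, 18 * 0.113)
print(f"t1/2 = {hl.value:.0f} min")
```

prints

```
Least-squares fit: 40 points, 1 parameter(s), SSE = 0.000126348 (mmol/L)^2, alpha = 0.05
parameter       estimate     std error   CI half-width  rel SD %
k1           0.000809501   1.18287e-05     2.39257e-05      1.46
t1/2 = 428 min
```

i.e. the fit recovers the generating k₁ = 8.03×10⁻⁴ L mmol⁻¹ min⁻¹ within
one percent (estimate 8.10×10⁻⁴, relative SD 1.5 %), and the implied
half-life of ~7 hours shows why short reduction protocols leave such a
protein partly oxidized.

The numbered drivers under `analysis/` run the full analyses and write
tables under `results/`: `01` simulates and classifies the three redox
regimes (reduction-dominated, steady state with incomplete conversion,
late reoxidation), `02` runs the k₁-recovery study (median bias −0.45 %,
95 % CI coverage 92 % over 100 replicates), `03` the Arrhenius analysis
(Ea = 44.5 kJ mol⁻¹), `04` the helix-length and steric-factor analyses
(TCEP: t½ = 2.07·e^{0.371n}, R² = 0.95; DTT extrapolation to n = 17 gives
≈30 460 min), and `05` the CD-ensemble deconvolution (folded fractions
recovered to ≤0.007 RMS at 2 % noise).

The same stages are available as a CLI:

```sh
ssredox --out-dir run synth --k1 1e-3 --ss0 1.0 --red0 2.0 --t-end-min 2000 --noise-sigma 0
ssredox --out-dir run fit run/synthetic_series.csv --fix ss0=1.0
ssredox --out-dir run arrhenius k_vs_T.csv
ssredox --out-dir run lengthfit dtt.csv --extrapolate 17
```

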