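# Methods

## Model

Two-sample summary-data MR treats each instrument j as providing a noisy
ratio estimate of a common causal effect θ (log odds of outcome per SD of
exposure). With harmonized exposure effect bx_j (SE sx_j) and outcome
effect by_j (SE sy_j), the working model is

    by_j = θ0 + θ·bx_j + ε_j,    Var(ε_j) = φ²·sy_j²

fitted by weighted least squares with weights 1/sy_j². The estimators
differ in what they constrain:

* **IVW, fixed effects**: θ0 ≡ 0, φ ≡ 1. Closed form
  θ̂ = Σ w bx by / Σ w bx², SE = (Σ w bx²)^(−1/2), normal p-values.
* **IVW, multiplicative random effects**: same point estimate; φ̂² =
  weighted RSS/(L−1) rescales the SE. φ is *not* floored at 1, so
  underdispersed instrument sets yield intervals narrower than the
  fixed-effect ones. This matches published tables in which the
  random-effects interval is sometimes the tighter of the two, which is
  impossible under flooring.
* **MR-Egger**: θ0 free; variants first oriented so every bx_j > 0 (the
  estimate is only identified up to that allele-coding convention). The
  intercept estimates the mean directional pleiotropic effect; its t-test
  (L−2 df) is the pleiotropy diagnostic. Fitted via statsmodels WLS, whose
  default scale is exactly the unfloored φ².
* **Weighted/simple median**: per-variant ratios r_j = by_j/bx_j with
  delta-method SE sy_j/|bx_j|; sorted ratios get percentile positions
  100·(S_j − w_j/2)/S_L (S_j cumulative weight) and the estimate is the
  linear interpolation at the 50th percentile. Consistent while valid
  instruments hold a majority of the weight. SEs come from a parametric
  bootstrap (default 1000 draws, seeded): bx and by resampled from normals
  at their SEs and the median recomputed.
* **Wald ratio** for a single instrument: by/bx, SE sy/|bx|.

95% intervals always use the exact 0.975 normal quantile 1.959964; all
intervals and p-values for IVW/median/Wald are normal-based, Egger's are
t-based (L−2 df).

## Sensitivity diagnostics

* **Cochran's Q** over the per-variant ratios with weights (bx/sy)²;
  identical to the weighted RSS of the fixed-effect fit. I² =
  100·max(0, (Q−df)/Q), reported as a whole percent in tables with full
  precision retained internally. Flags use p < 0.05; the published
  narrative threshold of 0.01 appears in sources as well, so the raw p is
  always stored.
* **MR-PRESSO**: the observed statistic is Σ_j w_j (by_j − θ̂_(−j)·bx_j)²
  with leave-one-out IVW slopes θ̂_(−j), so each variant is judged against
  a fit excluding it. The null distribution simulates by*_j ~
  N(θ̂_(−j)·bx_j, sy_j) and recomputes the statistic, leave-one-out slopes
  included (vectorised over simulations). Empirical p-values use the
  (1+k)/(1+n) estimator, so they can never be zero; per-variant outlier
  p-values are Bonferroni-multiplied by L and flagged at 0.05, and the
  fixed-effect IVW is refitted without flagged outliers. Default 5000
  simulations (1000 is the commonly recommended floor). The distortion
  test is not implemented; the outlier-corrected estimate is reported
  instead.
* **Steiger filtering**: per variant, compare variance explained in the
  exposure with variance explained in the outcome, both via
  r² = v·β²/(v·β² + v·se²·N). For the binary outcome this applies the
  continuous-trait formula on the log-odds scale with N the total outcome
  sample size — an approximation (no liability-scale conversion), recorded
  as such. direction_ok requires r²_exp > r²_out; the p-value is a
  two-sided z-test on Fisher-transformed |r| with variances 1/(N−3). An
  aggregate test uses the summed r² per side.
* **Leave-one-out**: fixed-effect IVW refitted L times with one instrument
  removed, plus the all-instrument reference row.

## Meta-analysis and power

Cohort estimates are pooled by fixed-effect inverse-variance weighting on
the log-OR scale. When a study is given as OR with 95% CI, its SE is
(ln hi − ln lo)/(2·1.959964); a warning is raised when ln OR sits more
than 0.01 off the log-interval midpoint, since published rounding then
contaminates the recovered SE (pooled values are expected to wobble by a
couple of units in the third decimal for this reason). Random-effects
pooling is deliberately out of scope — with two cohorts the heterogeneity
variance is essentially unestimable.

Power for a binary outcome uses a normal approximation in the style of
the mRnd calculator: noncentrality ν = |ln OR|·√(N·R²·K·(1−K)) with case
fraction K, and power = 1 − Φ(z_{1−α/2} − ν) + Φ(−z_{1−α/2} − ν). It is
validated by its analytic properties (power = α at OR 1, monotonicity,
the ν = 2.8016 → 80% anchor), not against external calculators.

## Instrument selection

Filters apply in a fixed order for the removal tally (p-value, chromosome,
biallelic, MAF, exclusion list) but commute as predicates. The p-value
threshold is strict (`<`). Clumping is greedy by ascending p-value, ties
broken by (chromosome, position, rsid); removal requires the same
chromosome, distance ≤ window (boundary inclusive) and r² ≥ threshold.
LD is a user input (square r² table); without it, variants are treated as
independent with a loud warning — the package never downloads a reference
panel. PhenoScanner-style confounder screening is replaced by the
exclusion list. Variants with F below the cutoff (default 10) are dropped
before estimation.

## Synthetic-data generator

The generator emulates the statistical structure the estimators assume: a
standardized continuous exposure (microbiome abundance after rank
transformation) measured in n_exp subjects and a binary outcome (log-odds
scale) in n_out subjects with case fraction K. Defaults are the emulated
study conditions: n_exp = 18,340; n_out = 33,970; K = 6692/33,970 ≈ 0.197
(a second cohort configuration, 7427/33,027 ≈ 0.225, is reachable through
the config); L = 10 instruments jointly explaining h² = 5% of exposure
variance, giving per-instrument F ≈ 90 so that, like the emulated studies,
no weak instruments arise and essentially all variants clear the
locus-wide 1e-5 threshold; EAF uniform on (0.1, 0.9).

Per variant: v = 2·eaf·(1−eaf); true effects γ_j have random sign and are
scaled so Σγ²v = h²; exact analytic SEs sx = 1/√(n_exp·v) and
sy = 1/√(n_out·K(1−K)·v); observed effects are normal draws around γ and
θγ + α. Pleiotropic effects α are zero ("none"), N(0, sd) ("balanced"),
or sign(γ)·N(mean, sd) ("directional") — directional pleiotropy is defined
relative to the exposure-increasing allele, since with random instrument
signs an orientation-agnostic mean would cancel under the Egger
orientation and be undetectable in principle. The InSIDE-violating mode
additionally correlates α with |γ| (correlation 0.7). Defaults sd = 0.02
(comparable to a typical per-variant outcome SE, i.e. pleiotropy large
enough to matter without drowning the signal) and mean = 0.05 (twice a
typical outcome SE, a clearly directional but not cartoonish violation).
Outliers shift by_j by a configured multiple of sy_j. The
reverse-causation mode puts the primary association on the outcome and
lets the exposure inherit θ-scaled effects, which Steiger filtering should
reject. Same seed → byte-identical tables.

What the generator does **not** emulate: LD between instruments (clumping
is exercised with explicit LD-matrix fixtures), realistic allele-frequency
spectra, winner's-curse selection of instruments, sample overlap between
cohorts, and population stratification. Passing calibration tests
therefore demonstrates correctness of the estimators under their own
assumptions, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

* SEs below 1e-12 are treated as exact zeros (exact-fit fixtures): the
  corresponding p-value is 1 for a zero estimate, 0 otherwise.
* Empirical p-values are floored at 1/(n_sim+1) by construction.
* Harmonization keeps dropped variants in its output with the reason
  recorded, so audits and count-conservation checks are trivial;
  estimation filters to the usable subset.
* Zero exposure effects make the Wald ratio undefined: fatal for a single
  instrument, excluded with a log entry inside the median estimator.
* Chromosome "X" is recoded to 23 on input; positions are 1-based. BED
  intervals are converted to 1-based closed; GFF3 used as-is. Gene
  overlap is closed-interval on both ends; strand is carried but ignored.
* Missing outcome EAF is permitted; such palindromic variants are dropped
  (they cannot be frequency-aligned), and Steiger falls back to the
  exposure EAF.

## Calibration results the test suite pins

Under the generator defaults (all seeded, hence exactly reproducible):
fixed-effect IVW type-I error 0.052 at nominal 0.05 (1000 replicates,
L = 50); mean IVW estimate 0.247 for θ = 0.25 with 94.4% CI coverage
(500 replicates, L = 30); a planted 10·SE outlier flagged by MR-PRESSO
with significant global p in 100% of 100 runs; MR-PRESSO global p under
the null significant in 3% of 200 runs; the Egger intercept within 2 SE
of zero in 92.4% of 500 balanced-pleiotropy replicates (slightly below
nominal because the multiplicative residual scale mismodels additive
heterogeneity — a known property of this weighting, accepted rather than
patched); directional pleiotropy (mean 0.05) detected in 77% of
replicates at L = 30, with mean IVW bias ≈ 0.60 against ≈ 0.15 for Egger.
Monte-Carlo problem sizes (500–1000 replicates, 100 PRESSO runs) were
chosen to keep each suite's statistical error well below the asserted
margins while the whole suite runs in seconds.

## Known limitations

Reading native consortium release formats, genome-build liftover,
multi-allelic decomposition, proxy-SNP lookup, LD computation from
genotypes, radial MR/Rucker framework diagnostics, mode-based and
multivariable estimators, and the MR-PRESSO distortion p-value are out of
scope. The binary-outcome Steiger r² and the power formula are
approximations on the log-odds scale.
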