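# Methods

This note describes, in the package's own words, the generative model
behind the synthetic data, the statistical procedures of the analysis
pipeline, and their known properties and limitations.

## Imaging model and response extraction

Trials are 13 s at 10 Hz (130 frames): 2 s pre-stimulus baseline, 3 s
stimulus, 8 s post-stimulus. All frame windows are half-open,
`[start, end)`; the stimulus window is frames 20–49 inclusive (30
frames).

Relative fluorescence change is `dF/F(t) = (F(t) − Fb)/Fb`, with `Fb`
the mean over the pre-stimulus window. The scalar response amplitude is
the mean dF/F over the stimulus window, averaged over trials (by
linearity, identical to the window mean of the trial-averaged course).
Missing (fly, glomerulus) combinations stay missing; nothing is
imputed, and every comparison reports how many complete cases entered.

**Cross-species normalization.** Each species' amplitudes are
multiplied by (mean of the two species' grand means)/(that species'
grand mean). The operation equalises the grand means exactly, preserves
all within-species ratios and is idempotent. It removes indicator- and
preparation-level gain differences but also any true global sensitivity
difference, so only *patterns* across glomeruli and odours are
interpreted downstream.

**Side pooling.** When both brain sides are measured, a four-factor
ANOVA (species, odour, glomerulus, side; two-way interactions) is run
and the side-containing terms are BH-adjusted as one family. Sides are
averaged only if no term is significant; otherwise they are kept
separate with a warning.

## Synthetic generator

Per glomerulus × odour, baseline tuning amplitudes are gamma(2, 0.25)
distributed. The second species' tuning is
`rectify(tuning_A + shift · D)` with `D` standard normal per cell and
`shift` the species divergence (default 0.08). Binary mixtures combine
component tunings with a divisive-normalization rule
`out = (a + b) / (1 + k · mean(a + b))`.

The temporal kernel rises as a saturating exponential (τ_rise) during
the stimulus and decays toward `tonic_fraction` of its end value after
offset (τ_decay), spanning phasic to tonic dynamics. Each fly carries a
lognormal gain `exp(σ_species · z)`; the defaults σ = (0.45, 0.15) give
the first species three times the fly-to-fly log-spread of the second.
Raw fluorescence is `F(t) = F0 · (1 + g · tuning · h(t)) + ε` with
Gaussian trial noise. Movies are rendered from traces onto a label-mask
grid with per-pixel noise; extraction inverts this exactly in the
noiseless limit.

All random streams derive from one seed through
`SeedSequence(seed, spawn_key=(crc32(label),))`, so every stage is
reproducible and independently re-runnable.

**Volumes.** Mean volume fractions over 32 named glomeruli are shared
between species except for six designed shifts in percentage points
(default +1.0 on DL1, DL5, DM4 and −1.0 on VA1d, VA1v, VA2, with the
unshifted fractions renormalised to compensate). The second species'
total AL volume is 1.5× the first's. Per-fly totals and per-glomerulus
volumes carry multiplicative lognormal noise (log-sd 0.10 each);
n = 10 flies/species by default.

**Behaviour.** Seven four-choice trap conditions (three reference
odours crossed with {same odour, odour + acetic acid mixture, acetic
acid}, duplicates removed). Each replicate releases a uniform 20–50
flies distributed multinomially over {bait 1, bait 2, oil, empty,
platform} in proportion to fixed attractiveness weights — identical
across species by design, with mixtures weighted above their
components.

## Statistics

**ANOVA.** Fixed-effects n-way ANOVA with interactions up to order 2 by
default, using partial (Type-II) sums of squares so unbalanced designs
are order-independent; on balanced designs this equals the textbook
decomposition (verified against a closed-form oracle). Factors with a
single observed level are dropped and recorded, never silently
absorbed. Terms with numerically zero sum of squares are reported as
F = 0, p = 1 by convention. Kolmogorov–Smirnov normality checks are
attached as advisory metadata, not as gates.

**Multiple comparisons.** Benjamini–Hochberg step-up adjustment within
explicitly declared families: all per-glomerulus species contrasts form
one family, per-odour contrasts another, the side-containing ANOVA
terms another, and each species' behavioural pairwise contrasts
another.

**Within/between distances.** Per-fly coding vectors (33 glomerular
amplitudes per odour) are compared by Euclidean distance over all
unordered fly pairs, partitioned into within-species and
between-species sets. Because pair distances sharing a fly are not
independent, the default test permutes *fly labels* (10,000 draws,
two-sided, +1-corrected p) on the statistic
T = mean(within) − mean(between); it is exact under exchangeability of
flies. A Wilcoxon rank-sum variant on the distance lists is provided
for comparison but inherits the non-independence caveat.

*Conservatism note.* In the full pipeline the permutation test runs
after cross-species normalization, which uses the true species labels.
Under the null this label-dependent preprocessing couples the two
groups and makes the test conservative: the measured pipeline-level
type-I rate at α = 0.05 is ~0–2 % over hundreds of null seeds, while
the same test on raw amplitudes rejects at ~3–5 %, i.e. the machinery
itself is calibrated. Conservative behaviour only strengthens positive
findings.

**Shared-basis PCA.** One SVD basis is fitted on the pooled,
column-mean-centred, subject-averaged time-resolved responses of both
species (k = 3), with a deterministic sign convention
(largest-magnitude loading positive). Each species is projected through
the *same* routine, so species trajectories differ only because their
data differ — re-projecting one species alone reproduces its joint-call
coordinates bitwise. Rank deficiency is reported via the effective
nonzero-component count.

**Clustering.** Odour codes (per species, glomerulus × odour amplitude
matrices) are clustered with Ward's minimum-variance linkage and cut at
70 % of the maximum merge height; labels are renumbered by first
occurrence so assignments are deterministic. The linkage is verified
against a brute-force ESS-increment oracle (merge height
√(2·ΔESS)).

**Morphometry.** Relative volumes (percent of the per-fly AL total,
either the sum of listed glomeruli or a supplied whole-AL total) are
invariant to global AL scaling, so a pure size difference yields no
species main effect; reallocation between glomeruli appears as a
species × glomerulus interaction, localised by FDR-corrected
per-glomerulus contrasts with effect directions.

## Known limitations

* **Exact volume-set recovery saturates near 75 %.** The six designed
  shifts are essentially always detected (per-glomerulus recall ≈ 0.97
  at the default effect size), but requiring the significant set to
  equal *exactly* the designed six also requires zero false positives
  among the 26 null glomeruli. Under BH at q = 0.05 the chance of a
  clean sweep is ≈ (1 − 7·0.05/32)²⁶ ≈ 0.75, independent of the true
  effect size; the measured exact-recovery rate (~0.74) matches this
  ceiling. This is a property of FDR control, not of the
  implementation, and is deliberately left visible in the acceptance
  suite rather than hidden by loosening the criterion.
* The permutation test's conservatism after normalization (above) means
  pipeline-level power figures understate the machinery's raw power.
* The generator's noise is Gaussian/lognormal and trials are i.i.d.;
  slow drift, motion and bleaching are out of scope.
* Problem sizes used throughout testing: 2 species × 12 flies × 33
  channels × 8 odours × 10 trials for imaging; n = 10/species × 32
  glomeruli for volumes; 7 conditions × 8 replicates × 2 species for
  behaviour.
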