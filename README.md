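# glomcode

Comparative analysis of glomerular odour codes in the fly antennal lobe.

## The scientific problem

Two closely related *Drosophila* species can occupy very different
ecological niches — one laying eggs in overripe, fermenting fruit, the
other in ripening fruit — and the first olfactory relay, the antennal
lobe (AL), is where such behavioural divergence could first appear in
the nervous system. The AL is organised into glomeruli, each pooling
the input of one receptor type, so an odour is represented as a vector
of activation amplitudes across glomeruli ("the odour code").

Comparing these codes across species raises several coupled analysis
problems that this package solves as one pipeline:

1. **Response extraction.** Calcium-imaging movies must be reduced to
   per-glomerulus ΔF/F time courses, trial-averaged, and summarised as
   stimulus-window response amplitudes.
2. **Cross-species comparability.** Indicator expression and optical
   conditions differ between preparations, so each species is rescaled
   to a common grand-mean amplitude before any comparison; only
   relative patterns are interpreted.
3. **Coding-space statistics.** Are the two species' codes drawn from
   the same distribution? The pipeline compares within-species against
   between-species Euclidean distances of per-fly coding vectors with a
   fly-label permutation test, projects both species' time-resolved
   codes through a single shared PCA basis, and clusters odours by
   Ward's criterion.
4. **Morphometry.** Whole-AL size differences (one species' AL is ~1.5×
   larger) must not masquerade as coding differences, so glomerular
   volumes are compared as percentages of each fly's total AL volume.
5. **Behaviour.** A four-choice trap assay (two baits, oil control,
   empty control, plus a release platform) links coding to preference;
   trap proportions are analysed per bait family with ANOVA and
   FDR-corrected pairwise contrasts.

A fully parameterised synthetic-data generator produces fluorescence
movies/traces, glomerular volumes and trap counts with known ground
truth, which makes every statistical claim of the pipeline testable.

## Worked example

A small but complete run (6 flies/species, 8 glomeruli, 4 trials):

```python
import numpy as np
from glomcode import synthetic, extraction, coding, morphometry
from glomcode.synthetic import SimConfig

cfg = SimConfig(n_flies_per_species=6, n_glomeruli=8, n_trials=4, seed=42)
traces = synthetic.gen_traces(cfg)
print("traces:", traces.values.shape)

amps = extraction.cross_species_normalize(extraction.amplitude_table(traces))
print(amps.groupby("species")["amplitude"].mean())

vectors = coding.coding_vectors(amps, list(cfg.glomeruli))
rng = np.random.default_rng(np.random.SeedSequence(42, spawn_key=(11,)))
sums = coding.distance_summaries(vectors, n_perm=5000, rng=rng)
for s in sums[:3]:
    t = s.tests
    print(f"{s.odour:>16}:  suzukii p={t['suzukii'].pvalue:.4f} "
          f"({t['suzukii'].direction}), melanogaster "
          f"p={t['melanogaster'].pvalue:.4f} ({t['melanogaster'].direction})")

codes = coding.time_resolved_codes(traces)
pca, traj = coding.fit_shared_pca(codes, k=3)
print("explained variance %:", np.round(100 * pca.explained_variance_ratio_, 1))

vols = synthetic.gen_volumes(cfg, shifts=synthetic.default_volume_shifts())
res = morphometry.volume_species_test(morphometry.relative_volumes(vols))
print(res.significant[["glomerulus", "diff", "p_fdr", "direction"]].to_string(index=False))
```

Output:

```text
traces: (3072, 130)
species
melanogaster    0.456915
suzukii         0.456915
Name: amplitude, dtype: float64
(Z)-3-hexenyl acetate:  suzukii p=0.0440 (within_smaller), melanogaster p=0.1754 (within_larger)
       1-hexanol:  suzukii p=0.0044 (within_smaller), melanogaster p=0.3125 (within_larger)
     2-heptanone:  suzukii p=0.0004 (within_smaller), melanogaster p=0.7712 (within_larger)
explained variance %: [63.5 15.9 10.4]
glomerulus      diff        p_fdr    direction
       DL1 -1.404313 1.679363e-08      suzukii
       DL5 -0.938319 2.045761e-05      suzukii
      VA1v  1.069396 3.671461e-10 melanogaster
      VA1d  1.084343 1.007378e-06 melanogaster
       DM4 -0.824835 4.679351e-05      suzukii
       VA2  1.098418 1.433281e-06 melanogaster
```

The designed pattern is visible at a glance: normalization equalises the
species' grand means exactly; the low-fly-variance species (`suzukii`
analog) clusters tighter than the between-species spread while the
high-variance species does not; the shared PCA concentrates the
signal in the first components; and the volume contrasts recover the
six glomeruli whose relative volumes the generator shifted (three
enlarged in one species, three in the other), with the correct
directions.

### Command line

```sh
glomcode run --seed 0 --out run0        # full pipeline, ~20 output CSVs
glomcode report --out run0              # print run0/summary.json
glomcode analyze-volumes --seed 0 --out vols
```

Re-running with the same seed reproduces `summary.json` byte for byte.

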