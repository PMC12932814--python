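# cccfp — copper-chloride-crystallisation fingerprint evaluation

Copper chloride crystallisation (CCC) characterises a complex sample — here
mistletoe (*Viscum album*) extracts used in phytotherapy — by letting the
sample co-crystallise with CuCl₂ on a glass plate. The resulting dendritic
pattern (the *fingerprint*) is measured by image analysis, and a factorial
experiment asks whether the measurements separate sample groups: mistletoe
subspecies (subsp. *album*, VAA, from deciduous hosts vs subsp.
*austriacum*, VAAu, from pine), host tree within the deciduous subspecies
(apple vs oak), and the pharmaceutical blending procedure (machine vs
hand). `cccfp` implements the full evaluation chain for that design, plus a
synthetic fingerprint simulator so every stage can be exercised and tested
without laboratory scans.

## What the package computes

**Design.** The standard Verum run crosses 6 experimental days × 2
chambers (each chamber carries one production batch, 2109 or 2204) × 6
samples (3 host trees × 2 blendings) × 4 technical replicates = **288
fingerprints** (48 per day). Subspecies is derived from the host tree, not
free: pine → VAAu, apple/oak → VAA.

**Features.** Per fingerprint, 15 second-order texture variables from a
grey-level co-occurrence matrix (one-pixel horizontal + vertical offsets,
ROI 0–100 % of the plate radius) and 15 needle-length outcome measures
from the skeletonised pattern (ROI 0–90 %). Seven variables carry the
analysis:

| variable | meaning |
|---|---|
| `entropy` | −Σ p(i,j) ln p(i,j): information content of the pattern |
| `cluster_shade` | Σ (i+j−μₓ−μᵧ)³ p(i,j): grey-level skewness |
| `diagonal_moment` | Σ \|i−j\|(i+j−μₓ−μᵧ) p(i,j): signed roughness of bright/dark areas |
| `kappa` | (P₀−Pₑ)/(1−Pₑ): chance-corrected consistency |
| `lend` | number of needle end-points (degree-1 skeleton pixels) |
| `l220` | needles with length in [19.2, 22.0) px |
| `l250` | needles with length ≥ 22.0 px |

**Randomisation.** Systematic-control measurements (one extract in all 43
chamber positions) are normalised to day means; 6×4 block partitions of
the 24 used positions are searched at random (2 × 10⁶ candidates by
default) to minimise the SD of block means, the winner must show no
location effect (one-way ANOVA, p > α), and a random 6×6 Latin square
rotates every sample through every block across the six days.

**Statistics.** Per variable: 4-way fixed-effects ANOVA (sum-to-zero
coding, Type-II sums of squares) with main effects and two-way
interactions; Fisher's LSD pairwise comparisons only when the F-test has
p < 0.01 (protected LSD); Cohen's d = (x̄₁−x̄₂)/s_pooled for the contrast of
interest; and a per-day drill-down when a day interaction is flagged. The
three sensitivity tests use 288, 192 (pine excluded) and 288 fingerprints
respectively.

## Worked example

```python
import cccfp
from cccfp.synthesis import EffectSpec, generate_feature_table

design = cccfp.build_verum_design(6)            # 288 plates
spec = EffectSpec(effects={"l250": {"subspecies": 1.76},
                           "l220": {"deciduous": 0.57},
                           "lend": {"blending": 0.28}},
                  residual_sigma=1.0, seed=7)
features = generate_feature_table(design, spec)  # direct-mode synthesis
results = cccfp.run_sensitivity_test(features, design, "subspecies")
print(results.summary().round(4).to_string(index=False))
```

prints

```
       variable      p stars  effect_size effect_label interactions
          kappa 0.2291             0.1524   negligible            -
diagonal_moment 0.7497             0.0386   negligible            -
        entropy 0.7795             0.0354   negligible            -
  cluster_shade 0.9524             0.0075   negligible            -
           lend 0.6525             0.0545   negligible            d
           l220 0.0261             0.2798        small            -
           l250 0.0000   ***       1.8736        large            -
```

Only `l250` — the one variable given a subspecies contrast in this
synthetic configuration — reaches the p < 0.01 threshold in the
subspecies test, with a recovered |d| ≈ 1.87 against the generating 1.76
(single-replicate sampling error at 192 vs 96 is ≈ 0.14). `l220`'s and
`lend`'s generating contrasts (apple vs oak, machine vs hand) are
orthogonal to the subspecies pooling, so they stay near the noise floor
here; the flagged day interaction for `lend` at p ≈ 0.65 main effect is a
type-I event at the 0.01 interaction screen.

The same chain runs end-to-end from rendered images
(`cccfp run --config cfg.yaml` with `mode: synthetic-image`) or from a
directory of scanned plates (`mode: from-images`). The CLI exposes
`simulate`, `features`, `randomise`, `evaluate` and `run`.

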