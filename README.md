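# citrusect

Cross-section image analysis of citrus fruit: a pipeline that dissects
sensorily scored fruit-quality traits (easiness of peeling, fruit
hardness) into quantitative morphological features of the fruit
cross-section.

Because the original scan data are not publicly deposited, the package
ships a first-class synthetic generator that renders citrus cross-sections
(concentric flavedo/albedo rings, radial flesh locules separated by septa,
seeds, a central core with optional degradation cavity, albedo degradation
gaps) with exact ground-truth region masks and trait scores derived from
the ground-truth morphology.

## Pipeline stages

| module | role |
| --- | --- |
| `citrusect.synthetic` | fruit renderer, population sampler (genotype x year), trait-score generator |
| `citrusect.segmentation` | recover the 8 region masks (Whole, Flavedo, Albedo, DegAlbedo, Flesh, Seed, Center, DegCenter) from an RGB image |
| `citrusect.features` | the 21 morphological features (areas, CIE L\*a\*b\* colors, circularity, locule statistics, albedo thickness) |
| `citrusect.blup` | mixed-model year adjustment; REML BLUPs as per-genotype expected values |
| `citrusect.association` | collinearity filter, MLR, shadow-feature random-forest importance, partial dependence, decision-path interactions, repeated shared-fold CV, apparent vs partial correlations |
| `citrusect.bayesnet` | Gaussian BIC structure learning (hill climbing, tabu), trait-endpoint blacklist, bootstrap arc strength/direction, consensus network |
| `citrusect.cnn` / `citrusect.relevance` | from-scratch numpy CNN, binary trait classification, Grad-CAM, per-region relevance with a between-class rank test |

## CLI

```sh
citrusect simulate --config cfg.yaml --out data/ --seed 1
citrusect segment  --image data/images/F00000.png --out label.png
citrusect features --images-dir data/images --masks-dir data/masks --out features.csv
citrusect adjust   --in long.csv --out genotype_values.csv
citrusect associate --matrix genotype_values.csv --traits Peeling,FruH --out assoc/
citrusect network  --matrix genotype_values.csv --trait Peeling --algorithm hc \
                   --replicates 5000 --seed 1 --out net/
citrusect xai      --data data/ --trait Peeling --seed 1 --out xai/
```

`simulate` writes PNG images, paletted label PNGs (0 = background, 1–8 =
regions) with a JSON label map, a ground-truth feature CSV, and a trait
table (continuous score, ordinal 1–5 category, binary class).

## Notes

- No deep-learning framework is assumed: the CNN (three 3x3 conv blocks,
  global average pooling, dense head, Adam) and Grad-CAM are implemented
  directly on numpy with exact analytic gradients (finite-difference
  checked in the test suite).
- The default training protocol mirrors the reference setup (224x224
  inputs, Adam, lr 1e-5, batch 30, 50 epochs, flip/rotation
  augmentation, min-validation-loss checkpointing);
  `TrainConfig.test_profile()` is a desk-scale profile used in CI.
- Bayesian-network scores are decomposable Gaussian BICs on the
  higher-is-better scale; single-arc reversals are score-equivalent, so
  bootstrap direction confidence for unorientable arcs hovers near 0.5.
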