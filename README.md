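# melonqmon

Non-destructive fruit-quality monitoring for netted muskmelon from RGB
images. The pipeline segments the fruit from a blue backdrop with an
excess-blue index (2B − R − G) and Otsu thresholding, extracts 65 external
phenotype parameters (45 color statistics over RGB/CIELAB/HSV, 6 gray-level
co-occurrence texture statistics, 14 contour morphology descriptors),
screens them against internal quality traits by Pearson correlation
(P < 0.05), and fits random-forest regression models per trait — a full
model on all screened features and a simplified model on the top 10 by
permutation importance.

Because no image cohort is publicly deposited, a seeded synthetic generator
produces melon-on-backdrop scenes with ripeness-linked coloration and
netting texture, ground-truth masks, and internal phenotypes monotonically
linked to the same latent ripeness, at the study's cohort geometry
(134 fruits × 3 views = 402 images by default).

## Command-line usage

```bash
# generate a synthetic cohort (images/, masks/, phenotypes.csv)
melonqmon simulate --n-fruits 134 --views 3 --seed 0 --out scratch/cohort

# segment one image
melonqmon segment --in scratch/cohort/images/fruit0000_v0.png \
    --out-mask scratch/mask.png --polarity backdrop_high

# extract the 65 features for every image/mask pair
melonqmon extract --images scratch/cohort/images --masks scratch/cohort/masks \
    --out scratch/features.csv --glcm-levels 64 --glcm-distance 1

# Pearson screening at alpha = 0.05
melonqmon screen --features scratch/features.csv \
    --phenotypes scratch/cohort/phenotypes.csv \
    --out scratch/screen.csv --plot scratch/screen.png

# full and simplified models for one trait
melonqmon train    --features scratch/features.csv --phenotypes scratch/cohort/phenotypes.csv \
    --screen scratch/screen.csv --trait sucrose --seed 42 --out scratch/sucrose.json
melonqmon simplify --features scratch/features.csv --phenotypes scratch/cohort/phenotypes.csv \
    --screen scratch/screen.csv --trait sucrose --seed 42 --k 10 --out scratch/sucrose_simplified.json

# or everything at once from a config
melonqmon run-all --config configs/default.yaml
```

`configs/default.yaml` reproduces the study-scale synthetic run (402 images;
ntree = 300, mtry tuned over 1..min(100, p) by 10-fold × 3 cross-validated
RMSE, 2/3–1/3 train/validation split, top-10 simplification). Note the
default mtry grid is exhaustive and slow; pass `mtry_grid: [5, 10, 20, 40]`
for a quick run.

## Package layout

- `melonqmon.synthetic` — seeded scene/phenotype/cohort generator
- `melonqmon.segmentation` — excess-blue index, Otsu mask, cleaning chain
- `melonqmon.features` — the 65-parameter extractor (color/GLCM/morphology)
- `melonqmon.screening` — Pearson screening, selection, profile plot
- `melonqmon.modeling` — RF tuning/fit, metrics (both R² forms), permutation
  importance, top-k simplification
- `melonqmon.pipeline` — YAML-config orchestration, run manifest, IO checks
- `melonqmon.cli` — the `melonqmon` entry point

Two R² conventions are reported everywhere: `r2_explained` is the explained-SS
over total-SS form (which can exceed 1 for non-least-squares predictors) and
`r2_conventional` is 1 − SSres/SStot; thresholds use the conventional form.
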