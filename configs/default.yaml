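# Default end-to-end run at study scale.
#
# Study-sourced constants: n_fruits=134, views_per_fruit=3 (402 images),
# alpha=0.05, ntree=300, cv_folds=10, cv_repeats=3, top_k=10,
# train_fraction=0.6667, mtry_grid null = 1..min(100, p).
# Everything else (image size, segmentation fractions, GLCM settings) is an
# artifact default, not a study fact.
out_dir: scratch/run
seed: 0
n_fruits: 134
views_per_fruit: 3
image_size: [320, 320]
noise_frac: 0.116
polarity: backdrop_high
min_object_frac: 0.005
min_hole_frac: 0.001
opening_radius: 5
white_balance: false
max_side: null
glcm_levels: 64
glcm_distance: 1
alpha: 0.05
aggregation: mean
ntree: 300
mtry_grid: null
cv_folds: 10
cv_repeats: 3
train_fraction: 0.6666666666666666
top_k: 10
traits: [fructose, glucose, sucrose, total_sugar, tss, vitamin_c, chl_a, chl_b, carotenoids]
stages: [simulate, segment, extract, screen, train]
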