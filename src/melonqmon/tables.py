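"""Fixed vocabularies: the 65 external feature names, their categories and
ordering, and the internal trait envelopes used by the synthetic generator
and the I/O validators."""

from __future__ import annotations

COLOR_CHANNELS = ("R", "G", "B", "L", "a", "b", "H", "S", "V")
COLOR_STAT_NAMES = ("mean", "sd", "median", "range", "cv")

COLOR_FEATURES = tuple(
    f"{ch}_{stat}" for ch in COLOR_CHANNELS for stat in COLOR_STAT_NAMES
)

TEXTURE_FEATURES = (
    "contrast",
    "dissimilarity",
    "homogeneity",
    "energy",
    "correlation",
    "asm",
)

MORPHO_FEATURES = (
    "contour_area",
    "perimeter",
    "w",
    "h",
    "hull_area",
    "x_w",
    "x_h",
    "MA",
    "ma",
    "r",
    "equivalent_diameter",
    "aspect_ratio",
    "extent",
    "solidity",
)

#: All 65 feature names in canonical (numbering) order: 45 color, 6 texture,
#: 14 morphology.
FEATURE_NAMES = COLOR_FEATURES + TEXTURE_FEATURES + MORPHO_FEATURES

#: 1-based feature number by name.
FEATURE_NUMBER = {name: i + 1 for i, name in enumerate(FEATURE_NAMES)}

#: Category by feature name.
FEATURE_CATEGORY = {
    **{name: "color" for name in COLOR_FEATURES},
    **{name: "texture" for name in TEXTURE_FEATURES},
    **{name: "morphology" for name in MORPHO_FEATURES},
}

CATEGORIES = ("color", "texture", "morphology")

#: Internal trait names in canonical order.
TRAIT_NAMES = (
    "fructose",
    "glucose",
    "sucrose",
    "total_sugar",
    "tss",
    "vitamin_c",
    "chl_a",
    "chl_b",
    "carotenoids",
)

#: Observed (min, max) envelope per trait, in the trait's native unit.
TRAIT_ENVELOPES = {
    "fructose": (4.79, 71.12),
    "glucose": (0.21, 72.25),
    "sucrose": (1.05, 46.90),
    "total_sugar": (10.20, 164.20),
    "tss": (5.80, 18.50),
    "vitamin_c": (3.38, 110.84),
    "chl_a": (0.27, 1.64),
    "chl_b": (0.16, 1.12),
    "carotenoids": (0.12, 0.40),
}

TRAIT_UNITS = {
    "fructose": "mg/g",
    "glucose": "mg/g",
    "sucrose": "mg/g",
    "total_sugar": "mg/g",
    "tss": "%",
    "vitamin_c": "mg/100 g",
    "chl_a": "mg/g",
    "chl_b": "mg/g",
    "carotenoids": "mg/100 g",
}


def feature_category_counts(feature_names) -> dict:
    """Count how many of `feature_names` fall in each category."""
    counts = {cat: 0 for cat in CATEGORIES}
    for name in feature_names:
        counts[FEATURE_CATEGORY[name]] += 1
    return counts
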