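"""Pearson screening of external features against internal traits.

Per (feature, trait) pair: product-moment r, two-sided p from the t
distribution with n-2 df, selection at p < alpha (0.05 default, no multiple
testing correction), and the -log10(p) profile plot with the threshold line
at -log10(0.05) = 1.301.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .tables import FEATURE_NAMES, FEATURE_NUMBER, TRAIT_NAMES

DEFAULT_ALPHA = 0.05

SCREEN_COLUMNS = ("trait", "feature", "feature_no", "r", "p", "neg_log10_p", "selected")


def aggregate_views(features: pd.DataFrame, how: str = "mean") -> pd.DataFrame:
    """Collapse an image-level feature table to fruit level.

    ``how="mean"`` averages a fruit's views; ``how="per_view"`` keeps one row
    per image (phenotypes are then replicated at join time). The input needs
    ``fruit_id`` plus the 65 feature columns.
    """
    if "fruit_id" not in features.columns:
        raise ValueError("feature table must have a fruit_id column")
    if features["fruit_id"].isna().any():
        raise ValueError("every image must be assigned to a fruit")
    cols = [c for c in FEATURE_NAMES if c in features.columns]
    if how == "mean":
        return features.groupby("fruit_id", sort=True)[cols].mean().reset_index()
    if how == "per_view":
        return features[["fruit_id", *cols]].reset_index(drop=True)
    raise ValueError(f"unknown aggregation mode {how!r}")


def pearson_screen(
    features: pd.DataFrame,
    phenotypes: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Screen every (feature, trait) pair; returns the long-format result.

    Complete-case per trait. A constant feature or trait makes r undefined:
    the pair is kept with NaN r/p and ``selected=False`` (never silently
    selected).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    merged = features.merge(phenotypes, on="fruit_id", how="inner")
    feat_cols = [c for c in FEATURE_NAMES if c in features.columns]
    trait_cols = [c for c in TRAIT_NAMES if c in phenotypes.columns]
    rows = []
    for trait in trait_cols:
        tvals = merged[trait].to_numpy(dtype=float)
        for feat in feat_cols:
            fvals = merged[feat].to_numpy(dtype=float)
            ok = np.isfinite(fvals) & np.isfinite(tvals)
            x, y = fvals[ok], tvals[ok]
            if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                r, p, nlp, sel = np.nan, np.nan, np.nan, False
            else:
                r, p = stats.pearsonr(x, y)
                p = max(float(p), np.finfo(float).tiny)
                nlp = -np.log10(p)
                sel = p < alpha
            rows.append(
                {
                    "trait": trait,
                    "feature": feat,
                    "feature_no": FEATURE_NUMBER[feat],
                    "r": float(r) if np.isfinite(r) else np.nan,
                    "p": p,
                    "neg_log10_p": nlp,
                    "selected": bool(sel),
                }
            )
    return pd.DataFrame(rows, columns=list(SCREEN_COLUMNS))


def selected_features(result: pd.DataFrame, trait: str) -> list:
    """Selected feature names for one trait, in canonical feature order."""
    sub = result[(result["trait"] == trait) & result["selected"]]
    return sub.sort_values("feature_no")["feature"].tolist()


def threshold_line(alpha: float = DEFAULT_ALPHA) -> float:
    """The -log10 significance threshold drawn in the profile plot."""
    return float(-np.log10(alpha))


def screening_plot(result: pd.DataFrame, out_path, alpha: float = DEFAULT_ALPHA):
    """Per-trait -log10(p) vs feature number profile with the alpha line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result.empty:
        raise ValueError("empty screening result")
    traits = [t for t in TRAIT_NAMES if t in set(result["trait"])]
    ncols = 3
    nrows = int(np.ceil(len(traits) / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4.2 * ncols, 3.0 * nrows), squeeze=False
    )
    line = threshold_line(alpha)
    for ax, trait in zip(axes.ravel(), traits):
        sub = result[result["trait"] == trait]
        ax.scatter(sub["feature_no"], sub["neg_log10_p"], s=12)
        ax.axhline(line, color="black", lw=1)
        ax.set_title(trait)
        ax.set_xlabel("feature no.")
        ax.set_ylabel(r"$-\log_{10} P$")
    for ax in axes.ravel()[len(traits):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
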