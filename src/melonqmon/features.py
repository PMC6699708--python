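"""The 65 external phenotype features: 45 color statistics, 6 gray-level
co-occurrence texture statistics, 14 contour morphology descriptors.

Color statistics are mean/SD/median/range/CV of nine channels (RGB, CIELAB,
HSV) over the fruit mask only. Texture uses a mask-restricted co-occurrence
matrix so zeroed background pixels never contribute pairs. Morphology is
computed from the cleaned single-component mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from skimage.color import rgb2hsv, rgb2lab
from skimage.measure import label, regionprops

from .tables import (
    COLOR_CHANNELS,
    COLOR_STAT_NAMES,
    FEATURE_NAMES,
    MORPHO_FEATURES,
    TEXTURE_FEATURES,
)


class EmptyMaskError(ValueError):
    pass


@dataclass(frozen=True)
class GlcmConfig:
    levels: int = 64
    distance: int = 1
    angles: tuple = (0, 45, 90, 135)
    symmetric: bool = True
    normalized: bool = True

    def validate(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")


@dataclass(frozen=True)
class FeatureVector:
    """The 65 features in canonical order plus extraction provenance."""

    values: np.ndarray
    image_id: str = ""
    mask_threshold: float | None = None
    working_scale: float = 1.0
    names: tuple = field(default=FEATURE_NAMES)

    def __post_init__(self):
        if len(self.values) != len(self.names):
            raise ValueError(f"expected {len(self.names)} values, got {len(self.values)}")

    def to_series(self) -> pd.Series:
        return pd.Series(np.asarray(self.values, dtype=float), index=list(self.names))

    def __len__(self) -> int:
        return len(self.values)


def convert_channels(image: np.ndarray, mask: np.ndarray) -> dict:
    """Nine per-pixel channels over the fruit mask.

    R/G/B in 0-255; L in 0-100 with a/b signed (CIELAB, D65); H in degrees
    0-360 with S/V in 0-1 (hexcone HSV).
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise ValueError("image/mask shape mismatch")
    if not mask.any():
        raise EmptyMaskError("mask has no foreground pixels")
    pixels = image[mask].astype(np.float64)  # (N, 3) in 0-255
    rgb01 = pixels / 255.0
    lab = rgb2lab(rgb01)
    hsv = rgb2hsv(rgb01)
    return {
        "R": pixels[:, 0],
        "G": pixels[:, 1],
        "B": pixels[:, 2],
        "L": lab[:, 0],
        "a": lab[:, 1],
        "b": lab[:, 2],
        "H": hsv[:, 0] * 360.0,
        "S": hsv[:, 1],
        "V": hsv[:, 2],
    }


def channel_stats(values: np.ndarray) -> tuple:
    """(mean, sample SD, median, range, CV) of one channel's foreground values.

    CV = SD/mean, defined as 0 when the mean is 0; single value gives SD 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    median = float(np.median(v))
    rng = float(v.max() - v.min())
    cv = sd / mean if mean != 0.0 else 0.0
    return mean, sd, median, rng, cv


def quantize_gray(image: np.ndarray, levels: int) -> np.ndarray:
    """Quantize masked RGB to gray levels 0..levels-1 using the luma weights."""
    img = np.asarray(image, dtype=float)
    gray = 0.2125 * img[..., 0] + 0.7154 * img[..., 1] + 0.0721 * img[..., 2]
    return np.minimum((gray / 256.0 * levels).astype(np.intp), levels - 1)


_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_matrix(gray: np.ndarray, mask: np.ndarray, config: GlcmConfig) -> np.ndarray:
    """Mask-restricted gray-level co-occurrence probability matrix.

    Pairs are counted only where both pixels lie inside the mask, at
    ``config.distance`` times each angle's unit offset; per-angle matrices are
    symmetrized, normalized, then averaged.
    """
    config.validate()
    gray = np.asarray(gray)
    mask = np.asarray(mask, dtype=bool)
    if gray.shape != mask.shape:
        raise ValueError("gray/mask shape mismatch")
    if gray.max(initial=0) >= config.levels:
        raise ValueError("gray values exceed the configured level count")

    d = config.distance
    per_angle = []
    for angle in config.angles:
        if angle not in _ANGLE_OFFSETS:
            raise ValueError(f"unsupported angle {angle}; use 0/45/90/135")
        dr, dc = (d * o for o in _ANGLE_OFFSETS[angle])
        h, w = gray.shape
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        src = np.s_[r0:r1, c0:c1]
        dst = np.s_[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = mask[src] & mask[dst]
        counts = np.zeros((config.levels, config.levels), dtype=float)
        np.add.at(counts, (gray[src][valid], gray[dst][valid]), 1.0)
        if config.symmetric:
            counts = counts + counts.T
        total = counts.sum()
        if total > 0:
            per_angle.append(counts / total if config.normalized else counts)
    if not per_angle:
        raise ValueError("no valid pixel pairs inside the mask")
    return np.mean(per_angle, axis=0)


def texture_stats(P: np.ndarray) -> dict:
    """Six co-occurrence statistics from a normalized probability matrix."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if not np.isclose(P.sum(), 1.0, atol=1e-8):
        raise ValueError("P must be normalized to sum 1")
    n = P.shape[0]
    i, j = np.mgrid[0:n, 0:n]
    diff = i - j
    contrast = float((P * diff**2).sum())
    dissimilarity = float((P * np.abs(diff)).sum())
    homogeneity = float((P / (1.0 + diff**2)).sum())
    asm = float((P**2).sum())
    energy = float(np.sqrt(asm))
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float((np.arange(n) * pi).sum())
    mu_j = float((np.arange(n) * pj).sum())
    sd_i = float(np.sqrt(((np.arange(n) - mu_i) ** 2 * pi).sum()))
    sd_j = float(np.sqrt(((np.arange(n) - mu_j) ** 2 * pj).sum()))
    if sd_i * sd_j == 0.0:
        correlation = 0.0
    else:
        correlation = float(((i - mu_i) * (j - mu_j) * P).sum() / (sd_i * sd_j))
    return {
        "contrast": contrast,
        "dissimilarity": dissimilarity,
        "homogeneity": homogeneity,
        "energy": energy,
        "correlation": correlation,
        "asm": asm,
    }


def _hull_corner_points(mask: np.ndarray) -> np.ndarray:
    """Convex hull vertices of the foreground, expanded to pixel corners so a
    side-n square measures n, not n-1."""
    coords = np.column_stack(np.nonzero(mask)).astype(float)
    if len(coords) < 3:
        corners = []
        for dy, dx in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5)):
            corners.append(coords + [dy, dx])
        return np.vstack(corners)
    hull = ConvexHull(coords)
    verts = coords[hull.vertices]
    corners = np.vstack(
        [verts + [dy, dx] for dy, dx in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))]
    )
    hull2 = ConvexHull(corners)
    return corners[hull2.vertices]


def min_area_rect(points: np.ndarray) -> tuple:
    """Rotating calipers over the hull: (long side, short side) of the
    minimum-area enclosing rectangle."""
    pts = np.asarray(points, dtype=float)
    if len(pts) == 1:
        return 0.0, 0.0
    hull = pts if len(pts) < 3 else pts[ConvexHull(pts).vertices]
    edges = np.roll(hull, -1, axis=0) - hull
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    edges = edges[lengths > 0] / lengths[lengths > 0, None]
    if len(edges) == 0:
        return 0.0, 0.0
    best = None
    for ux, uy in edges:
        proj1 = hull @ np.array([ux, uy])
        proj2 = hull @ np.array([-uy, ux])
        s1 = proj1.max() - proj1.min()
        s2 = proj2.max() - proj2.min()
        if best is None or s1 * s2 < best[0] * best[1]:
            best = (s1, s2)
    return (max(best), min(best))


def _circle_from(points) -> tuple:
    """Circumscribed circle of 1-3 points."""
    pts = [np.asarray(p, dtype=float) for p in points]
    if len(pts) == 0:
        return np.zeros(2), 0.0
    if len(pts) == 1:
        return pts[0], 0.0
    if len(pts) == 2:
        c = (pts[0] + pts[1]) / 2.0
        return c, float(np.linalg.norm(pts[0] - c))
    (ax, ay), (bx, by), (cx, cy) = pts
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        # collinear: fall back to the widest pair
        pairs = [(pts[0], pts[1]), (pts[0], pts[2]), (pts[1], pts[2])]
        far = max(pairs, key=lambda p: np.linalg.norm(p[0] - p[1]))
        return _circle_from(far)
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    c = np.array([ux, uy])
    return c, float(np.linalg.norm(pts[0] - c))


def min_enclosing_circle(points: np.ndarray, seed: int = 0) -> tuple:
    """Welzl's algorithm (iterative, expected linear): (center, radius)."""
    pts = np.asarray(points, dtype=float)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pts))
    P = pts[order]
    eps = 1e-9

    def inside(c, r, p):
        return np.linalg.norm(p - c) <= r + eps

    c, r = P[0], 0.0
    for i in range(1, len(P)):
        if inside(c, r, P[i]):
            continue
        c, r = P[i], 0.0
        for j in range(i):
            if inside(c, r, P[j]):
                continue
            c, r = _circle_from([P[i], P[j]])
            for k in range(j):
                if inside(c, r, P[k]):
                    continue
                c, r = _circle_from([P[i], P[j], P[k]])
    return c, float(r)


def morphology_stats(mask: np.ndarray) -> dict:
    """The 14 contour descriptors of a single-component mask, in pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("empty mask")
    labels, n = label(mask, connectivity=2, return_num=True)
    if n != 1:
        raise ValueError(f"expected a single connected component, found {n}")
    props = regionprops(labels)[0]

    area = float(props.area)
    minr, minc, maxr, maxc = props.bbox
    w = float(maxc - minc)
    h = float(maxr - minr)
    hull_area = float(props.area_convex)
    hull_pts = _hull_corner_points(mask)
    x_w, x_h = min_area_rect(hull_pts)
    _, radius = min_enclosing_circle(hull_pts)
    equivalent_diameter = float(np.sqrt(4.0 * area / np.pi))
    aspect_ratio = x_w / x_h if x_h > 0 else float("inf")
    return {
        "contour_area": area,
        "perimeter": float(props.perimeter),
        "w": w,
        "h": h,
        "hull_area": hull_area,
        "x_w": float(x_w),
        "x_h": float(x_h),
        "MA": float(props.axis_major_length),
        "ma": float(props.axis_minor_length),
        "r": radius,
        "equivalent_diameter": equivalent_diameter,
        "aspect_ratio": float(aspect_ratio),
        "extent": area / (w * h),
        "solidity": area / hull_area,
    }


def extract_features(
    image: np.ndarray,
    mask: np.ndarray,
    glcm_config: GlcmConfig | None = None,
    image_id: str = "",
    mask_threshold: float | None = None,
    working_scale: float = 1.0,
) -> FeatureVector:
    """All 65 features of one segmented fruit view, in canonical order."""
    if glcm_config is None:
        glcm_config = GlcmConfig()
    channels = convert_channels(image, mask)
    values = []
    for ch in COLOR_CHANNELS:
        values.extend(channel_stats(channels[ch]))
    gray = quantize_gray(image, glcm_config.levels)
    P = glcm_matrix(gray, mask, glcm_config)
    tex = texture_stats(P)
    values.extend(tex[name] for name in TEXTURE_FEATURES)
    morph = morphology_stats(mask)
    values.extend(morph[name] for name in MORPHO_FEATURES)
    return FeatureVector(
        values=np.asarray(values, dtype=float),
        image_id=image_id,
        mask_threshold=mask_threshold,
        working_scale=working_scale,
    )


def features_to_frame(rows) -> pd.DataFrame:
    """Stack (image_id, fruit_id, view, FeatureVector) rows into the CSV schema."""
    data = []
    for image_id, fruit_id, view, fv in rows:
        rec = {"image_id": image_id, "fruit_id": fruit_id, "view": view}
        rec.update(fv.to_series().to_dict())
        data.append(rec)
    return pd.DataFrame(data, columns=["image_id", "fruit_id", "view", *FEATURE_NAMES])
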