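"""Fruit segmentation: excess-blue index, Otsu threshold, mask cleaning.

The chain is: excess-blue index (2B - R - G, clipped to 8-bit) -> Otsu
threshold -> small-object removal -> hole filling -> morphological opening ->
largest-component selection -> masked image. The backdrop is blue-dominant,
so the index is high on the backdrop; the fruit mask is the complement
(``polarity="backdrop_high"``, the default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import (
    disk,
    opening,
    remove_small_holes,
    remove_small_objects,
)


class DegenerateImageError(ValueError):
    """Index image is constant; no threshold can separate it."""


class NoFruitFoundError(ValueError):
    """Mask is empty after cleaning."""


POLARITIES = ("backdrop_high", "fruit_high")


@dataclass(frozen=True)
class CleaningParams:
    min_object_area: int = 0
    min_hole_area: int = 0
    opening_radius: int = 0

    def validate(self) -> None:
        if min(self.min_object_area, self.min_hole_area, self.opening_radius) < 0:
            raise ValueError("cleaning parameters must be non-negative")


def default_cleaning_params(image_shape) -> CleaningParams:
    """Defaults scale with image area: objects < 0.5%, holes < 0.1%, disk 5."""
    area = int(image_shape[0]) * int(image_shape[1])
    return CleaningParams(
        min_object_area=max(1, round(0.005 * area)),
        min_hole_area=max(1, round(0.001 * area)),
        opening_radius=5,
    )


def excess_blue(image: np.ndarray) -> np.ndarray:
    """Per-pixel 2B - R - G, clipped to [0, 255], as uint8."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    rgb = img.astype(np.int32)
    idx = 2 * rgb[..., 2] - rgb[..., 0] - rgb[..., 1]
    return np.clip(idx, 0, 255).astype(np.uint8)


def threshold_mask(
    index: np.ndarray,
    polarity: str = "backdrop_high",
    return_threshold: bool = False,
):
    """Otsu-threshold the index image into a fruit mask.

    With ``backdrop_high`` the bright (blue-excess) side is the backdrop and
    the fruit mask is ``index <= t``; with ``fruit_high`` it is ``index > t``.
    """
    if polarity not in POLARITIES:
        raise ValueError(f"polarity must be one of {POLARITIES}")
    index = np.asarray(index)
    if index.min() == index.max():
        raise DegenerateImageError("index image is constant")
    t = threshold_otsu(index)
    mask = index > t if polarity == "fruit_high" else index <= t
    return (mask, t) if return_threshold else mask


def clean_mask(mask: np.ndarray, params: CleaningParams) -> np.ndarray:
    """Remove specks, fill holes, open, and keep the largest component."""
    params.validate()
    m = np.asarray(mask, dtype=bool)
    # max_size removes areas <= the value; the contract is "area < threshold"
    if params.min_object_area > 1:
        m = remove_small_objects(m, max_size=params.min_object_area - 1, connectivity=2)
    if params.min_hole_area > 1:
        m = remove_small_holes(m, max_size=params.min_hole_area - 1, connectivity=2)
    if params.opening_radius > 0:
        m = opening(m, disk(params.opening_radius)).astype(bool)
    labels, n = label(m, connectivity=2, return_num=True)
    if n == 0:
        raise NoFruitFoundError("mask is empty after cleaning")
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        m = labels == sizes.argmax()
    return m


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero the background; foreground pixels pass through unchanged."""
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise ValueError(f"shape mismatch: image {image.shape[:2]} vs mask {mask.shape}")
    if not mask.any():
        raise NoFruitFoundError("mask has no foreground pixels")
    return image * mask[..., None]


def gray_world_white_balance(image: np.ndarray) -> np.ndarray:
    """Optional pre-step: scale channels so their means are equal."""
    img = np.asarray(image, dtype=float)
    means = img.reshape(-1, 3).mean(axis=0)
    gain = means.mean() / np.maximum(means, 1e-9)
    return np.clip(np.rint(img * gain), 0, 255).astype(np.uint8)


def segment(
    image: np.ndarray,
    polarity: str = "backdrop_high",
    cleaning: CleaningParams | None = None,
    white_balance: bool = False,
):
    """Full chain from RGB image to cleaned fruit mask.

    Returns ``(mask, otsu_threshold)``.
    """
    if white_balance:
        image = gray_world_white_balance(image)
    if cleaning is None:
        cleaning = default_cleaning_params(np.asarray(image).shape[:2])
    index = excess_blue(image)
    raw, t = threshold_mask(index, polarity=polarity, return_threshold=True)
    return clean_mask(raw, cleaning), t
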