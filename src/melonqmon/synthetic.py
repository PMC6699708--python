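"""Seeded synthetic melon scenes and internal phenotypes.

Scenes are a single ellipse-shaped fruit with a procedural netting texture on
a uniform saturated-blue backdrop, so the excess-blue index separates backdrop
from fruit. Internal traits are monotone (logistic) functions of a latent
ripeness in [0, 1], scaled into each trait's observed envelope, with optional
seeded Gaussian noise. Fruit hue follows the same monotone link, so color
statistics carry signal for every trait.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .tables import TRAIT_ENVELOPES, TRAIT_NAMES

#: Steepness of the shared logistic ripeness link.
LINK_STEEPNESS = 6.0

#: Hue endpoints (degrees) for unripe (green) -> ripe (orange) fruit.
HUE_UNRIPE = 100.0
HUE_RIPE = 30.0

#: Default per-trait noise SD as a fraction of the trait's envelope width.
#: With uniform ripeness the logistic link has SD ~0.347, so 0.116 puts the
#: generative signal-to-total variance ratio near 0.9.
DEFAULT_NOISE_FRAC = 0.116


class InvalidGeometryError(ValueError):
    """Fruit ellipse does not fit inside the image frame."""


@dataclass(frozen=True)
class SceneParams:
    """Parameters for one rendered fruit view.

    ``fruit_axes`` are the ellipse semi-axes along (rows, cols).
    """

    image_size: tuple = (320, 320)
    fruit_center: tuple = (160.0, 160.0)
    fruit_axes: tuple = (110.0, 95.0)
    base_hue: float = 60.0
    net_density: float = 0.35
    net_brightness: int = 40
    backdrop_color: tuple = (30, 40, 220)
    illumination_gain: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        cy, cx = self.fruit_center
        ay, ax = self.fruit_axes
        if ay <= 0 or ax <= 0:
            raise InvalidGeometryError("fruit axes must be positive")
        if cy - ay < 0 or cy + ay > h - 1 or cx - ax < 0 or cx + ax > w - 1:
            raise InvalidGeometryError(
                f"fruit ellipse (center={self.fruit_center}, axes={self.fruit_axes}) "
                f"does not fit inside a {h}x{w} frame"
            )
        if not 0.0 <= self.net_density <= 1.0:
            raise ValueError("net_density must lie in [0, 1]")
        r, g, b = self.backdrop_color
        if 2 * b - r - g <= 0:
            raise ValueError("backdrop must be blue-dominant (2B - R - G > 0)")


@dataclass(frozen=True)
class LatentPhenotypes:
    ripeness: float
    trait_values: dict
    noise_sd: dict


@dataclass(frozen=True)
class CohortSpec:
    n_fruits: int = 134
    views_per_fruit: int = 3
    image_size: tuple = (320, 320)
    noise_frac: float = DEFAULT_NOISE_FRAC
    seed: int = 0

    def validate(self) -> None:
        if self.n_fruits < 1:
            raise ValueError("n_fruits must be >= 1")
        if self.views_per_fruit < 1:
            raise ValueError("views_per_fruit must be >= 1")


@dataclass(frozen=True)
class SceneRecord:
    """One view of one fruit: identifiers plus its render parameters."""

    fruit_id: str
    view: int
    params: SceneParams

    @property
    def image_id(self) -> str:
        return f"{self.fruit_id}_v{self.view}"


def ripeness_link(ripeness):
    """Strictly monotone logistic link mapping [0, 1] onto [0, 1] exactly."""
    k = LINK_STEEPNESS
    lo = expit(-k / 2.0)
    hi = expit(k / 2.0)
    return (expit(k * (np.asarray(ripeness, dtype=float) - 0.5)) - lo) / (hi - lo)


def ellipse_mask(image_size, center, axes) -> np.ndarray:
    """Analytic rasterization of a filled ellipse at pixel centers."""
    h, w = image_size
    cy, cx = center
    ay, ax = axes
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _hue_to_rgb(hue_deg: float, sat: float = 0.75, val: float = 0.72):
    rgb = colorsys.hsv_to_rgb((hue_deg % 360.0) / 360.0, sat, val)
    return np.array([c * 255.0 for c in rgb])


def generate_scene(params: SceneParams):
    """Render one fruit view; returns ``(rgb_image, ground_truth_mask)``.

    Identical params (including seed) give byte-identical arrays. The netting
    texture brightens all three channels equally, so fruit hue is untouched.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size

    mask = ellipse_mask(params.image_size, params.fruit_center, params.fruit_axes)

    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(params.backdrop_color, dtype=float)
    img[mask] = _hue_to_rgb(params.base_hue)

    if params.net_density > 0 and mask.any():
        noise = gaussian_filter(rng.random((h, w)), sigma=2.0)
        # strict > so density 0 would select nothing even at the max
        thresh = np.quantile(noise[mask], 1.0 - params.net_density)
        net = (noise > thresh) & mask
        img[net] += float(params.net_brightness)

    img *= params.illumination_gain
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask


def generate_phenotypes(ripeness: float, noise_sd=0.0, seed: int = 0) -> LatentPhenotypes:
    """Internal trait values for one fruit at the given latent ripeness.

    ``noise_sd`` is either a scalar fraction of each trait's envelope width,
    or a mapping of trait name to an absolute SD in the trait's unit. Values
    are clipped to the trait envelope, so with zero noise ripeness 0 and 1
    land exactly on the envelope minimum and maximum.
    """
    if not 0.0 <= ripeness <= 1.0:
        raise ValueError("ripeness must lie in [0, 1]")
    if isinstance(noise_sd, dict):
        sd_map = {t: float(noise_sd.get(t, 0.0)) for t in TRAIT_NAMES}
    else:
        frac = float(noise_sd)
        sd_map = {
            t: frac * (TRAIT_ENVELOPES[t][1] - TRAIT_ENVELOPES[t][0])
            for t in TRAIT_NAMES
        }
    if any(sd < 0 for sd in sd_map.values()):
        raise ValueError("noise SD must be non-negative")

    rng = np.random.default_rng(seed)
    link = float(ripeness_link(ripeness))
    values = {}
    for trait in TRAIT_NAMES:
        lo, hi = TRAIT_ENVELOPES[trait]
        v = lo + link * (hi - lo)
        if sd_map[trait] > 0:
            v += rng.normal(0.0, sd_map[trait])
        values[trait] = float(np.clip(v, lo, hi))
    return LatentPhenotypes(ripeness=float(ripeness), trait_values=values, noise_sd=sd_map)


def scene_params_for_fruit(
    ripeness: float,
    image_size: tuple,
    seed: int,
    jitter: float = 0.0,
) -> SceneParams:
    """Map ripeness to render parameters: hue and fruit size are monotone in
    ripeness through the shared link; `jitter` perturbs geometry per view."""
    link = float(ripeness_link(ripeness))
    h, w = image_size
    base = 0.30 * min(h, w)
    scale = 0.85 + 0.25 * link
    ay = base * scale
    ax = 0.87 * ay
    return SceneParams(
        image_size=image_size,
        fruit_center=(h / 2.0 + jitter, w / 2.0 - jitter),
        fruit_axes=(ay, ax),
        base_hue=HUE_UNRIPE + link * (HUE_RIPE - HUE_UNRIPE),
        net_density=0.25 + 0.3 * link,
        net_brightness=40,
        seed=seed,
    )


def generate_cohort(spec: CohortSpec):
    """Build a cohort of scene records plus the fruit-level phenotype table.

    Returns ``(records, phenotypes)`` where records is a list of SceneRecord
    (render images on demand with :func:`generate_scene`) and phenotypes is a
    DataFrame with a ``fruit_id`` column followed by the nine traits. All
    views of one fruit share its phenotypes; base hue is strictly monotone in
    ripeness across fruits.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ripeness = rng.uniform(0.0, 1.0, size=spec.n_fruits)
    view_seeds = rng.integers(0, 2**31 - 1, size=(spec.n_fruits, spec.views_per_fruit))
    pheno_seeds = rng.integers(0, 2**31 - 1, size=spec.n_fruits)
    jitters = rng.uniform(-3.0, 3.0, size=(spec.n_fruits, spec.views_per_fruit))

    records = []
    pheno_rows = []
    for i in range(spec.n_fruits):
        fruit_id = f"fruit{i:04d}"
        phen = generate_phenotypes(
            ripeness[i], noise_sd=spec.noise_frac, seed=int(pheno_seeds[i])
        )
        pheno_rows.append({"fruit_id": fruit_id, **phen.trait_values})
        for v in range(spec.views_per_fruit):
            params = scene_params_for_fruit(
                ripeness[i],
                image_size=spec.image_size,
                seed=int(view_seeds[i, v]),
                jitter=float(jitters[i, v]),
            )
            records.append(SceneRecord(fruit_id=fruit_id, view=v, params=params))
    phenotypes = pd.DataFrame(pheno_rows, columns=["fruit_id", *TRAIT_NAMES])
    return records, phenotypes


def write_cohort(records, phenotypes, out_dir, image_format: str = "png"):
    """Render and write a cohort to disk: images/, masks/, phenotypes.csv.

    Returns the list of written image paths.
    """
    import imageio.v3 as iio
    from pathlib import Path

    out = Path(out_dir)
    img_dir = out / "images"
    mask_dir = out / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)

    paths = []
    for rec in records:
        image, mask = generate_scene(rec.params)
        img_path = img_dir / f"{rec.image_id}.{image_format}"
        iio.imwrite(img_path, image)
        iio.imwrite(mask_dir / f"{rec.image_id}.png", (mask * 255).astype(np.uint8))
        paths.append(img_path)
    phenotypes.to_csv(out / "phenotypes.csv", index=False)
    return paths
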