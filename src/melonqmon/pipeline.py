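"""End-to-end orchestration: simulate -> segment -> extract -> screen ->
train/simplify, with a machine-readable run manifest.

Every stage reads and writes plain files under the run's output directory, so
any stage can be re-run from its on-disk inputs alone. The manifest records
per-stage record counts, output hashes and seeds; deterministic stages
reproduce identical hashes on re-run.
"""

from __future__ import annotations

import hashlib
import json
import re
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import modeling, screening, segmentation, synthetic
from .features import GlcmConfig, extract_features, features_to_frame
from .tables import FEATURE_NAMES, TRAIT_ENVELOPES, TRAIT_NAMES

STAGES = ("simulate", "segment", "extract", "screen", "train")


@dataclass
class RunConfig:
    out_dir: str = "scratch/run"
    seed: int = 0
    n_fruits: int = 134
    views_per_fruit: int = 3
    image_size: tuple = (320, 320)
    noise_frac: float = synthetic.DEFAULT_NOISE_FRAC
    polarity: str = "backdrop_high"
    min_object_frac: float = 0.005
    min_hole_frac: float = 0.001
    opening_radius: int = 5
    white_balance: bool = False
    max_side: int | None = None  # downscale longest side before segmentation
    glcm_levels: int = 64
    glcm_distance: int = 1
    alpha: float = 0.05
    aggregation: str = "mean"
    ntree: int = 300
    mtry_grid: tuple | None = None
    cv_folds: int = 10
    cv_repeats: int = 3
    train_fraction: float = 2.0 / 3.0
    top_k: int = 10
    traits: tuple = TRAIT_NAMES
    stages: tuple = STAGES

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("image_size", "traits", "stages"):
            val = getattr(cfg, name)
            if isinstance(val, list):
                object.__setattr__(cfg, name, tuple(val))
        if cfg.mtry_grid is not None:
            cfg.mtry_grid = tuple(cfg.mtry_grid)
        return cfg

    def rf_config(self) -> modeling.RfConfig:
        return modeling.RfConfig(
            ntree=self.ntree,
            mtry_grid=self.mtry_grid,
            cv_folds=self.cv_folds,
            cv_repeats=self.cv_repeats,
            train_fraction=self.train_fraction,
            seed=self.seed,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def to_working_resolution(image: np.ndarray, max_side: int):
    """Downscale so the longest side is at most max_side; returns (image, scale)."""
    from skimage.transform import resize

    h, w = image.shape[:2]
    long_side = max(h, w)
    if long_side <= max_side:
        return image, 1.0
    scale = max_side / long_side
    out = resize(
        image,
        (round(h * scale), round(w * scale)),
        anti_aliasing=True,
        preserve_range=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8), scale


_IMAGE_ID_RE = re.compile(r"^(?P<fruit>.+)_v(?P<view>\d+)$")


def parse_image_id(stem: str):
    """Split ``<fruit>_v<view>`` stems; plain stems become a one-view fruit."""
    m = _IMAGE_ID_RE.match(stem)
    if m:
        return m.group("fruit"), int(m.group("view"))
    return stem, 0


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": _jsonable(asdict(config)), "stages": {}}

    def record(stage, count, paths):
        manifest["stages"][stage] = {
            "records": int(count),
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in paths},
            "timestamp": time.time(),
            "seed": config.seed,
        }

    for stage in config.stages:
        try:
            if stage == "simulate":
                spec = synthetic.CohortSpec(
                    n_fruits=config.n_fruits,
                    views_per_fruit=config.views_per_fruit,
                    image_size=tuple(config.image_size),
                    noise_frac=config.noise_frac,
                    seed=config.seed,
                )
                records, phenotypes = synthetic.generate_cohort(spec)
                paths = synthetic.write_cohort(records, phenotypes, out)
                record(stage, len(paths), [*paths, out / "phenotypes.csv"])
            elif stage == "segment":
                paths = _segment_stage(config, out)
                record(stage, len(paths) - 1, paths)
            elif stage == "extract":
                n = _extract_stage(config, out)
                record(stage, n, [out / "features.csv"])
            elif stage == "screen":
                n = _screen_stage(config, out)
                record(stage, n, [out / "screen.csv", out / "screening.png"])
            elif stage == "train":
                paths = _train_stage(config, out)
                record(stage, len(paths), paths)
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            if isinstance(exc, StageError):
                raise
            raise StageError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _segment_stage(config: RunConfig, out: Path):
    img_dir = out / "images"
    mask_dir = out / "masks_pred"
    mask_dir.mkdir(exist_ok=True)
    rows, paths = [], []
    for img_path in sorted(img_dir.glob("*.png")) + sorted(img_dir.glob("*.jpg")):
        image = iio.imread(img_path)[..., :3]
        scale = 1.0
        if config.max_side:
            image, scale = to_working_resolution(image, config.max_side)
        area = image.shape[0] * image.shape[1]
        cleaning = segmentation.CleaningParams(
            min_object_area=max(1, round(config.min_object_frac * area)),
            min_hole_area=max(1, round(config.min_hole_frac * area)),
            opening_radius=config.opening_radius,
        )
        mask, t = segmentation.segment(
            image,
            polarity=config.polarity,
            cleaning=cleaning,
            white_balance=config.white_balance,
        )
        mpath = mask_dir / f"{img_path.stem}.png"
        iio.imwrite(mpath, (mask * 255).astype(np.uint8))
        rows.append(
            {"image_id": img_path.stem, "threshold": float(t), "scale": scale}
        )
        paths.append(mpath)
    log_path = out / "segment_log.csv"
    pd.DataFrame(rows).to_csv(log_path, index=False)
    return [*paths, log_path]


def _extract_stage(config: RunConfig, out: Path) -> int:
    img_dir = out / "images"
    mask_dir = out / "masks_pred"
    seg_log = out / "segment_log.csv"
    thresholds = {}
    if seg_log.exists():
        tdf = pd.read_csv(seg_log)
        thresholds = dict(zip(tdf["image_id"], tdf["threshold"]))
    glcm = GlcmConfig(levels=config.glcm_levels, distance=config.glcm_distance)
    rows = []
    for img_path in sorted(img_dir.glob("*.png")) + sorted(img_dir.glob("*.jpg")):
        stem = img_path.stem
        image = iio.imread(img_path)[..., :3]
        if config.max_side:
            image, _ = to_working_resolution(image, config.max_side)
        mask = iio.imread(mask_dir / f"{stem}.png") > 0
        fv = extract_features(
            image, mask, glcm, image_id=stem, mask_threshold=thresholds.get(stem)
        )
        fruit_id, view = parse_image_id(stem)
        rows.append((stem, fruit_id, view, fv))
    if not rows:
        raise FileNotFoundError(f"no images found under {img_dir}")
    df = features_to_frame(rows)
    df.to_csv(out / "features.csv", index=False)
    return len(df)


def _screen_stage(config: RunConfig, out: Path) -> int:
    features = pd.read_csv(out / "features.csv")
    phenotypes = pd.read_csv(out / "phenotypes.csv")
    fruit_level = screening.aggregate_views(features, how=config.aggregation)
    result = screening.pearson_screen(fruit_level, phenotypes, alpha=config.alpha)
    result.to_csv(out / "screen.csv", index=False)
    screening.screening_plot(result, out / "screening.png", alpha=config.alpha)
    return len(result)


def _train_stage(config: RunConfig, out: Path):
    features = pd.read_csv(out / "features.csv")
    phenotypes = pd.read_csv(out / "phenotypes.csv")
    screen = pd.read_csv(out / "screen.csv")
    fruit_level = screening.aggregate_views(features, how=config.aggregation)
    merged = fruit_level.merge(phenotypes, on="fruit_id", how="inner")
    rf = config.rf_config()
    model_dir = out / "models"
    model_dir.mkdir(exist_ok=True)
    paths = []
    for trait in config.traits:
        feats = screening.selected_features(screen, trait)
        if not feats:
            continue
        X = merged[feats]
        y = merged[trait].to_numpy(dtype=float)
        forest, full_report = modeling.tune_fit(X, y, rf, trait=trait)
        Xval = X.to_numpy(dtype=float)[forest.validation_index_]
        yval = y[forest.validation_index_]
        ranking = modeling.importance(
            forest, pd.DataFrame(Xval, columns=feats), yval, seed=config.seed,
            repeats=rf.importance_repeats,
        )
        comparison = modeling.simplify(
            X, y, ranking, k=config.top_k, config=rf, trait=trait,
            full_report=full_report,
        )
        payload = {
            "trait": trait,
            "screened_features": feats,
            "full": full_report.to_dict(),
            "simplified": comparison.simplified.to_dict(),
            "retained_features": comparison.retained_features,
            "r2_decrease_pct": comparison.r2_decrease_pct,
            "importance": ranking.to_dict(orient="records"),
        }
        jpath = model_dir / f"{trait}.json"
        with open(jpath, "w") as fh:
            json.dump(_jsonable(payload), fh, indent=2)
        ppath = model_dir / f"{trait}_predictions.csv"
        full_report.predictions.to_csv(ppath, index=False)
        paths.extend([jpath, ppath])
    return paths


def validate_io(features_csv, phenotypes_csv) -> dict:
    """Schema and consistency checks on the two table files.

    Returns ``{"violations": [...], "warnings": [...]}``; violations are
    schema breaks, warnings are plausibility flags (e.g. a trait outside its
    observed envelope).
    """
    violations, warnings = [], []
    features = pd.read_csv(features_csv)
    phenotypes = pd.read_csv(phenotypes_csv)

    expected = ["image_id", "fruit_id", "view", *FEATURE_NAMES]
    missing = [c for c in expected if c not in features.columns]
    if missing:
        violations.append(f"feature table missing columns: {missing}")
    extra = [c for c in features.columns if c not in expected]
    if extra:
        warnings.append(f"feature table has extra columns: {extra}")
    present = [c for c in expected if c in features.columns]
    if list(features.columns[: len(present)]) != present and not missing:
        violations.append("feature columns out of canonical order")
    if "image_id" in features.columns and features["image_id"].duplicated().any():
        dups = features.loc[features["image_id"].duplicated(), "image_id"].tolist()
        violations.append(f"duplicate image ids: {dups}")
    feat_cols = [c for c in FEATURE_NAMES if c in features.columns]
    if feat_cols and features[feat_cols].isna().any().any():
        bad = features[feat_cols].columns[features[feat_cols].isna().any()].tolist()
        violations.append(f"missing feature values in columns: {bad}")

    if "fruit_id" not in phenotypes.columns:
        violations.append("phenotype table missing fruit_id column")
    else:
        if phenotypes["fruit_id"].duplicated().any():
            violations.append("duplicate fruit ids in phenotype table")
        if "fruit_id" in features.columns:
            unmatched = set(features["fruit_id"]) - set(phenotypes["fruit_id"])
            if unmatched:
                warnings.append(
                    f"{len(unmatched)} fruit ids in features lack phenotypes"
                )
    unknown_traits = [
        c for c in phenotypes.columns if c not in ("fruit_id", *TRAIT_NAMES)
    ]
    if unknown_traits:
        violations.append(f"unknown phenotype columns: {unknown_traits}")
    for trait in TRAIT_NAMES:
        if trait not in phenotypes.columns:
            continue
        lo, hi = TRAIT_ENVELOPES[trait]
        vals = phenotypes[trait].dropna()
        if ((vals < lo) | (vals > hi)).any():
            warnings.append(
                f"{trait} values outside the observed envelope [{lo}, {hi}]"
            )
    return {"violations": violations, "warnings": warnings}
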