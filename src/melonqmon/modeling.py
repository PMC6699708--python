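"""Random-forest regression of internal traits on screened features.

Per trait: a 2/3-1/3 seeded train/validation split, mtry tuned by repeated
10-fold cross-validated RMSE on the training rows at ntree=300, held-out
metrics (both the explained-SS R-squared form and the
conventional 1 - SSres/SStot), permutation importance by MSE increase, and a
top-10 simplified model compared against the full one.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import RepeatedKFold

from .tables import FEATURE_CATEGORY, FEATURE_NUMBER, feature_category_counts


@dataclass(frozen=True)
class RfConfig:
    ntree: int = 300
    mtry_grid: tuple | None = None  # None -> 1..min(100, p)
    cv_folds: int = 10
    cv_repeats: int = 3
    train_fraction: float = 2.0 / 3.0
    seed: int = 0
    importance_repeats: int = 5

    def grid_for(self, p: int) -> tuple:
        if self.mtry_grid is not None:
            grid = tuple(int(m) for m in self.mtry_grid if 1 <= m <= p)
            if not grid:
                raise ValueError("mtry grid has no value in 1..p")
            return grid
        return tuple(range(1, min(100, p) + 1))


@dataclass
class CvReport:
    trait: str
    chosen_mtry: int
    rmse: float
    mae: float
    r2_explained: float
    r2_conventional: float
    cv_results: pd.DataFrame
    predictions: pd.DataFrame
    n_train: int
    n_validation: int
    train_seconds: float

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "chosen_mtry": int(self.chosen_mtry),
            "rmse": self.rmse,
            "mae": self.mae,
            "r2_explained": self.r2_explained,
            "r2_conventional": self.r2_conventional,
            "n_train": self.n_train,
            "n_validation": self.n_validation,
            "train_seconds": self.train_seconds,
            "cv_results": self.cv_results.to_dict(orient="records"),
        }


@dataclass
class SimplifiedComparison:
    full: CvReport
    simplified: CvReport
    retained_features: list
    r2_decrease_pct: float


def metrics(y: np.ndarray, yhat: np.ndarray) -> dict:
    """Validation metrics, including the explained-SS form of R-squared
    (which can exceed 1 for non-least-squares predictors) and the
    conventional 1 - SSres/SStot."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("y and yhat must be equal-length with n >= 2")
    ybar = y.mean()
    ss_tot = float(((y - ybar) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("constant y: R-squared undefined")
    ss_exp = float(((yhat - ybar) ** 2).sum())
    ss_res = float(((y - yhat) ** 2).sum())
    return {
        "r2_explained": ss_exp / ss_tot,
        "r2_conventional": 1.0 - ss_res / ss_tot,
        "rmse": float(np.sqrt(ss_res / y.size)),
        "mae": float(np.abs(y - yhat).mean()),
    }


def split_train_validation(
    n: int,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    groups=None,
):
    """Seeded train/validation index split; group-aware when groups given
    (all rows of one group land on the same side)."""
    rng = np.random.default_rng(seed)
    if groups is None:
        idx = rng.permutation(n)
        n_train = int(round(train_fraction * n))
        return np.sort(idx[:n_train]), np.sort(idx[n_train:])
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    perm = rng.permutation(len(uniq))
    n_train_g = int(round(train_fraction * len(uniq)))
    train_groups = set(uniq[perm[:n_train_g]])
    is_train = np.array([g in train_groups for g in groups])
    return np.flatnonzero(is_train), np.flatnonzero(~is_train)


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def _cv_rmse(Xtr, ytr, mtry, config: RfConfig) -> float:
    cv = RepeatedKFold(
        n_splits=config.cv_folds, n_repeats=config.cv_repeats, random_state=config.seed
    )
    errs = []
    for tr, te in cv.split(Xtr):
        forest = RandomForestRegressor(
            n_estimators=config.ntree, max_features=mtry, random_state=config.seed
        )
        forest.fit(Xtr[tr], ytr[tr])
        pred = forest.predict(Xtr[te])
        errs.append(np.sqrt(np.mean((ytr[te] - pred) ** 2)))
    return float(np.mean(errs))


def tune_fit(X, y, config: RfConfig, trait: str = "", groups=None):
    """Tune mtry by repeated k-fold CV RMSE on the training split, refit at
    the winner, and report held-out metrics on the validation split.

    Returns ``(fitted forest, CvReport)``. Ties in CV RMSE go to the smaller
    mtry. Identical data + config + seed give identical output.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n < 20:
        raise ValueError("need at least 20 samples")
    if not (np.isfinite(Xm).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in X or y")
    if n * min(config.train_fraction, 1 - config.train_fraction) < config.cv_folds / 2:
        raise ValueError("too few samples for the configured folds")

    t0 = time.perf_counter()
    tr_idx, val_idx = split_train_validation(
        n, config.train_fraction, config.seed, groups=groups
    )
    Xtr, ytr = Xm[tr_idx], y[tr_idx]
    Xval, yval = Xm[val_idx], y[val_idx]

    grid = config.grid_for(p)
    cv_rows = [{"mtry": m, "cv_rmse": _cv_rmse(Xtr, ytr, m, config)} for m in grid]
    cv_results = pd.DataFrame(cv_rows)
    best = cv_results.sort_values(["cv_rmse", "mtry"]).iloc[0]
    chosen = int(best["mtry"])

    forest = RandomForestRegressor(
        n_estimators=config.ntree, max_features=chosen, random_state=config.seed
    )
    forest.fit(Xtr, ytr)
    yhat = forest.predict(Xval)
    m = metrics(yval, yhat)
    preds = pd.DataFrame(
        {"row": val_idx, "y": yval, "yhat": yhat, "split": "validation"}
    )
    report = CvReport(
        trait=trait,
        chosen_mtry=chosen,
        rmse=m["rmse"],
        mae=m["mae"],
        r2_explained=m["r2_explained"],
        r2_conventional=m["r2_conventional"],
        cv_results=cv_results,
        predictions=preds,
        n_train=len(tr_idx),
        n_validation=len(val_idx),
        train_seconds=time.perf_counter() - t0,
    )
    forest.feature_names_ = names
    forest.train_index_ = tr_idx
    forest.validation_index_ = val_idx
    return forest, report


def _feature_order_key(name: str, position: int) -> int:
    return FEATURE_NUMBER.get(name, 10_000 + position)


def importance(forest, X, y, seed: int = 0, repeats: int = 5) -> pd.DataFrame:
    """Permutation importance: per-tree MSE increase when one column is
    shuffled, averaged over trees and seeded repetitions (the per-tree
    averaging matters: it keeps importance additive across duplicated
    predictors). Ranks descend by score, ties broken by canonical feature
    number."""
    if not hasattr(forest, "estimators_"):
        raise ValueError("forest is not fitted")
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    trees = forest.estimators_

    def mean_tree_mse(Xeval):
        preds = np.stack([t.predict(Xeval) for t in trees])
        return float(np.mean((preds - y) ** 2))

    base_mse = mean_tree_mse(Xm)
    scores = np.zeros(Xm.shape[1])
    for j in range(Xm.shape[1]):
        incr = []
        for _ in range(repeats):
            Xp = Xm.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            incr.append(mean_tree_mse(Xp) - base_mse)
        scores[j] = np.mean(incr)
    df = pd.DataFrame({"feature": names, "importance": scores})
    df["order_key"] = [_feature_order_key(nm, i) for i, nm in enumerate(names)]
    df = df.sort_values(["importance", "order_key"], ascending=[False, True])
    df["rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns="order_key").reset_index(drop=True)


def simplify(
    X,
    y,
    ranking: pd.DataFrame,
    k: int = 10,
    config: RfConfig = RfConfig(),
    trait: str = "",
    groups=None,
    full_report: CvReport | None = None,
) -> SimplifiedComparison:
    """Retain the top-k ranked features, re-tune on the reduced matrix with
    the mtry grid capped at k, and compare against the full model."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not isinstance(X, pd.DataFrame):
        Xm, names = _as_matrix(X)
        X = pd.DataFrame(Xm, columns=names)
    if full_report is None:
        _, full_report = tune_fit(X, y, config, trait=trait, groups=groups)
    top = set(ranking.sort_values("rank")["feature"].tolist()[: min(k, X.shape[1])])
    # canonical column order, so k = p reproduces the full design matrix
    keep = [c for c in X.columns if c in top]
    grid = config.grid_for(X.shape[1])
    simp_grid = tuple(m for m in grid if m <= len(keep)) or (len(keep),)
    simp_config = replace(config, mtry_grid=simp_grid)
    _, simp_report = tune_fit(X[keep], y, simp_config, trait=trait, groups=groups)
    if full_report.r2_conventional != 0:
        dec = (
            (full_report.r2_conventional - simp_report.r2_conventional)
            / abs(full_report.r2_conventional)
            * 100.0
        )
    else:
        dec = float("nan")
    return SimplifiedComparison(
        full=full_report,
        simplified=simp_report,
        retained_features=keep,
        r2_decrease_pct=float(dec),
    )


def summarize_importance_categories(rankings: dict, k: int = 10) -> pd.DataFrame:
    """Per-trait counts of color/texture/morphology among the top-k features.

    Features not in the canonical vocabulary are ignored; counts sum to the
    number of canonical features retained (k when all are canonical).
    """
    rows = []
    for trait, ranking in rankings.items():
        top = ranking.sort_values("rank")["feature"].tolist()[:k]
        counts = feature_category_counts([f for f in top if f in FEATURE_CATEGORY])
        rows.append({"trait": trait, **counts})
    return pd.DataFrame(rows, columns=["trait", "color", "texture", "morphology"])
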