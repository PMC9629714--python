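"""Presence/pseudo-absence driver modelling with boosted regression trees.

Where does AIS disabling happen, relative to where fishing happens?  The
question is cast as a presence/background classification on the
quarter-degree grid: presences are cells with at least one suspected
disabling event, absences are sampled uniformly (1:1) from cells with
fishing activity and no disabling.  A gradient-boosted tree ensemble
(binomial deviance; tree depth 3, learning rate 0.01, bag fraction 0.5, the
standard ecological-BRT settings) relates the label to eight driver rasters:
distance to shore, distance to marine protected areas, transshipment-vessel
loitering, distance to reported piracy, chlorophyll-a, eddy kinetic energy,
sea-surface temperature and its temporal variability.  Distance drivers are
clipped at 400 km so only proximal effects enter.

Outputs follow the ecological BRT toolkit: per-driver relative importance
(normalised split-gain, summing to 100%), partial-dependence curves, and an
evaluation protocol of 50 iterations of stratified 75/25 splits with the
absence set redrawn each iteration, scored by AUC and the true skill
statistic (TSS = sensitivity + specificity - 1 at the TSS-maximising
threshold), plus training explained deviance of the final model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .geo import haversine_km
from .grid import GridSpec, Raster
from .synthetic import DISTANCE_CLIP_KM, DISTANCE_DRIVERS, DRIVER_NAMES


class DriverModelError(ValueError):
    pass


@dataclass
class DriverStack:
    """The eight driver rasters on one shared grid; distance layers are
    clipped at 400 km on construction."""
    rasters: dict[str, Raster]

    def __post_init__(self) -> None:
        missing = set(DRIVER_NAMES) - set(self.rasters)
        if missing:
            raise DriverModelError(f"driver stack missing layers: {sorted(missing)}")
        specs = {r.spec for r in self.rasters.values()}
        if len(specs) != 1:
            raise DriverModelError("driver rasters do not share one grid geometry")
        for name in DISTANCE_DRIVERS:
            r = self.rasters[name]
            self.rasters[name] = r.copy_with(
                np.minimum(r.values, DISTANCE_CLIP_KM))

    @property
    def spec(self) -> GridSpec:
        return next(iter(self.rasters.values())).spec

    @classmethod
    def from_world(cls, world) -> "DriverStack":
        return cls({name: world.drivers[name] for name in DRIVER_NAMES})


@dataclass(frozen=True)
class BRTHyper:
    tree_complexity: int = 3       # max tree depth
    learning_rate: float = 0.01
    bag_fraction: float = 0.5
    max_trees: int = 2000          # ceiling for the internal-CV choice
    n_trees: int | None = None     # fixed size; skips the internal CV
    cv_folds: int = 5
    cv_step: int = 25              # evaluate the staged CV deviance every so many trees


@dataclass
class BRTFit:
    model: GradientBoostingClassifier
    hyper: BRTHyper
    n_trees: int
    feature_names: list[str]
    relative_importance: pd.Series      # %, sums to 100
    partial_dependence: pd.DataFrame    # columns: driver, x, response
    explained_deviance: float           # training, 1 - residual/null


@dataclass
class EvalReport:
    auc_mean: float
    auc_sd: float
    tss_mean: float
    tss_sd: float
    explained_deviance: float
    n_iter: int


def distance_raster(sources: np.ndarray, grid: GridSpec,
                    clip_km: float = DISTANCE_CLIP_KM) -> Raster:
    """Great-circle distance (km) from each cell center to the nearest
    source point, clipped at ``clip_km``."""
    sources = np.atleast_2d(np.asarray(sources, dtype=float))
    if sources.size == 0:
        raise DriverModelError("empty source set for distance raster")
    lon, lat = grid.center_mesh()
    best = np.full(grid.shape, np.inf)
    for slon, slat in sources:
        np.minimum(best, haversine_km(lon, lat, slon, slat), out=best)
    return Raster(grid, np.minimum(best, clip_km), layer="distance", units="km")


def build_dataset(disabling: Raster, fishing: Raster, drivers: DriverStack,
                  gear: str | None = None, seed: int = 0) -> pd.DataFrame:
    """Presence/pseudo-absence table at exact 1:1 balance.

    Presences: cells with >= 1 suspected disabling event.  Eligible
    absences: cells with fishing activity and no disabling.  Cells with any
    missing driver are dropped (count logged as a warning) before sampling;
    the absence draw is uniform without replacement, reproducible from seed.
    """
    if disabling.spec != fishing.spec or disabling.spec != drivers.spec:
        raise DriverModelError("disabling/fishing/driver grids do not match")
    dis = np.nan_to_num(disabling.values, nan=0.0)
    fish = np.nan_to_num(fishing.values, nan=0.0)
    drv = {n: drivers.rasters[n].values for n in DRIVER_NAMES}
    valid = np.ones(disabling.spec.shape, dtype=bool)
    for v in drv.values():
        valid &= np.isfinite(v)
    n_dropped = int((~valid).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} cells with missing driver values",
                      RuntimeWarning, stacklevel=2)
    pres_mask = (dis > 0) & valid
    abs_mask = (fish > 0) & (dis == 0) & valid
    n_pres = int(pres_mask.sum())
    if n_pres == 0:
        raise DriverModelError("zero presence cells: no model possible")
    abs_rows, abs_cols = np.nonzero(abs_mask)
    if len(abs_rows) < n_pres:
        raise DriverModelError(
            f"only {len(abs_rows)} eligible absence cells for {n_pres} "
            "presences; use a larger fixture or relax eligibility")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(abs_rows), size=n_pres, replace=False)

    def _rows(mask_rows, mask_cols, label):
        rec = {"row": mask_rows, "col": mask_cols, "label": label}
        for n in DRIVER_NAMES:
            rec[n] = drv[n][mask_rows, mask_cols]
        return pd.DataFrame(rec)

    pres_rows, pres_cols = np.nonzero(pres_mask)
    table = pd.concat([_rows(pres_rows, pres_cols, "presence"),
                       _rows(abs_rows[pick], abs_cols[pick], "absence")],
                      ignore_index=True)
    table["gear"] = gear if gear is not None else "all"
    table.attrs["seed"] = seed
    return table


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _make_gbm(hyper: BRTHyper, n_trees: int, seed: int
              ) -> GradientBoostingClassifier:
    return GradientBoostingClassifier(
        loss="log_loss", n_estimators=n_trees,
        learning_rate=hyper.learning_rate, max_depth=hyper.tree_complexity,
        subsample=hyper.bag_fraction, random_state=seed)


def _choose_n_trees(X: np.ndarray, y: np.ndarray, hyper: BRTHyper,
                    seed: int) -> int:
    """Internal k-fold CV over the staged deviance curve, up to the ceiling."""
    if hyper.n_trees is not None:
        return hyper.n_trees
    skf = StratifiedKFold(n_splits=hyper.cv_folds, shuffle=True,
                          random_state=seed)
    stages = np.arange(hyper.cv_step, hyper.max_trees + 1, hyper.cv_step)
    dev = np.zeros(len(stages))
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        gbm = _make_gbm(hyper, hyper.max_trees, seed + fold)
        gbm.fit(X[tr], y[tr])
        staged = gbm.staged_predict_proba(X[te])
        for i, proba in enumerate(staged):
            j = (i + 1) // hyper.cv_step - 1
            if (i + 1) % hyper.cv_step == 0:
                dev[j] += _binomial_deviance(y[te], proba[:, 1])
    return int(stages[int(np.argmin(dev))])


def fit_brt(table: pd.DataFrame, hyper: BRTHyper = BRTHyper(),
            seed: int = 0, pdp_points: int = 100) -> BRTFit:
    """Fit the boosted ensemble; importance is normalised split-gain per
    driver (summing to 100%), partial dependence is evaluated on a
    ``pdp_points``-point grid spanning each driver's observed range.
    Constant drivers are retained (zero importance) with a warning.
    """
    counts = table["label"].value_counts().reindex(["presence", "absence"],
                                                   fill_value=0)
    if counts.min() < 20:
        raise DriverModelError("need >= 20 rows per class to fit")
    X = table[list(DRIVER_NAMES)].to_numpy(dtype=float)
    y = (table["label"] == "presence").to_numpy(dtype=int)
    for j, name in enumerate(DRIVER_NAMES):
        if np.ptp(X[:, j]) == 0:
            warnings.warn(f"driver {name!r} is constant; it will carry zero "
                          "importance", RuntimeWarning, stacklevel=2)
    n_trees = _choose_n_trees(X, y, hyper, seed)
    gbm = _make_gbm(hyper, n_trees, seed)
    gbm.fit(X, y)

    raw = gbm.feature_importances_
    total = raw.sum()
    imp = pd.Series(100.0 * raw / total if total > 0 else raw,
                    index=list(DRIVER_NAMES), name="relative_importance_pct")

    pdp_frames = []
    for j, name in enumerate(DRIVER_NAMES):
        lo, hi = X[:, j].min(), X[:, j].max()
        xs = np.linspace(lo, hi, pdp_points)
        resp = np.empty(pdp_points)
        base = X.copy()
        for i, xv in enumerate(xs):
            base[:, j] = xv
            resp[i] = gbm.decision_function(base).mean()
        pdp_frames.append(pd.DataFrame({"driver": name, "x": xs,
                                        "response": resp}))
    pdp = pd.concat(pdp_frames, ignore_index=True)

    p_hat = gbm.predict_proba(X)[:, 1]
    null_dev = _binomial_deviance(y, np.full_like(p_hat, y.mean()))
    resid_dev = _binomial_deviance(y, p_hat)
    expl = 1.0 - resid_dev / null_dev if null_dev > 0 else np.nan

    return BRTFit(model=gbm, hyper=hyper, n_trees=n_trees,
                  feature_names=list(DRIVER_NAMES), relative_importance=imp,
                  partial_dependence=pdp, explained_deviance=expl)


def _tss(y_true: np.ndarray, score: np.ndarray) -> float:
    """TSS at the threshold maximising sensitivity + specificity - 1."""
    fpr, tpr, _ = roc_curve(y_true, score)
    return float(np.max(tpr - fpr))


def evaluate_brt(table_factory: Callable[[int], pd.DataFrame],
                 hyper: BRTHyper = BRTHyper(), n_iter: int = 50,
                 train_frac: float = 0.75, seed: int = 0) -> EvalReport:
    """Held-out AUC/TSS over ``n_iter`` iterations of stratified
    train/test splits.

    ``table_factory(seed)`` must return a presence/absence table; passing a
    factory bound to build_dataset makes each iteration redraw the absence
    set (1:1 ratio maintained) before splitting 75/25.  Explained deviance
    is the training value of a final fit on ``table_factory(seed)``.
    A degenerate (single-class) test split is redrawn, erroring after 10
    failures.
    """
    rng = np.random.default_rng(seed)
    aucs, tsss = [], []
    for it in range(n_iter):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        table = table_factory(sub_seed)
        X = table[list(DRIVER_NAMES)].to_numpy(dtype=float)
        y = (table["label"] == "presence").to_numpy(dtype=int)
        for attempt in range(10):
            Xtr, Xte, ytr, yte = train_test_split(
                X, y, train_size=train_frac, stratify=y,
                random_state=sub_seed % (2**31) + attempt)
            if 0 < yte.sum() < len(yte):
                break
        else:
            raise DriverModelError("could not draw a two-class test split")
        n_trees = hyper.n_trees or min(hyper.max_trees, 500)
        gbm = _make_gbm(BRTHyper(hyper.tree_complexity, hyper.learning_rate,
                                 hyper.bag_fraction, n_trees=n_trees),
                        n_trees, sub_seed)
        gbm.fit(Xtr, ytr)
        score = gbm.decision_function(Xte)
        aucs.append(roc_auc_score(yte, score))
        tsss.append(_tss(yte, score))
    final = fit_brt(table_factory(seed), hyper=hyper, seed=seed)
    return EvalReport(auc_mean=float(np.mean(aucs)),
                      auc_sd=float(np.std(aucs, ddof=1)) if n_iter > 1 else 0.0,
                      tss_mean=float(np.mean(tsss)),
                      tss_sd=float(np.std(tsss, ddof=1)) if n_iter > 1 else 0.0,
                      explained_deviance=final.explained_deviance,
                      n_iter=n_iter)
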