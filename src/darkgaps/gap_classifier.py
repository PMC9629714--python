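"""Gap detection, filtering and rule-based classification of suspected
intentional AIS disabling.

A gap event is the interval between consecutive AIS messages of one vessel
spanning at least 12 hours.  Gaps are filtered to open water with good
satellite coverage — start position more than 50 nautical miles from shore
and predicted reception above 10 positions/day — so that the remaining gaps
cannot plausibly be explained by poor reception.  A retained gap is then
classified as suspected intentional disabling when the vessel was
broadcasting at a healthy rate immediately before going dark: at least ``k``
positions in the lookback window ending at the gap start (the window is
half-open, ``(start - L, start]``, so the boundary ping itself counts).

Rule models are selected by F0.5 — precision weighted over recall — under
repeated stratified k-fold cross-validation against ground-truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold

from .geo import km_to_nmi
from .grid import Raster
from .reception import ReceptionGrid

DEFAULT_LOOKBACKS_H = (6, 12, 18, 24)

SUSPECTED = "suspected_disabling"
NOT_SUSPECTED = "not_suspected"
EXCLUDED = "excluded"
RETAINED = "retained"  # interim marker between filter_gaps and classify


class GapError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class RuleModel:
    """Threshold rule: suspect a retained gap when the lookback window holds
    at least ``k`` positions and predicted reception exceeds ``reception_min``."""
    lookback_h: int = 12
    k: int = 14
    reception_min: float = 10.0

    def __post_init__(self) -> None:
        if self.k < 1 or self.lookback_h <= 0:
            raise GapError("RuleModel requires k >= 1 and lookback_h > 0")


@dataclass
class ClassifierEval:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) > 0 else None

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else None

    @property
    def fpr(self) -> float | None:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) > 0 else None

    @property
    def f_beta(self) -> float:
        return f_beta(self.tp, self.fp, self.fn)


def detect_gaps(messages: pd.DataFrame, min_gap_h: float = 12.0,
                lookback_hours: Sequence[int] = DEFAULT_LOOKBACKS_H
                ) -> pd.DataFrame:
    """Detect per-vessel transmission gaps of at least ``min_gap_h`` hours.

    One row per consecutive message pair with spacing >= ``min_gap_h``;
    ``pings_{L}h`` columns count positions in the half-open window
    ``(start - L, start]`` for every configured lookback.  Vessels with
    fewer than two messages yield no gaps.  Rows are ordered by vessel then
    start time.
    """
    cols = (["vessel_id", "start_time", "end_time", "duration_h",
             "start_lon", "start_lat", "end_lon", "end_lat",
             "device_class", "gear", "flag"]
            + [f"pings_{L}h" for L in lookback_hours])
    if len(messages) == 0:
        return pd.DataFrame(columns=cols)
    frames = []
    for vessel, sub in messages.groupby("vessel_id", sort=True):
        sub = sub.sort_values("timestamp", kind="stable")
        if len(sub) < 2:
            continue
        t = pd.DatetimeIndex(sub["timestamp"])      # tz-aware, for storage
        t64 = t.tz_convert("UTC").tz_localize(None).to_numpy()
        th = (t64 - t64[0]) / np.timedelta64(1, "s") / 3600.0  # hours, monotone
        dt = np.diff(th)
        idx = np.flatnonzero(dt >= min_gap_h - 1e-12)
        if idx.size == 0:
            continue
        row = {
            "vessel_id": vessel,
            "start_time": t[idx], "end_time": t[idx + 1],
            "duration_h": dt[idx],
            "start_lon": sub["lon"].to_numpy()[idx],
            "start_lat": sub["lat"].to_numpy()[idx],
            "end_lon": sub["lon"].to_numpy()[idx + 1],
            "end_lat": sub["lat"].to_numpy()[idx + 1],
            "device_class": sub["device_class"].to_numpy()[idx],
            "gear": sub["gear"].to_numpy()[idx],
            "flag": sub["flag"].to_numpy()[idx],
        }
        for L in lookback_hours:
            # pings in (start - L, start]: indices (first_in, gap_index]
            first_in = np.searchsorted(th, th[idx] - L, side="right")
            row[f"pings_{L}h"] = (idx + 1) - first_in
        frames.append(pd.DataFrame(row))
    if not frames:
        return pd.DataFrame(columns=cols)
    gaps = pd.concat(frames, ignore_index=True)
    return gaps.sort_values(["vessel_id", "start_time"], ignore_index=True)


def filter_gaps(gaps: pd.DataFrame, shore: Raster,
                reception: dict[str, ReceptionGrid] | ReceptionGrid,
                min_shore_nmi: float = 50.0,
                min_reception: float = 10.0,
                min_gap_h: float = 12.0) -> pd.DataFrame:
    """Apply the open-water filters; sets ``dist_shore_nmi``,
    ``reception_pred`` and ``classification`` on a copy of ``gaps``.

    A gap is retained iff dist_shore_nmi > min_shore_nmi (strict) AND
    reception_pred > min_reception (strict) AND duration_h >= min_gap_h;
    everything else is marked excluded.  Covariates are evaluated at the gap
    start position and stored regardless of outcome.
    """
    gaps = gaps.copy()
    if len(gaps) == 0:
        gaps["dist_shore_nmi"] = pd.Series(dtype=float)
        gaps["reception_pred"] = pd.Series(dtype=float)
        gaps["classification"] = pd.Series(dtype=object)
        return gaps
    lon = gaps["start_lon"].to_numpy()
    lat = gaps["start_lat"].to_numpy()
    inside = shore.spec.contains(lon, lat)
    if not inside.all():
        i = int(np.flatnonzero(~inside)[0])
        raise GapError(
            "gap start position outside raster extent for vessel "
            f"{gaps['vessel_id'].iat[i]} at {gaps['start_time'].iat[i]}")
    gaps["dist_shore_nmi"] = km_to_nmi(shore.value_at(lon, lat))
    if isinstance(reception, ReceptionGrid):
        reception = {dc: reception for dc in gaps["device_class"].unique()}
    pred = np.full(len(gaps), np.nan)
    for dev, grid in reception.items():
        m = (gaps["device_class"] == dev).to_numpy()
        if m.any():
            pred[m] = grid.raster.value_at(lon[m], lat[m])
    gaps["reception_pred"] = pred
    retained = ((gaps["dist_shore_nmi"] > min_shore_nmi)
                & (gaps["reception_pred"] > min_reception)
                & (gaps["duration_h"] >= min_gap_h - 1e-12))
    gaps["classification"] = np.where(retained, RETAINED, EXCLUDED)
    return gaps


def classify(gaps: pd.DataFrame, model: RuleModel) -> pd.DataFrame:
    """Classify retained gaps with a rule model (deterministic)."""
    col = f"pings_{model.lookback_h}h"
    if col not in gaps.columns:
        raise GapError(f"gaps table lacks lookback column {col!r}; "
                       "re-run detect_gaps with this lookback")
    gaps = gaps.copy()
    retained = gaps["classification"] != EXCLUDED
    hit = ((gaps[col] >= model.k)
           & (gaps["reception_pred"] > model.reception_min))
    gaps.loc[retained, "classification"] = np.where(
        hit[retained], SUSPECTED, NOT_SUSPECTED)
    return gaps


def f_beta(tp: int, fp: int, fn: int, beta: float = 0.5) -> float:
    """F-beta from confusion counts; 0 when tp == 0, error when all are 0."""
    if min(tp, fp, fn) < 0:
        raise GapError("confusion counts must be >= 0")
    if tp + fp + fn == 0:
        raise GapError("f_beta undefined: tp + fp + fn == 0")
    if tp == 0:
        return 0.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    b2 = beta * beta
    return (1 + b2) * p * r / (b2 * p + r)


def label_gaps(gaps: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Attach ground-truth causes: a gap is ``intentional`` iff a logged
    intentional interval of the same vessel is nested inside it (1 s
    tolerance); otherwise its cause is ``reception``."""
    gaps = gaps.copy()
    tol = pd.Timedelta(seconds=1)
    label = np.full(len(gaps), "reception", dtype=object)
    tr = truth[truth["cause"] == "intentional"]
    by_vessel = dict(tuple(tr.groupby("vessel_id"))) if len(tr) else {}
    for i, row in enumerate(gaps.itertuples(index=False)):
        sub = by_vessel.get(row.vessel_id)
        if sub is None:
            continue
        nested = ((sub["start"] >= row.start_time - tol)
                  & (sub["end"] <= row.end_time + tol))
        if nested.any():
            label[i] = "intentional"
    gaps["truth"] = label
    return gaps


def evaluate(gaps: pd.DataFrame, model: RuleModel | None = None
             ) -> ClassifierEval:
    """Confusion counts of suspected-vs-truth over retained gaps only.

    If ``model`` is given the gaps are (re)classified with it first.
    """
    if "truth" not in gaps.columns:
        raise GapError("gaps table lacks truth labels; call label_gaps first")
    if model is not None:
        gaps = classify(gaps, model)
    sub = gaps[gaps["classification"] != EXCLUDED]
    pos = sub["classification"] == SUSPECTED
    true = sub["truth"] == "intentional"
    return ClassifierEval(tp=int((pos & true).sum()),
                          fp=int((pos & ~true).sum()),
                          fn=int((~pos & true).sum()),
                          tn=int((~pos & ~true).sum()))


def default_candidate_grid(lookbacks: Iterable[int] = DEFAULT_LOOKBACKS_H,
                           ks: Iterable[int] = range(2, 31),
                           reception_mins: Iterable[float] = (10.0, 15.0, 20.0)
                           ) -> list[RuleModel]:
    return [RuleModel(L, k, r)
            for L in lookbacks for k in ks for r in reception_mins]


def select_model(gaps: pd.DataFrame, candidates: Sequence[RuleModel],
                 k_folds: int = 5, n_repeats: int = 10, seed: int = 0
                 ) -> tuple[RuleModel, pd.DataFrame, ClassifierEval]:
    """Pick the rule model maximising mean held-out F0.5 under repeated
    stratified k-fold cross-validation.

    Ties break toward higher full-data precision, then smaller ``k``, then
    shorter lookback.  Returns the winner, the per-candidate score table
    (mean and sd of F0.5 over folds) and the winner's evaluation over all
    retained gaps (the rule has no trained state, so pooled held-out-fold
    counts coincide with full-data counts).
    """
    if not candidates:
        raise GapError("candidate grid is empty")
    if "truth" not in gaps.columns:
        raise GapError("model selection requires truth labels")
    sub = gaps[gaps["classification"] != EXCLUDED].reset_index(drop=True)
    y = (sub["truth"] == "intentional").to_numpy()
    if y.sum() == 0 or (~y).sum() == 0:
        raise GapError("stratification impossible: need both truth classes "
                       "among retained gaps")
    n_splits = min(k_folds, int(y.sum()), int((~y).sum()))
    if n_splits < 2:
        raise GapError("too few gaps of one truth class for k-fold CV")

    recep = sub["reception_pred"].to_numpy()
    preds = np.empty((len(candidates), len(sub)), dtype=bool)
    for ci, c in enumerate(candidates):
        col = f"pings_{c.lookback_h}h"
        if col not in sub.columns:
            raise GapError(f"gaps table lacks lookback column {col!r}")
        preds[ci] = (sub[col].to_numpy() >= c.k) & (recep > c.reception_min)

    rskf = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=n_repeats,
                                   random_state=seed)
    scores = []
    for _, test_idx in rskf.split(np.zeros(len(y)), y):
        yt = y[test_idx]
        pt = preds[:, test_idx]
        tp = (pt & yt).sum(axis=1)
        fp = (pt & ~yt).sum(axis=1)
        fn = (~pt & yt).sum(axis=1)
        b2 = 0.25
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
            r = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
            f = np.where(tp > 0, (1 + b2) * p * r / np.maximum(b2 * p + r, 1e-300), 0.0)
        scores.append(f)
    scores = np.array(scores)          # (n_folds_total, n_candidates)
    mean_f = scores.mean(axis=0)
    sd_f = scores.std(axis=0, ddof=1) if len(scores) > 1 else np.zeros(len(candidates))

    # full-data precision for the tie-break
    tp_full = (preds & y).sum(axis=1)
    fp_full = (preds & ~y).sum(axis=1)
    prec_full = np.where(tp_full + fp_full > 0,
                         tp_full / np.maximum(tp_full + fp_full, 1), 0.0)
    order = sorted(range(len(candidates)),
                   key=lambda i: (-mean_f[i], -prec_full[i],
                                  candidates[i].k, candidates[i].lookback_h))
    best = candidates[order[0]]

    table = pd.DataFrame({
        "lookback_h": [c.lookback_h for c in candidates],
        "k": [c.k for c in candidates],
        "reception_min": [c.reception_min for c in candidates],
        "mean_f05": mean_f, "sd_f05": sd_f, "precision": prec_full,
    }).sort_values("mean_f05", ascending=False, ignore_index=True)
    return best, table, evaluate(classify(gaps, best))
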