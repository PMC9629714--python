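"""Spatial allocation of hidden (disabled) time and activity rasters.

Two allocation methods spread each suspected disabling event's hidden hours
over the quarter-degree grid:

* linear — traverse the great-circle segment between the last ping before
  and the first ping after the gap at constant speed, splitting
  min(duration, cap) hours across cells in proportion to arc length
  (computed by sampling the arc at a fine angular step and binning);
* probabilistic — spread the hours over every cell reachable within the gap
  (cells whose center c satisfies d(start, c) + d(c, end) <= max_speed x
  duration, a great-circle ellipse), weighted by a fishing-activity prior
  (uniform when none is given).

Both conserve total attributed time exactly; events are capped at 336 h
(2 weeks) for the lower-bound estimate, uncapped for the upper bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .geo import great_circle_points, haversine_km, haversine_nmi, is_antipodal
from .grid import GridSpec, Raster

CAP_HOURS_DEFAULT = 336.0  # two weeks


class AllocationError(ValueError):
    pass


@dataclass(frozen=True)
class AllocationConfig:
    """Parameters of the probabilistic (bridge) allocation.

    ``max_speed_knots`` bounds the reachable set; ``detour_scale_knots``
    sets the exponential decay of cell weight with detour excess (the extra
    distance via the cell beyond the direct route), expressed in nautical
    miles of slack per gap hour.  Larger values spread the mass wider;
    0.0 would degenerate to the direct route only.
    """
    cap_h: float | None = CAP_HOURS_DEFAULT
    max_speed_knots: float = 10.0
    detour_scale_knots: float = 0.5
    arc_step_deg: float = 0.01

    def __post_init__(self) -> None:
        if self.cap_h is not None and self.cap_h <= 0:
            raise AllocationError("cap_h must be > 0 when set")
        if self.max_speed_knots <= 0:
            raise AllocationError("max_speed_knots must be > 0")
        if self.detour_scale_knots < 0:
            raise AllocationError("detour_scale_knots must be >= 0")


def _attributed_hours(duration_h: float, cap_h: float | None) -> float:
    return duration_h if cap_h is None else min(duration_h, cap_h)


def allocate_linear(start_lon: float, start_lat: float,
                    end_lon: float, end_lat: float, duration_h: float,
                    grid: GridSpec, cap_h: float | None = CAP_HOURS_DEFAULT,
                    arc_step_deg: float = 0.01) -> np.ndarray:
    """Hours-per-cell increments for one gap under the linear method.

    Antipodal endpoints (undefined great circle) fall back to all time at
    the start cell with a warning.
    """
    hours = _attributed_hours(duration_h, cap_h)
    out = np.zeros(grid.shape)
    if hours <= 0:
        return out
    same = (start_lon == end_lon) and (start_lat == end_lat)
    if not same and is_antipodal(start_lon, start_lat, end_lon, end_lat):
        warnings.warn("antipodal gap endpoints: allocating all time to the "
                      "start cell", RuntimeWarning, stacklevel=2)
        same = True
    if same:
        r, c = grid.cell_index(start_lon, start_lat)
        out[r, c] = hours
        return out
    arc_deg = np.degrees(haversine_km(start_lon, start_lat, end_lon, end_lat)
                         / 6371.0)
    n_seg = max(2, int(np.ceil(arc_deg / arc_step_deg)))
    lon, lat = great_circle_points(start_lon, start_lat, end_lon, end_lat,
                                   n_seg + 1)
    # bin segment midpoints; each segment carries an equal share of the time
    mlon = 0.5 * (lon[:-1] + lon[1:])
    mlat = 0.5 * (lat[:-1] + lat[1:])
    row, col = grid.cell_index(mlon, mlat)
    np.add.at(out, (row, col), hours / n_seg)
    return out


def allocate_probabilistic(start_lon: float, start_lat: float,
                           end_lon: float, end_lat: float, duration_h: float,
                           grid: GridSpec,
                           config: AllocationConfig = AllocationConfig(),
                           prior: Raster | None = None) -> np.ndarray:
    """Hours-per-cell increments under the rasterized-probability method.

    The feasible set is every cell center reachable within the gap at
    ``max_speed_knots`` (d(start, c) + d(c, end) <= speed x duration).
    Within it, cell weight is (prior + 1e-9) x exp(-excess / scale), where
    excess is the detour beyond the direct route and scale =
    detour_scale_knots x duration — a bridge-style kernel concentrating
    mass near the direct route for short gaps and spreading it for long
    ones.  Weights are normalised so the attributed hours are conserved.
    An empty feasible set degenerates to the start cell.
    """
    if prior is not None and prior.spec != grid:
        raise AllocationError("prior raster geometry does not match the grid")
    hours = _attributed_hours(duration_h, config.cap_h)
    out = np.zeros(grid.shape)
    if hours <= 0:
        return out
    lon, lat = grid.center_mesh()
    reach_nmi = config.max_speed_knots * duration_h
    detour = (haversine_nmi(start_lon, start_lat, lon, lat)
              + haversine_nmi(lon, lat, end_lon, end_lat))
    feasible = detour <= reach_nmi
    if not feasible.any():
        r, c = grid.cell_index(start_lon, start_lat)
        out[r, c] = hours
        return out
    direct = haversine_nmi(start_lon, start_lat, end_lon, end_lat)
    w = np.zeros(grid.shape)
    base = np.nan_to_num(prior.values, nan=0.0) if prior is not None \
        else np.zeros(grid.shape)
    if config.detour_scale_knots > 0:
        scale = config.detour_scale_knots * duration_h
        decay = np.exp(-(detour[feasible] - direct) / scale)
    else:
        decay = 1.0
    w[feasible] = (base[feasible] + 1e-9) * decay
    out = hours * w / w.sum()
    return out


def allocate_gaps(gaps: pd.DataFrame, grid: GridSpec, method: str = "linear",
                  cap_h: float | None = CAP_HOURS_DEFAULT,
                  config: AllocationConfig | None = None,
                  prior: Raster | None = None,
                  layer: str | None = None) -> Raster:
    """Sum per-gap allocations over a table of suspected disabling events."""
    import dataclasses
    config = AllocationConfig(cap_h=cap_h) if config is None \
        else dataclasses.replace(config, cap_h=cap_h)
    total = np.zeros(grid.shape)
    for g in gaps.itertuples(index=False):
        if method == "linear":
            total += allocate_linear(g.start_lon, g.start_lat, g.end_lon,
                                     g.end_lat, g.duration_h, grid,
                                     cap_h=cap_h,
                                     arc_step_deg=config.arc_step_deg)
        elif method == "probabilistic":
            total += allocate_probabilistic(g.start_lon, g.start_lat,
                                            g.end_lon, g.end_lat,
                                            g.duration_h, grid, config,
                                            prior=prior)
        else:
            raise AllocationError(f"unknown allocation method {method!r}")
    name = layer or f"disabling_time_{method}"
    return Raster(grid, total, layer=name, units="hours")


def activity_hours(messages: pd.DataFrame, grid: GridSpec,
                   stratum: str | None = None, max_interval_h: float = 12.0
                   ) -> Raster | dict[str, Raster]:
    """Broadcast-activity hours per cell.

    Time between consecutive pings of a vessel shorter than
    ``max_interval_h`` is split half/half between the two ping cells;
    longer intervals are gap candidates and contribute nothing.  With
    ``stratum`` ("gear" or "flag") a dict of per-stratum rasters is
    returned; strata partition the unstratified hours exactly.
    """
    def _accumulate(sub: pd.DataFrame, out: np.ndarray) -> None:
        for _, v in sub.groupby("vessel_id", sort=False):
            v = v.sort_values("timestamp", kind="stable")
            t = pd.DatetimeIndex(v["timestamp"]).tz_convert("UTC") \
                .tz_localize(None).to_numpy()
            dt_h = np.diff(t) / np.timedelta64(1, "s") / 3600.0
            ok = dt_h < max_interval_h
            if not ok.any():
                continue
            lon = v["lon"].to_numpy()
            lat = v["lat"].to_numpy()
            half = 0.5 * dt_h[ok]
            i = np.flatnonzero(ok)
            r1, c1 = grid.cell_index(lon[i], lat[i])
            r2, c2 = grid.cell_index(lon[i + 1], lat[i + 1])
            np.add.at(out, (r1, c1), half)
            np.add.at(out, (r2, c2), half)

    if stratum is None:
        out = np.zeros(grid.shape)
        _accumulate(messages, out)
        return Raster(grid, out, layer="vessel_activity", units="hours")
    result: dict[str, Raster] = {}
    for key, sub in messages.groupby(stratum, sort=True):
        out = np.zeros(grid.shape)
        _accumulate(sub, out)
        result[str(key)] = Raster(grid, out, layer=f"vessel_activity_{key}",
                                  units="hours")
    return result


def fraction_obscured(disabling: Raster, activity: Raster) -> Raster:
    """Fraction of at-sea time hidden per cell: d / (a + d), missing where
    the denominator is zero."""
    if disabling.spec != activity.spec:
        raise AllocationError("disabling/activity raster geometry mismatch")
    d = disabling.values
    a = activity.values
    denom = np.nan_to_num(a, nan=0.0) + np.nan_to_num(d, nan=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, np.nan_to_num(d, nan=0.0) / np.where(denom > 0, denom, 1),
                        np.nan)
    return Raster(disabling.spec, frac, layer="fraction_obscured", units="")


def hotspots(fraction: Raster, activity: Raster, f_min: float, a_min: float
             ) -> pd.DataFrame:
    """Cells with fraction >= f_min and activity >= a_min, labelled by
    rook-adjacent (edge-sharing) connected component."""
    if fraction.spec != activity.spec:
        raise AllocationError("fraction/activity raster geometry mismatch")
    sel = (np.nan_to_num(fraction.values, nan=-np.inf) >= f_min) \
        & (np.nan_to_num(activity.values, nan=-np.inf) >= a_min)
    labels, n = ndimage.label(sel)  # default structure = rook adjacency
    rows, cols = np.nonzero(sel)
    lon, lat = fraction.spec.cell_center(rows, cols)
    return pd.DataFrame({"row": rows, "col": cols, "lon": lon, "lat": lat,
                         "component": labels[rows, cols],
                         "fraction": fraction.values[rows, cols],
                         "activity_h": activity.values[rows, cols]})


def summarize_disabling(gaps: pd.DataFrame, messages: pd.DataFrame,
                        grid: GridSpec, by: str = "gear",
                        cap_h: float = CAP_HOURS_DEFAULT) -> pd.DataFrame:
    """Per-stratum summary of suspected disabling: event count, hours lost
    (lower bound = capped at ``cap_h``, upper = uncapped) and fraction of
    at-sea time obscured (hidden / (activity + hidden))."""
    from .gap_classifier import SUSPECTED
    sus = gaps[gaps["classification"] == SUSPECTED]
    act = activity_hours(messages, grid, stratum=by)
    rows = []
    for key, sub in sus.groupby(by, sort=True):
        lower = np.minimum(sub["duration_h"], cap_h).sum()
        upper = sub["duration_h"].sum()
        a = float(np.nansum(act[str(key)].values)) if str(key) in act else 0.0
        rows.append({by: key, "events": len(sub),
                     "hours_lost_lower": lower, "hours_lost_upper": upper,
                     "fraction_lower": lower / (a + lower) if a + lower > 0 else np.nan,
                     "fraction_upper": upper / (a + upper) if a + upper > 0 else np.nan})
    return pd.DataFrame(rows)
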