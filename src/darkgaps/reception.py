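"""Satellite reception quality: observed per-cell maps and a finer
interpolated prediction surface.

Observed reception in a cell is the average number of satellite-received
AIS positions per vessel per day, computed separately for class A and
class B transponders: each vessel-day is attributed to the cell holding the
vessel's daily mean position, and the cell value is total messages divided
by total vessel-days.  Cells with no vessel-days are missing (NaN), never
zero — absence of vessels is not absence of reception.

The predicted surface interpolates observed 1-degree cell-center values to a
finer grid (0.25 degrees by default) with a thin-plate-spline radial basis
function, zero smoothing (exact at the observed centers) and a degree-1
polynomial tail, then clamps negative interpolants at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator

from .grid import GridSpec, Raster


class ReceptionError(ValueError):
    pass


@dataclass
class ReceptionGrid:
    """Per-cell reception quality (positions per vessel per day) for one
    device class; ``support`` is vessel-days per cell (observed grids only)."""
    raster: Raster
    device_class: str
    kind: str  # "observed" | "predicted"
    support: Raster | None = None

    @property
    def spec(self) -> GridSpec:
        return self.raster.spec

    @property
    def values(self) -> np.ndarray:
        return self.raster.values


def _grid_for(messages: pd.DataFrame, cell_size: float) -> GridSpec:
    """Smallest grid with cells on the global (-180, -90) lattice covering
    all message positions."""
    west = np.floor((messages["lon"].min() + 180) / cell_size) * cell_size - 180
    south = np.floor((messages["lat"].min() + 90) / cell_size) * cell_size - 90
    east = np.ceil((messages["lon"].max() + 180) / cell_size) * cell_size - 180
    north = np.ceil((messages["lat"].max() + 90) / cell_size) * cell_size - 90
    if east <= messages["lon"].max():
        east += cell_size
    if north <= messages["lat"].max():
        north += cell_size
    return GridSpec(west, south, east, north, cell_size)


def observed_reception(messages: pd.DataFrame, cell_size: float = 1.0,
                       spec: GridSpec | None = None) -> dict[str, ReceptionGrid]:
    """Observed reception per device class at ``cell_size`` degrees.

    Returns a dict keyed by device class.  Raises if there are no messages.
    """
    if len(messages) == 0:
        raise ReceptionError("no messages: zero vessel-days overall")
    if spec is None:
        spec = _grid_for(messages, cell_size)
    out: dict[str, ReceptionGrid] = {}
    for dev, sub in messages.groupby("device_class", sort=True):
        day = sub["timestamp"].dt.floor("D")
        per_day = sub.groupby(["vessel_id", day], observed=True).agg(
            lon=("lon", "mean"), lat=("lat", "mean"), n=("lon", "size"))
        row, col = spec.cell_index(per_day["lon"].to_numpy(),
                                   per_day["lat"].to_numpy())
        msgs = np.zeros(spec.shape)
        vdays = np.zeros(spec.shape)
        np.add.at(msgs, (row, col), per_day["n"].to_numpy())
        np.add.at(vdays, (row, col), 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(vdays > 0, msgs / np.where(vdays > 0, vdays, 1), np.nan)
        out[str(dev)] = ReceptionGrid(
            raster=Raster(spec, vals, layer=f"reception_observed_{dev}",
                          units="positions/vessel/day"),
            device_class=str(dev), kind="observed",
            support=Raster(spec, vdays, layer="vessel_days"))
    return out


def reception_interpolator(observed: ReceptionGrid):
    """Exact (zero-smoothing) thin-plate-spline interpolant through the
    non-missing observed cell-center values; callable on (n, 2) lon/lat
    points.  Requires at least 4 observed cells."""
    obs = observed.raster
    mask = np.isfinite(obs.values)
    if mask.sum() < 4:
        raise ReceptionError(
            f"need >= 4 observed cells for interpolation, have {int(mask.sum())}")
    vals = obs.values[mask]
    if not np.all(np.isfinite(vals)):
        raise ReceptionError("non-finite observed reception values")
    lon, lat = obs.spec.center_mesh()
    pts = np.column_stack([lon[mask], lat[mask]])
    return RBFInterpolator(pts, vals, kernel="thin_plate_spline",
                           smoothing=0.0, degree=1)


def predict_reception(observed: ReceptionGrid,
                      target_cell_size: float = 0.25,
                      spec: GridSpec | None = None) -> ReceptionGrid:
    """Interpolate observed cell-center values to a finer grid.

    Exact thin-plate-spline interpolation (see
    :func:`reception_interpolator`) evaluated at the target cell centers;
    negative interpolants are clamped to zero.
    """
    obs = observed.raster
    rbf = reception_interpolator(observed)
    if spec is None:
        s = obs.spec
        spec = GridSpec(s.west, s.south, s.east, s.north, target_cell_size)
    tlon, tlat = spec.center_mesh()
    pred = rbf(np.column_stack([tlon.ravel(), tlat.ravel()])).reshape(spec.shape)
    pred = np.clip(pred, 0.0, None)
    return ReceptionGrid(
        raster=Raster(spec, pred, layer=f"reception_predicted_{observed.device_class}",
                      units="positions/vessel/day"),
        device_class=observed.device_class, kind="predicted")


def reception_at(grid: ReceptionGrid, lon, lat):
    """Reception at a point: value of the containing cell, NaN if the cell is
    missing; raises OutsideExtentError outside the extent."""
    return grid.raster.value_at(lon, lat)
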