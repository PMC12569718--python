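"""Linkage of gridded monthly exposure fields to residence histories.

Individual annual exposure is built in two steps: the monthly concentration
at a residence is obtained by bilinear interpolation over the nearest four
grid nodes, and the time-varying annual mean is the arithmetic mean of the
twelve monthly values. A residence move takes effect on the first day of
its recorded month.

Grid node values are treated as point values at cell centres (the bilinear
form has point support). Points outside the grid's bounding box raise
``OutOfDomainError``; if any of the four surrounding nodes is missing the
result is NaN, a missing-exposure flag that later triggers the
complete-exposure eligibility exclusion rather than extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "GridField",
    "ResidenceHistory",
    "OutOfDomainError",
    "bilinear_interpolate",
    "annual_mean_exposure",
    "link_history",
]


class OutOfDomainError(ValueError):
    """Raised when a query point falls outside the grid's bounding box."""


class GridField:
    """A regular 2-D grid of monthly concentration surfaces.

    Parameters
    ----------
    values : array, shape (n_months, ny, nx)
        Monthly concentrations in µg/m³; NaN marks missing nodes.
    x, y : 1-D arrays
        Strictly monotone coordinate axes (projected or degree units).
    """

    def __init__(self, values, x, y):
        values = np.asarray(values, dtype=float)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if values.ndim == 2:
            values = values[None, :, :]
        if values.ndim != 3:
            raise ValueError("values must have shape (n_months, ny, nx)")
        if values.shape[1] != y.size or values.shape[2] != x.size:
            raise ValueError("axis lengths do not match values shape")
        for ax in (x, y):
            d = np.diff(ax)
            if ax.size < 2 or not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("axes must be strictly monotone with >=2 nodes")
        # normalise to ascending axes so lookups are uniform
        if x[1] < x[0]:
            x, values = x[::-1], values[:, :, ::-1]
        if y[1] < y[0]:
            y, values = y[::-1], values[:, ::-1, :]
        with np.errstate(invalid="ignore"):
            if np.any(values < 0):
                raise ValueError("concentrations must be >= 0 or missing (NaN)")
        self.values = values
        self.x = x
        self.y = y

    @property
    def n_months(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_dataarray(cls, da: xr.DataArray, x: str = "x", y: str = "y",
                       time: str = "time") -> "GridField":
        da = da.transpose(time, y, x)
        return cls(da.values, da[x].values, da[y].values)

    @classmethod
    def from_file(cls, path, **kwargs) -> "GridField":
        return cls.from_dataarray(xr.open_dataarray(path), **kwargs)

    def to_dataarray(self) -> xr.DataArray:
        return xr.DataArray(
            self.values,
            coords={"time": np.arange(self.n_months), "y": self.y, "x": self.x},
            dims=("time", "y", "x"),
            name="concentration",
        )

    def interpolate(self, x: float, y: float, month: int) -> float:
        return bilinear_interpolate(self, (x, y), month)


def _bracket(axis: np.ndarray, v: float) -> tuple[int, float]:
    """Index i and fraction f with axis[i] <= v <= axis[i+1]."""
    if v < axis[0] or v > axis[-1]:
        raise OutOfDomainError(f"coordinate {v} outside [{axis[0]}, {axis[-1]}]")
    i = int(np.searchsorted(axis, v, side="right") - 1)
    i = min(i, axis.size - 2)
    f = (v - axis[i]) / (axis[i + 1] - axis[i])
    return i, f


def bilinear_interpolate(field: GridField, point, month: int) -> float:
    """Bilinear interpolation at ``point`` using the nearest 4 grid nodes.

    Returns NaN (missing-exposure flag) when any of the four surrounding
    node values is missing. The result always lies within [min, max] of
    the four node values.
    """
    px, py = float(point[0]), float(point[1])
    if not 0 <= month < field.n_months:
        raise IndexError(f"month {month} outside 0..{field.n_months - 1}")
    ix, fx = _bracket(field.x, px)
    iy, fy = _bracket(field.y, py)
    z = field.values[month, iy : iy + 2, ix : ix + 2]
    if np.any(np.isnan(z)):
        return float("nan")
    return float(
        z[0, 0] * (1 - fx) * (1 - fy)
        + z[0, 1] * fx * (1 - fy)
        + z[1, 0] * (1 - fx) * fy
        + z[1, 1] * fx * fy
    )


def annual_mean_exposure(monthly: Sequence[float]) -> float:
    """Arithmetic mean of exactly 12 monthly values.

    Any missing month (NaN) propagates: the annual value is NaN, flagging
    the subject-year as missing exposure.
    """
    arr = np.asarray(monthly, dtype=float)
    if arr.shape != (12,):
        raise ValueError(f"expected 12 monthly values, got shape {arr.shape}")
    if np.any(np.isnan(arr)):
        return float("nan")
    return float(arr.mean())


@dataclass(frozen=True)
class ResidenceSegment:
    start_month: int  # first month (0-based index into the field) of validity
    x: float
    y: float


class ResidenceHistory:
    """Ordered residence segments; each valid from its start month onward."""

    def __init__(self, segments: Sequence[ResidenceSegment | tuple]):
        segs = [s if isinstance(s, ResidenceSegment) else ResidenceSegment(*s)
                for s in segments]
        if not segs:
            raise ValueError("residence history must contain >=1 segment")
        starts = [s.start_month for s in segs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start months must be strictly increasing")
        self.segments = segs

    def location_at(self, month: int) -> tuple[float, float]:
        if month < self.segments[0].start_month:
            raise ValueError(f"month {month} precedes the residence history")
        active = self.segments[0]
        for seg in self.segments:
            if seg.start_month <= month:
                active = seg
            else:
                break
        return active.x, active.y

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResidenceHistory":
        df = df.sort_values("start_month")
        return cls(list(df[["start_month", "x", "y"]].itertuples(index=False, name=None)))


def link_history(field: GridField, history: ResidenceHistory, year: int) -> float:
    """Annual mean exposure for ``year`` (0-based from the field's origin).

    Interpolates month by month at the residence active in that month,
    then averages; missing flags propagate as NaN.
    """
    months = range(12 * year, 12 * year + 12)
    vals = [bilinear_interpolate(field, history.location_at(m), m) for m in months]
    return annual_mean_exposure(vals)


def read_residence_histories(path) -> dict[object, ResidenceHistory]:
    """Read residence histories from CSV with columns subject_id, start_month, x, y."""
    df = pd.read_csv(path)
    return {sid: ResidenceHistory.from_frame(g) for sid, g in df.groupby("subject_id")}
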