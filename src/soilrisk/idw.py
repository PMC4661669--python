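"""Inverse-distance-weighted interpolation onto a raster grid, with
leave-one-out RMSE cross-validation and raster classification.

IDW is exact at data points, bounded by the data range and — unlike
kriging or spline smoothing — preserves local extrema, which is the
point of using it for hotspot mapping: the interpolated surface keeps
the local maxima and minima that pollution regionalization cares about.

    z(x) = sum_i w_i z_i / sum_i w_i,   w_i = d_i^(-p)

over the k nearest sample points (ties at the k-th distance are all
included, making the neighborhood order-independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .config import ConfigError, classify_value


@dataclass(frozen=True)
class GridSpec:
    """Planar cell grid; origin at the lower-left corner, cell-center
    evaluation.  Row 0 of the value array is the northernmost row (the
    ESRI ASCII file order)."""

    x_origin: float
    y_origin: float
    cell_size: float
    n_cols: int
    n_rows: int
    nodata: float = -9999.0

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ConfigError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ConfigError("grid must have at least one row and column")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of shape (n_rows, n_cols) of cell-center coordinates."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.x_origin + (cols + 0.5) * self.cell_size
        # row 0 is the northernmost row
        y = self.y_origin + (self.n_rows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def rowcol_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/column of the cell containing (x, y); raises if outside."""
        col = int(np.floor((x - self.x_origin) / self.cell_size))
        row_from_south = int(np.floor((y - self.y_origin) / self.cell_size))
        row = self.n_rows - 1 - row_from_south
        if not (0 <= col < self.n_cols and 0 <= row < self.n_rows):
            raise ValueError(f"point ({x}, {y}) outside grid")
        return row, col

    def matches(self, other: "GridSpec", rtol: float = 1e-6) -> bool:
        return (
            self.n_cols == other.n_cols
            and self.n_rows == other.n_rows
            and np.isclose(self.x_origin, other.x_origin, rtol=rtol, atol=1e-9)
            and np.isclose(self.y_origin, other.y_origin, rtol=rtol, atol=1e-9)
            and np.isclose(self.cell_size, other.cell_size, rtol=rtol)
        )


@dataclass
class Raster:
    """Values on a grid plus a nodata mask (True = nodata)."""

    spec: GridSpec
    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError(
                f"raster shape {self.values.shape} does not match spec "
                f"({self.spec.n_rows}, {self.spec.n_cols})"
            )
        if self.mask is None:
            self.mask = np.zeros_like(self.values, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values")

    def valid_values(self) -> np.ndarray:
        return self.values[~self.mask]


@dataclass(frozen=True)
class IdwParams:
    """power: inverse-distance exponent p; k: neighbor count (None = all);
    snap_eps: distance in meters below which a query snaps to a data point."""

    power: float = 2.0
    k: Optional[int] = 12
    snap_eps: float = 1e-9

    def __post_init__(self):
        if not (self.power > 0):
            raise ConfigError(f"idw power must be > 0, got {self.power}")
        if self.k is not None and self.k < 1:
            raise ConfigError(f"idw k must be >= 1, got {self.k}")

    @classmethod
    def from_mapping(cls, raw) -> "IdwParams":
        allowed = {"power", "k", "snap_eps"}
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigError(f"idw: unknown key(s) {sorted(unknown)}")
        k = raw.get("k", 12)
        if isinstance(k, str):
            if k != "all":
                raise ConfigError(f"idw.k: expected an integer or 'all', got {k!r}")
            k = None
        return cls(power=float(raw.get("power", 2.0)),
                   k=(None if k is None else int(k)),
                   snap_eps=float(raw.get("snap_eps", 1e-9)))


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of x, y")
    return pts


def idw_predict(points: Sequence, values: Sequence[float], at,
                params: IdwParams = IdwParams()) -> float:
    """IDW prediction at a single location."""
    pts = _as_points(points)
    vals = np.asarray(values, dtype=float)
    if len(pts) == 0:
        raise ValueError("empty point set")
    if len(vals) != len(pts):
        raise ValueError(f"{len(pts)} points but {len(vals)} values")
    at = np.asarray(at, dtype=float)
    d = np.hypot(pts[:, 0] - at[0], pts[:, 1] - at[1])
    imin = int(np.argmin(d))
    if d[imin] <= params.snap_eps:
        return float(vals[imin])
    if params.k is not None and params.k < len(pts):
        kth = np.partition(d, params.k - 1)[params.k - 1]
        use = d <= kth  # include all points co-distant with the k-th
    else:
        use = slice(None)
    du = d[use]
    # normalize by the nearest distance so large powers cannot overflow
    w = (du / du.min()) ** (-params.power)
    return float(np.sum(w * vals[use]) / np.sum(w))


def idw_grid(points: Sequence, values: Sequence[float], spec: GridSpec,
             params: IdwParams = IdwParams(),
             mask: Optional[np.ndarray] = None) -> Raster:
    """IDW surface over the grid's cell centers; masked cells hold nodata."""
    pts = _as_points(points)
    vals = np.asarray(values, dtype=float)
    if len(pts) == 0:
        raise ValueError("empty point set")
    if len(vals) != len(pts):
        raise ValueError(f"{len(pts)} points but {len(vals)} values")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (spec.n_rows, spec.n_cols):
            raise ValueError("mask dimensions do not match grid spec")

    X, Y = spec.cell_centers()
    q = np.column_stack([X.ravel(), Y.ravel()])
    if mask is not None:
        active = ~mask.ravel()
        q_active = q[active]
    else:
        active = np.ones(len(q), dtype=bool)
        q_active = q

    out = np.full(len(q), spec.nodata, dtype=float)
    n = len(pts)
    k = n if (params.k is None or params.k >= n) else params.k

    if k < n:
        tree = cKDTree(pts)
        d, idx = tree.query(q_active, k=k)
        d = np.atleast_2d(d)
        idx = np.atleast_2d(idx)
        # tie inclusion: widen any neighborhood whose k-th distance is
        # matched by an excluded point
        kth = d[:, -1]
        counts = tree.query_ball_point(q_active, kth + 1e-12, return_length=True)
        ragged = np.nonzero(counts > k)[0]
        pred = _weighted(d, np.take(vals, idx), params)
        for i in ragged:
            pred[i] = idw_predict(pts, vals, q_active[i], params)
    else:
        d = np.sqrt(((q_active[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        pred = _weighted(d, np.broadcast_to(vals, d.shape), params)

    out[active] = pred
    raster = Raster(
        spec=spec,
        values=out.reshape(spec.n_rows, spec.n_cols),
        mask=(mask.copy() if mask is not None else None),
    )
    return raster


def _weighted(d: np.ndarray, v: np.ndarray, params: IdwParams) -> np.ndarray:
    dmin = d.min(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (d / np.where(dmin > 0, dmin, 1.0)) ** (-params.power)
    exact = d <= params.snap_eps
    rows_exact = exact.any(axis=1)
    w = np.where(np.isfinite(w), w, 0.0)
    pred = np.einsum("ij,ij->i", w, v) / w.sum(axis=1)
    if rows_exact.any():
        first = exact.argmax(axis=1)
        pred[rows_exact] = v[rows_exact, first[rows_exact]]
    return pred


def loo_rmse(points: Sequence, values: Sequence[float],
             params: IdwParams = IdwParams()) -> float:
    """Leave-one-out cross-validation RMSE of the IDW predictor."""
    pts = _as_points(points)
    vals = np.asarray(values, dtype=float)
    if len(pts) < 2:
        raise ValueError("leave-one-out validation needs at least 2 points")
    sq = 0.0
    keep = np.ones(len(pts), dtype=bool)
    for i in range(len(pts)):
        keep[i] = False
        pred = idw_predict(pts[keep], vals[keep], pts[i], params)
        sq += (vals[i] - pred) ** 2
        keep[i] = True
    return float(np.sqrt(sq / len(pts)))


def classify_raster(r: Raster, breaks: Sequence[float]) -> Raster:
    """Cellwise interval classification into rank 0..len(breaks).

    Uses the shared lower-open/upper-closed convention; nodata
    propagates unchanged.
    """
    brks = tuple(float(b) for b in breaks)
    if any(b <= a for a, b in zip(brks, brks[1:])):
        raise ValueError(f"non-increasing breaks {brks}")
    # searchsorted(side='left') counts breaks strictly below each value,
    # matching classify_value's convention
    ranks = np.searchsorted(brks, r.values, side="left").astype(float)
    ranks[r.mask] = r.spec.nodata
    return Raster(spec=r.spec, values=ranks, mask=r.mask.copy())


__all__ = [
    "GridSpec", "Raster", "IdwParams",
    "idw_predict", "idw_grid", "loo_rmse", "classify_raster", "classify_value",
]
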