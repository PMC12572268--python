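"""Facility-to-grid assignment and inter-facility distance covariates.

Facilities are matched to their nearest precipitation grid cell with a k-d
tree over the raw (lat, lon) cell centres, mirroring the usual reanalysis
station-matching workflow. Inter-facility distances use an equirectangular
local projection (longitude scaled by cos of the mean latitude, 111,320 m per
degree): over a country-sized extent any consistent planar metric preserves
the ordering the regression needs, and the projection is documented and
configurable through `metres_per_degree`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

METRES_PER_DEGREE = 111_320.0


def nearest_grid_cell(
    lon: np.ndarray | float,
    lat: np.ndarray | float,
    grid_lat: np.ndarray,
    grid_lon: np.ndarray,
) -> np.ndarray:
    """Assign points to nearest grid-cell centres (row-major cell ids).

    Distance is computed in degree space over the raw grid coordinates.
    Ties are broken by the lowest cell id. Points outside the grid hull are
    still assigned to the nearest cell, with a warning.

    Returns an int array of cell ids (``lat_index * n_lon + lon_index``);
    a scalar input yields a 0-d-compatible length-1 handling via np.atleast_1d.
    """
    grid_lat = np.asarray(grid_lat, dtype=float)
    grid_lon = np.asarray(grid_lon, dtype=float)
    if grid_lat.size == 0 or grid_lon.size == 0:
        raise ValueError("empty grid")
    lon_a = np.atleast_1d(np.asarray(lon, dtype=float))
    lat_a = np.atleast_1d(np.asarray(lat, dtype=float))

    glat, glon = np.meshgrid(grid_lat, grid_lon, indexing="ij")
    centres = np.column_stack([glat.ravel(), glon.ravel()])
    tree = cKDTree(centres)
    points = np.column_stack([lat_a, lon_a])
    k = min(4, len(centres))
    dist, idx = tree.query(points, k=k)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    # lowest-id tie-break among centres at (numerically) minimal distance
    best = np.empty(len(points), dtype=np.int64)
    for i in range(len(points)):
        tied = idx[i][np.isclose(dist[i], dist[i, 0], rtol=0.0, atol=1e-9)]
        best[i] = tied.min()

    # a point within half a cell spacing of the outermost centre is still
    # inside that cell, not outside the hull
    lat_margin = np.diff(grid_lat).max() / 2 if grid_lat.size > 1 else 0.0
    lon_margin = np.diff(grid_lon).max() / 2 if grid_lon.size > 1 else 0.0
    outside = (
        (lat_a < grid_lat.min() - lat_margin) | (lat_a > grid_lat.max() + lat_margin)
        | (lon_a < grid_lon.min() - lon_margin) | (lon_a > grid_lon.max() + lon_margin)
    )
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} point(s) outside the grid hull; "
            "assigned to nearest edge cell",
            stacklevel=2,
        )
    return best if np.ndim(lon) else int(best[0])


def assign_cells(facilities: pd.DataFrame, grid_lat: np.ndarray,
                 grid_lon: np.ndarray) -> pd.DataFrame:
    """Return a copy of the facility table with a ``cell_id`` column."""
    out = facilities.copy()
    out["cell_id"] = nearest_grid_cell(
        out["lon"].to_numpy(), out["lat"].to_numpy(), grid_lat, grid_lon
    )
    return out


def project_lonlat_to_metres(
    lon: np.ndarray, lat: np.ndarray, metres_per_degree: float = METRES_PER_DEGREE
) -> np.ndarray:
    """Equirectangular projection of lon/lat degrees to planar metres."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lat0 = np.deg2rad(lat.mean())
    x = lon * np.cos(lat0) * metres_per_degree
    y = lat * metres_per_degree
    return np.column_stack([x, y])


def min_distance_to_closest(
    facilities: pd.DataFrame, metres_per_degree: float = METRES_PER_DEGREE
) -> pd.Series:
    """Euclidean distance (m) from each facility to its closest neighbour."""
    if len(facilities) < 2:
        raise ValueError("min_distance_to_closest needs at least 2 facilities")
    xy = project_lonlat_to_metres(
        facilities["lon"].to_numpy(), facilities["lat"].to_numpy(),
        metres_per_degree,
    )
    tree = cKDTree(xy)
    dist, _ = tree.query(xy, k=2)
    return pd.Series(dist[:, 1], index=facilities.index, name="min_distance_m")


def add_min_distance(facilities: pd.DataFrame,
                     metres_per_degree: float = METRES_PER_DEGREE) -> pd.DataFrame:
    out = facilities.copy()
    out["min_distance_m"] = min_distance_to_closest(out, metres_per_degree)
    return out
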