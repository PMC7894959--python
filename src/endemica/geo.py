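"""Range geometry: EOO by minimum convex polygon, AOO by occupied grid cells.

Extent of occurrence (EOO) is the area of the minimum convex polygon around
all occurrences; area of occupancy (AOO) is the summed area of occupied grid
cells (1 × 1 km by default). Points are projected with a spherical Lambert
azimuthal equal-area projection centred on their centroid, so hull and cell
areas are area-true without any zone configuration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import MultiPoint

from .datamodel import OccurrencePoint

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius

__all__ = [
    "RangeMetrics",
    "project_points",
    "eoo",
    "aoo",
    "density",
    "format_density",
    "range_metrics",
]


@dataclass
class RangeMetrics:
    """Bundle of range metrics for one set of occurrences."""

    eoo_km2: float
    eoo_km2_raw: float
    eoo_degenerate: bool
    aoo_km2: float
    n_cells: int
    cell_km: float
    hull_vertices: np.ndarray
    cells_by_subpop: dict[str, set[tuple[int, int]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "eoo_km2": self.eoo_km2,
            "eoo_km2_raw": self.eoo_km2_raw,
            "eoo_degenerate": self.eoo_degenerate,
            "aoo_km2": self.aoo_km2,
            "n_cells": self.n_cells,
            "cell_km": self.cell_km,
            "hull_vertices": self.hull_vertices.tolist(),
            "cells_by_subpop": {
                k: sorted(list(c) for c in v) for k, v in self.cells_by_subpop.items()
            },
        }


def project_points(points: Sequence[OccurrencePoint]) -> np.ndarray:
    """Project WGS84 points to planar (x, y) km, equal-area, centroid-centred.

    Spherical Lambert azimuthal equal-area projection centred on the mean
    lon/lat of the input. Returns an (n, 2) array in km.
    """
    if len(points) == 0:
        raise ValueError("cannot project an empty point set")
    lon = np.radians([p.lon for p in points])
    lat = np.radians([p.lat for p in points])
    lon0 = lon.mean()
    lat0 = lat.mean()
    # Lambert azimuthal equal-area (Snyder 1987, eq. 24-2..24-4)
    cos_c = np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(lon - lon0)
    cos_c = np.clip(cos_c, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        kprime = np.sqrt(2.0 / (1.0 + cos_c))
    kprime = np.where(np.isfinite(kprime), kprime, 0.0)
    x = EARTH_RADIUS_KM * kprime * np.cos(lat) * np.sin(lon - lon0)
    y = EARTH_RADIUS_KM * kprime * (
        np.cos(lat0) * np.sin(lat) - np.sin(lat0) * np.cos(lat) * np.cos(lon - lon0)
    )
    return np.column_stack([x, y])


def eoo(
    xy: np.ndarray, aoo_km2: Optional[float] = None
) -> tuple[float, float, bool, np.ndarray]:
    """Convex-hull area of projected points.

    Returns ``(adjusted, raw, degenerate, hull_vertices)``. Degenerate hulls
    (fewer than 3 distinct points, or collinear points) have raw area 0. Per
    IUCN guidance the reported EOO is never smaller than the AOO, so when
    ``aoo_km2`` is supplied the adjusted value is ``max(raw, aoo_km2)``.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[0] == 0:
        raise ValueError("need at least one projected point")
    hull = MultiPoint([tuple(p) for p in xy]).convex_hull
    raw = float(hull.area)
    if hull.geom_type == "Polygon":
        verts = np.asarray(hull.exterior.coords)[:-1]
    else:  # Point or LineString: degenerate
        verts = np.asarray(hull.coords)
    degenerate = hull.geom_type != "Polygon" or raw == 0.0
    if degenerate:
        raw = 0.0
    adjusted = raw
    if aoo_km2 is not None and adjusted < aoo_km2:
        adjusted = float(aoo_km2)
    return adjusted, raw, degenerate, verts


def _cells(
    xy: np.ndarray, cell_km: float, origin: tuple[float, float]
) -> set[tuple[int, int]]:
    ox, oy = origin
    ix = np.floor((xy[:, 0] - ox) / cell_km).astype(int)
    iy = np.floor((xy[:, 1] - oy) / cell_km).astype(int)
    return set(zip(ix.tolist(), iy.tolist()))


def aoo(
    xy: np.ndarray, cell_km: float = 1.0, origin: tuple[float, float] = (0.0, 0.0)
) -> tuple[float, int, set[tuple[int, int]]]:
    """Occupied-grid-cell area of projected points.

    Cells are half-open squares ``[origin + k*cell, origin + (k+1)*cell)``.
    Returns ``(aoo_km2, n_cells, cell_index_set)``.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[0] == 0:
        raise ValueError("need at least one projected point")
    if not cell_km > 0:
        raise ValueError(f"cell_km must be > 0, got {cell_km}")
    cells = _cells(xy, cell_km, origin)
    return len(cells) * cell_km**2, len(cells), cells


def density(n_mature: int, local_eoo_m2: float) -> float:
    """Plants per m²: mature individuals divided by the local EOO."""
    if not local_eoo_m2 > 0:
        raise ValueError(f"local_eoo_m2 must be > 0, got {local_eoo_m2}")
    if n_mature < 0:
        raise ValueError("n_mature must be >= 0")
    return n_mature / local_eoo_m2


def format_density(value: float, sig_figs: int = 1) -> str:
    """Round a density for display to the given significant figures.

    Field tables print densities to one significant figure (0.003, 0.7, ...).
    """
    if value == 0:
        return "0"
    exponent = math.floor(math.log10(abs(value)))
    decimals = max(sig_figs - 1 - exponent, 0)
    return f"{round(value, sig_figs - 1 - exponent):.{decimals}f}"


def range_metrics(
    points: Sequence[OccurrencePoint],
    cell_km: float = 1.0,
    origin: tuple[float, float] = (0.0, 0.0),
    local_eoo_m2_by_subpop: Optional[dict[str, float]] = None,
) -> RangeMetrics:
    """Compute EOO, AOO and per-subpopulation cell sets for a point set."""
    xy = project_points(points)
    aoo_km2, n_cells, _ = aoo(xy, cell_km=cell_km, origin=origin)
    adjusted, raw, degenerate, verts = eoo(xy, aoo_km2=aoo_km2)
    cells_by_subpop: dict[str, set[tuple[int, int]]] = {}
    for p, coord in zip(points, xy):
        cells_by_subpop.setdefault(p.subpopulation, set()).update(
            _cells(coord[None, :], cell_km, origin)
        )
    logger.info(
        "range metrics: %d points, EOO %.3f km2 (raw %.3f), AOO %.1f km2 (%d cells)",
        len(points),
        adjusted,
        raw,
        aoo_km2,
        n_cells,
    )
    return RangeMetrics(
        eoo_km2=adjusted,
        eoo_km2_raw=raw,
        eoo_degenerate=degenerate,
        aoo_km2=aoo_km2,
        n_cells=n_cells,
        cell_km=cell_km,
        hull_vertices=verts,
        cells_by_subpop=cells_by_subpop,
    )
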