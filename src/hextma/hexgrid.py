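"""Hexagonal tiling of nuclei point data.

A whole-slide digital image analysis (DIA) run exports one record per
detected nucleus: planar coordinates and a positive/negative marker call.
This module overlays a dense hexagonal grid on those points — each hexagon
standing in for one virtual tissue-microarray core — counts positive and
negative nuclei per tile, computes local and whole-region labeling indices
(LI = positives / total), and applies the informativeness filters used for
the sampling simulations: empty tiles are *missing* data, tiles with fewer
than ``min_nuclei`` profiles are *insufficiently sampled*, and a case enters
the simulations only if it has at least ``min_informative_tiles``
informative tiles.

Coordinates are micrometres internally.  Hexagons are addressed by axial
coordinates ``(q, r)``; the default circumradius of 412.5 µm (825 pixels at
0.5 µm/px) gives a tile of 0.442 mm², the area of a 0.75 mm-diameter
circular TMA core to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint
from shapely.geometry.base import BaseGeometry

__all__ = [
    "DEFAULT_CIRCUMRADIUS_UM",
    "HexGridSpec",
    "TumorCase",
    "TilingResult",
    "hexagon_area",
    "build_tiling",
    "whole_region_li",
]

#: 825 pixels at 0.5 µm per pixel.
DEFAULT_CIRCUMRADIUS_UM = 412.5

# Axial offsets of the 6 hexagon neighbours (distance 1 on the hex lattice).
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1),
)

# Column order of the tiles table produced by build_tiling.
TILE_COLUMNS = (
    "q", "r", "center_x_um", "center_y_um", "n_pos", "n_neg", "local_li", "status",
)

STATUS_MISSING = "missing"
STATUS_INSUFFICIENT = "insufficient"
STATUS_INFORMATIVE = "informative"


def hexagon_area(circumradius_um: float) -> float:
    """Area in mm² of a regular hexagon with the given circumradius in µm.

    The circumradius equals the side length; area = (3√3/2)·r².  For the
    default 412.5 µm radius this is 0.442 mm² — the area of a 0.75 mm
    diameter circle to two decimal places, which is what makes the hexagon a
    faithful virtual TMA core.
    """
    if not np.isfinite(circumradius_um) or circumradius_um <= 0:
        raise ValueError(f"circumradius must be positive, got {circumradius_um!r}")
    r_mm = circumradius_um / 1000.0
    return 1.5 * math.sqrt(3.0) * r_mm * r_mm


@dataclass(frozen=True)
class HexGridSpec:
    """Geometry of the hexagonal tiling.

    Parameters
    ----------
    circumradius : float
        Hexagon circumradius (= side length) in µm.
    orientation : {"flat_top", "pointy_top"}
        Whether hexagons have a flat or a pointed top edge.
    origin_offset : (float, float), optional
        Grid translation in µm.  ``None`` means "draw a uniformly random
        offset from ``seed``" when the tiling is built — the random grid
        placement of the sampling protocol.
    seed : int, optional
        Seed for the random placement; recorded in outputs.
    """

    circumradius: float = DEFAULT_CIRCUMRADIUS_UM
    orientation: Literal["flat_top", "pointy_top"] = "flat_top"
    origin_offset: Optional[tuple[float, float]] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.circumradius) or self.circumradius <= 0:
            raise ValueError("circumradius must be positive and finite")
        if self.orientation not in ("flat_top", "pointy_top"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.origin_offset is not None:
            ox, oy = self.origin_offset
            if not (np.isfinite(ox) and np.isfinite(oy)):
                raise ValueError("origin_offset components must be finite")
            object.__setattr__(
                self, "origin_offset", self._normalize_offset(float(ox), float(oy))
            )

    # The lattice is generated by a1 = (1.5R, √3R/2) and a2 = (0, √3R) for
    # flat-top hexes (axes swapped for pointy-top); offsets are reduced to
    # the fundamental rectangle [0, 1.5R) × [0, √3R).
    def _normalize_offset(self, ox: float, oy: float) -> tuple[float, float]:
        r = self.circumradius
        if self.orientation == "pointy_top":
            oy, ox = self._normalize_flat(oy, ox, r)
            return ox, oy
        return self._normalize_flat(ox, oy, r)

    @staticmethod
    def _normalize_flat(ox: float, oy: float, r: float) -> tuple[float, float]:
        px, py = 1.5 * r, math.sqrt(3.0) * r
        k1 = math.floor(ox / px)
        ox -= k1 * px
        oy -= k1 * py / 2.0
        oy -= math.floor(oy / py) * py
        return ox, oy

    def resolve_offset(self) -> "HexGridSpec":
        """Return a spec with a concrete origin offset.

        If ``origin_offset`` is unset, a uniform offset over one lattice
        period is drawn from ``seed`` (seed ``None`` gives the deterministic
        zero offset).
        """
        if self.origin_offset is not None:
            return self
        if self.seed is None:
            return replace(self, origin_offset=(0.0, 0.0))
        rng = np.random.default_rng(self.seed)
        r = self.circumradius
        u = rng.random(2)
        off = (u[0] * 1.5 * r, u[1] * math.sqrt(3.0) * r)
        if self.orientation == "pointy_top":
            off = (off[1], off[0])
        return replace(self, origin_offset=off)

    # --- geometry -----------------------------------------------------

    def centers(self, q: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cartesian centers (µm) of axial cells (q, r)."""
        ox, oy = self.origin_offset if self.origin_offset is not None else (0.0, 0.0)
        R = self.circumradius
        s3 = math.sqrt(3.0)
        q = np.asarray(q, dtype=float)
        r = np.asarray(r, dtype=float)
        if self.orientation == "flat_top":
            return 1.5 * R * q + ox, s3 * R * (r + q / 2.0) + oy
        return s3 * R * (q + r / 2.0) + ox, 1.5 * R * r + oy

    def fractional_axial(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ox, oy = self.origin_offset if self.origin_offset is not None else (0.0, 0.0)
        R = self.circumradius
        s3 = math.sqrt(3.0)
        dx = np.asarray(x, dtype=float) - ox
        dy = np.asarray(y, dtype=float) - oy
        if self.orientation == "flat_top":
            q = (2.0 / 3.0) * dx / R
            r = (dy / s3 - dx / 3.0) / R
        else:
            r = (2.0 / 3.0) * dy / R
            q = (dx / s3 - dy / 3.0) / R
        return q, r

    def assign(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Axial index of the hexagon containing each point.

        Cube rounding of the fractional axial coordinates, then an exact
        nearest-center check over the rounded cell and its six neighbours
        (the tiling is the Voronoi diagram of the centers).  A point
        equidistant from several centers — on a shared edge or vertex — goes
        to the lexicographically smallest (q, r), a deterministic,
        order-independent boundary rule.
        """
        qf, rf = self.fractional_axial(x, y)
        q0, r0 = _axial_round(qf, rf)
        offsets = np.array(((0, 0),) + NEIGHBOR_OFFSETS, dtype=np.int64)  # (7, 2)
        qc = q0[:, None] + offsets[:, 0]
        rc = r0[:, None] + offsets[:, 1]
        cx, cy = self.centers(qc, rc)
        d2 = (np.asarray(x, float)[:, None] - cx) ** 2 + (
            np.asarray(y, float)[:, None] - cy
        ) ** 2
        dmin = d2.min(axis=1, keepdims=True)
        tol = 1e-9 * self.circumradius**2
        tied = d2 <= dmin + tol
        # lexicographic key on (q, r); +inf where not tied
        span = np.int64(1 << 20)
        key = np.where(tied, qc * span + rc, np.iinfo(np.int64).max)
        best = np.argmin(key, axis=1)
        idx = np.arange(len(best))
        return qc[idx, best], rc[idx, best]

    def polygons(self, q: np.ndarray, r: np.ndarray) -> np.ndarray:
        """Shapely polygons of the given cells (vectorized)."""
        cx, cy = self.centers(q, r)
        start = 0.0 if self.orientation == "flat_top" else math.pi / 6.0
        ang = start + np.arange(6) * (math.pi / 3.0)
        vx = cx[:, None] + self.circumradius * np.cos(ang)
        vy = cy[:, None] + self.circumradius * np.sin(ang)
        return shapely.polygons(np.stack([vx, vy], axis=-1))


def _axial_round(qf: np.ndarray, rf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Round fractional axial coordinates to the nearest hex (cube rounding)."""
    sf = -qf - rf
    q = np.round(qf)
    r = np.round(rf)
    s = np.round(sf)
    dq = np.abs(q - qf)
    dr = np.abs(r - rf)
    ds = np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q = np.where(fix_q, -r - s, q)
    r = np.where(fix_r, -q - s, r)
    return q.astype(np.int64), r.astype(np.int64)


@dataclass
class TumorCase:
    """One case's DIA export: nuclei coordinates (µm) and marker calls.

    ``nuclei`` is a DataFrame with columns ``x``, ``y`` (float, µm) and
    ``positive`` (bool).  ``roi`` is an optional simple polygon delimiting
    the invasive tumor area; without it the convex hull of the nuclei is
    used.
    """

    case_id: str
    nuclei: pd.DataFrame
    roi: Optional[BaseGeometry] = None
    pixel_size: float = 0.5

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be nonempty")
        missing = {"x", "y", "positive"} - set(self.nuclei.columns)
        if missing:
            raise ValueError(f"nuclei table missing columns: {sorted(missing)}")
        xy = self.nuclei[["x", "y"]].to_numpy(dtype=float)
        if xy.size and not np.isfinite(xy).all():
            raise ValueError(f"case {self.case_id}: non-finite coordinates")
        if self.roi is not None and not self.roi.is_valid:
            raise ValueError(f"case {self.case_id}: ROI polygon is not simple/valid")

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)


def whole_region_li(case: TumorCase) -> float:
    """Whole-region labeling index: positives / all nuclei inside the ROI.

    This is the reference value T against which every subsampled estimate is
    judged in the error analysis.
    """
    nuc = _roi_nuclei(case)
    if len(nuc) == 0:
        raise ValueError(f"case {case.case_id}: no nuclei in ROI")
    return float(nuc["positive"].sum()) / float(len(nuc))


def _roi_nuclei(case: TumorCase) -> pd.DataFrame:
    if case.roi is None or len(case.nuclei) == 0:
        return case.nuclei
    pts = shapely.points(case.nuclei["x"].to_numpy(float),
                         case.nuclei["y"].to_numpy(float))
    keep = shapely.covers(case.roi, pts)
    return case.nuclei.loc[keep]


@dataclass
class TilingResult:
    """A case's hexagonal tiling with per-tile counts and the reference LI.

    ``tiles`` has one row per instantiated hexagon (columns
    :data:`TILE_COLUMNS`); the partition property holds: every ROI nucleus
    is counted in exactly one tile, so pooling counts over all tiles
    reproduces the whole-region LI exactly.
    """

    case_id: str
    grid: HexGridSpec
    tiles: pd.DataFrame
    T: float
    eligible: bool
    min_nuclei: int = 100
    min_informative_tiles: int = 30

    @property
    def informative(self) -> pd.DataFrame:
        return self.tiles[self.tiles["status"] == STATUS_INFORMATIVE]

    @property
    def n_informative(self) -> int:
        return int((self.tiles["status"] == STATUS_INFORMATIVE).sum())

    def pooled_li(self) -> float:
        """Sum-based LI over all tiles — equals T by conservation."""
        pos = self.tiles["n_pos"].sum()
        tot = pos + self.tiles["n_neg"].sum()
        return float(pos) / float(tot)


def build_tiling(
    case: TumorCase,
    grid: Optional[HexGridSpec] = None,
    min_nuclei: int = 100,
    min_informative_tiles: int = 30,
) -> TilingResult:
    """Tile a case with hexagons and classify every tile.

    Tiles are instantiated wherever a hexagon overlaps the region of
    interest (the case ROI, or the nuclei convex hull when none is given);
    overlapping but empty hexagons are kept with status ``missing``, tiles
    with fewer than ``min_nuclei`` profiles are ``insufficient``, the rest
    ``informative``.  The case is ``eligible`` for sampling simulations when
    at least ``min_informative_tiles`` tiles are informative.
    """
    if grid is None:
        grid = HexGridSpec()
    grid = grid.resolve_offset()
    nuc = _roi_nuclei(case)
    if len(nuc) == 0:
        raise ValueError(f"case {case.case_id}: empty nuclei set")

    x = nuc["x"].to_numpy(float)
    y = nuc["y"].to_numpy(float)
    pos = nuc["positive"].to_numpy(bool)
    q, r = grid.assign(x, y)

    counts = (
        pd.DataFrame({"q": q, "r": r, "pos": pos.astype(np.int64)})
        .groupby(["q", "r"], sort=True)
        .agg(n_pos=("pos", "sum"), n_tot=("pos", "size"))
        .reset_index()
    )
    counts["n_neg"] = counts["n_tot"] - counts["n_pos"]

    roi = case.roi if case.roi is not None else MultiPoint(np.c_[x, y]).convex_hull
    cand = _overlapping_cells(grid, roi)
    occupied = counts[["q", "r"]]
    cells = (
        pd.concat([cand, occupied], ignore_index=True)
        .drop_duplicates()
        .sort_values(["q", "r"])
        .reset_index(drop=True)
    )

    tiles = cells.merge(counts[["q", "r", "n_pos", "n_neg"]], on=["q", "r"], how="left")
    tiles[["n_pos", "n_neg"]] = tiles[["n_pos", "n_neg"]].fillna(0).astype(np.int64)
    cx, cy = grid.centers(tiles["q"].to_numpy(), tiles["r"].to_numpy())
    tiles["center_x_um"] = cx
    tiles["center_y_um"] = cy
    n_tot = tiles["n_pos"] + tiles["n_neg"]
    with np.errstate(invalid="ignore"):
        tiles["local_li"] = np.where(n_tot > 0, tiles["n_pos"] / n_tot.replace(0, 1), np.nan)
    tiles.loc[n_tot == 0, "local_li"] = np.nan
    status = np.full(len(tiles), STATUS_INFORMATIVE, dtype=object)
    status[(n_tot > 0) & (n_tot < min_nuclei)] = STATUS_INSUFFICIENT
    status[n_tot == 0] = STATUS_MISSING
    tiles["status"] = status
    tiles = tiles[list(TILE_COLUMNS)]

    total_pos = int(tiles["n_pos"].sum())
    total = int(n_tot.sum())
    T = total_pos / total
    eligible = int((tiles["status"] == STATUS_INFORMATIVE).sum()) >= min_informative_tiles
    return TilingResult(
        case_id=case.case_id,
        grid=grid,
        tiles=tiles,
        T=T,
        eligible=eligible,
        min_nuclei=min_nuclei,
        min_informative_tiles=min_informative_tiles,
    )


def _overlapping_cells(grid: HexGridSpec, roi: BaseGeometry) -> pd.DataFrame:
    """Axial indices of all grid cells whose hexagon overlaps ``roi``."""
    minx, miny, maxx, maxy = roi.bounds
    R = grid.circumradius
    corners_x = np.array([minx - R, maxx + R, minx - R, maxx + R])
    corners_y = np.array([miny - R, miny - R, maxy + R, maxy + R])
    qf, rf = grid.fractional_axial(corners_x, corners_y)
    q_lo, q_hi = int(np.floor(qf.min())) - 1, int(np.ceil(qf.max())) + 1
    r_lo, r_hi = int(np.floor(rf.min())) - 1, int(np.ceil(rf.max())) + 1
    qq, rr = np.meshgrid(
        np.arange(q_lo, q_hi + 1, dtype=np.int64),
        np.arange(r_lo, r_hi + 1, dtype=np.int64),
        indexing="ij",
    )
    qq, rr = qq.ravel(), rr.ravel()
    # cheap prefilter on centers before exact polygon intersection
    cx, cy = grid.centers(qq, rr)
    near = (
        (cx >= minx - 2 * R) & (cx <= maxx + 2 * R)
        & (cy >= miny - 2 * R) & (cy <= maxy + 2 * R)
    )
    qq, rr = qq[near], rr[near]
    polys = grid.polygons(qq, rr)
    hit = shapely.intersects(polys, roi)
    return pd.DataFrame({"q": qq[hit], "r": rr[hit]})
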