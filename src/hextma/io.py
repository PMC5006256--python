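"""Readers and writers for the CSV interchange formats.

There is no community standard for per-nucleus DIA exports, so the package
reads a documented delimited-text dialect:

nuclei CSV
    columns ``case_id, x, y, label``; coordinates in µm or pixels
    (flag-selected, pixels converted at ``pixel_size`` µm/px); labels
    accepted as ``positive``/``negative`` or ``1``/``0``.
ROI
    per-case WKT polygon strings in a CSV (``case_id, wkt``), or a GeoJSON
    FeatureCollection whose features carry a ``case_id`` property.
tiles CSV
    one row per hexagon: ``case_id, q, r, center_x_um, center_y_um, n_pos,
    n_neg, local_li, status``.

Every file written here starts with ``#``-prefixed header lines recording
the seed and a hash of the producing configuration, so any output can be
traced to the exact run that made it; readers skip those lines.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as geojson_shape

from .hexgrid import HexGridSpec, TilingResult, TumorCase

__all__ = [
    "read_nuclei",
    "write_nuclei",
    "read_roi",
    "write_tiles",
    "read_tiles",
    "write_csv",
    "read_csv",
    "config_hash",
]

_LABEL_MAP = {
    "positive": True, "negative": False,
    "pos": True, "neg": False,
    "1": True, "0": False,
    "true": True, "false": False,
}

NUCLEI_COLUMNS = ("case_id", "x", "y", "label")


class LoadReportError(ValueError):
    """Input file rejected; ``items`` lists row-level problems."""

    def __init__(self, path, items: Sequence[str]):
        self.items = list(items)
        preview = "; ".join(self.items[:10])
        more = "" if len(self.items) <= 10 else f" (+{len(self.items) - 10} more)"
        super().__init__(f"{path}: {preview}{more}")


def config_hash(params: Mapping) -> str:
    """Short stable hash of a parameter mapping, for output provenance."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:10]


def write_csv(df: pd.DataFrame, path, meta: Optional[Mapping] = None) -> Path:
    """Write a CSV with ``# key=value`` provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)
    return path


def read_csv(path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV written by :func:`write_csv`; returns (frame, meta)."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("# ") and "=" in line:
                k, _, v = line[2:].strip().partition("=")
                meta[k] = v
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)
    return df, meta


def read_nuclei(
    path,
    units: str = "um",
    pixel_size: float = 0.5,
    roi: Optional[Mapping[str, shapely.Geometry]] = None,
) -> list[TumorCase]:
    """Load per-nucleus records into one :class:`TumorCase` per case_id.

    Pixel coordinates are converted to µm at ``pixel_size`` (default
    0.5 µm/px, a 20x whole-slide scan).  Malformed labels or non-finite
    coordinates are collected into an itemized :class:`LoadReportError`
    naming the offending rows.
    """
    if units not in ("um", "px"):
        raise ValueError("units must be 'um' or 'px'")
    df = pd.read_csv(path, comment="#")
    missing = set(NUCLEI_COLUMNS) - set(df.columns)
    if missing:
        raise LoadReportError(path, [f"missing columns: {sorted(missing)}"])

    problems: list[str] = []
    labels = df["label"].astype(str).str.strip().str.lower()
    mapped = labels.map(_LABEL_MAP)
    for i in df.index[mapped.isna()]:
        problems.append(f"row {i + 2}: unrecognized label {df.at[i, 'label']!r}")
    xy = df[["x", "y"]].apply(pd.to_numeric, errors="coerce")
    bad_xy = xy.isna().any(axis=1) | ~np.isfinite(xy).all(axis=1)
    for i in df.index[bad_xy]:
        problems.append(f"row {i + 2}: non-numeric or non-finite coordinates")
    if problems:
        raise LoadReportError(path, problems)

    scale = pixel_size if units == "px" else 1.0
    out = []
    for case_id, sub in df.groupby("case_id", sort=True):
        nuclei = pd.DataFrame(
            {
                "x": xy.loc[sub.index, "x"].to_numpy(float) * scale,
                "y": xy.loc[sub.index, "y"].to_numpy(float) * scale,
                "positive": mapped.loc[sub.index].to_numpy(bool),
            }
        ).reset_index(drop=True)
        out.append(
            TumorCase(
                case_id=str(case_id),
                nuclei=nuclei,
                roi=(roi or {}).get(str(case_id)),
                pixel_size=pixel_size,
            )
        )
    if not out:
        raise LoadReportError(path, ["file contains no nuclei records"])
    return out


def write_nuclei(cases: Iterable[TumorCase], path, meta: Optional[Mapping] = None) -> Path:
    frames = []
    for c in cases:
        frames.append(
            pd.DataFrame(
                {
                    "case_id": c.case_id,
                    "x": c.nuclei["x"],
                    "y": c.nuclei["y"],
                    "label": np.where(c.nuclei["positive"], "positive", "negative"),
                }
            )
        )
    return write_csv(pd.concat(frames, ignore_index=True), path, meta)


def read_roi(path) -> dict[str, shapely.Geometry]:
    """Per-case region-of-interest polygons from WKT CSV or GeoJSON."""
    path = Path(path)
    if path.suffix.lower() in (".json", ".geojson"):
        with open(path) as fh:
            gj = json.load(fh)
        feats = gj.get("features", [gj]) if isinstance(gj, dict) else gj
        out = {}
        for f in feats:
            cid = str(f.get("properties", {}).get("case_id", ""))
            if not cid:
                raise ValueError(f"{path}: GeoJSON feature without case_id property")
            out[cid] = geojson_shape(f["geometry"])
        return out
    df = pd.read_csv(path, comment="#")
    if not {"case_id", "wkt"} <= set(df.columns):
        raise ValueError(f"{path}: ROI CSV needs columns case_id, wkt")
    return {str(r.case_id): shapely.from_wkt(r.wkt) for r in df.itertuples()}


def write_tiles(
    tilings: Iterable[TilingResult], path, meta: Optional[Mapping] = None
) -> Path:
    """Tile tables of many cases in one CSV, with grid provenance in meta."""
    tilings = list(tilings)
    frames = []
    for t in tilings:
        df = t.tiles.copy()
        df.insert(0, "case_id", t.case_id)
        frames.append(df)
    meta = dict(meta or {})
    if tilings:
        g = tilings[0].grid
        ox, oy = g.origin_offset if g.origin_offset else (0.0, 0.0)
        meta.setdefault("circumradius_um", g.circumradius)
        meta.setdefault("orientation", g.orientation)
        meta.setdefault("min_nuclei", tilings[0].min_nuclei)
        meta.setdefault("min_informative_tiles", tilings[0].min_informative_tiles)
        # per-case offsets differ when placement is randomized; record per case
        meta.setdefault(
            "grid_offsets",
            ";".join(
                f"{t.case_id}:{t.grid.origin_offset[0]:.6f},{t.grid.origin_offset[1]:.6f}"
                if t.grid.origin_offset else f"{t.case_id}:0,0"
                for t in tilings
            ),
        )
    return write_csv(pd.concat(frames, ignore_index=True), path, meta)


def read_tiles(path) -> list[TilingResult]:
    """Rebuild per-case :class:`TilingResult` objects from a tiles CSV."""
    df, meta = read_csv(path)
    radius = float(meta.get("circumradius_um", 412.5))
    orientation = meta.get("orientation", "flat_top")
    min_nuclei = int(meta.get("min_nuclei", 100))
    min_tiles = int(meta.get("min_informative_tiles", 30))
    offsets = {}
    for item in meta.get("grid_offsets", "").split(";"):
        if ":" in item:
            cid, _, xy = item.partition(":")
            ox, oy = (float(v) for v in xy.split(","))
            offsets[cid] = (ox, oy)
    out = []
    for cid, sub in df.groupby("case_id", sort=True):
        tiles = sub.drop(columns="case_id").reset_index(drop=True)
        pos = int(tiles["n_pos"].sum())
        tot = pos + int(tiles["n_neg"].sum())
        if tot == 0:
            raise ValueError(f"{path}: case {cid} has no nuclei in any tile")
        n_info = int((tiles["status"] == "informative").sum())
        grid = HexGridSpec(
            circumradius=radius,
            orientation=orientation,
            origin_offset=offsets.get(str(cid)),
        )
        out.append(
            TilingResult(
                case_id=str(cid),
                grid=grid,
                tiles=tiles,
                T=pos / tot,
                eligible=n_info >= min_tiles,
                min_nuclei=min_nuclei,
                min_informative_tiles=min_tiles,
            )
        )
    return out
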