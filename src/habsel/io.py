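"""Plain-text artifact I/O.

Rasters round-trip as ESRI ASCII grids (.asc, nodata -9999), point sets
as CSV and GeoJSON, polygons as GeoJSON, and run manifests as key-value
text with SHA-256 file hashes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .landscape import CovariateStack, RasterGrid

NODATA = -9999.0


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> Path:
    """Write a raster as an ESRI ASCII grid (rows written north-to-south)."""
    path = Path(path)
    ny, nx = grid.shape
    header = (f"ncols {nx}\nnrows {ny}\n"
              f"xllcorner {grid.origin[0]:.6f}\nyllcorner {grid.origin[1]:.6f}\n"
              f"cellsize {grid.resolution:.6f}\nNODATA_value {NODATA}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.values[::-1], fmt="%.6g")
    return path


def read_ascii_grid(path: str | Path, name: str = "") -> RasterGrid:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)[::-1].copy()
    return RasterGrid(values, resolution=header["cellsize"],
                      origin=(header["xllcorner"], header["yllcorner"]),
                      name=name or path.stem)


def write_stack(stack: CovariateStack, outdir: str | Path) -> Path:
    """Write every layer of a stack plus a plain-text manifest of files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = []
    for name, grid in stack.layers.items():
        p = write_ascii_grid(grid, outdir / f"{name}.asc")
        lines.append(f"layer {name} {p.name}")
    for (name, radius), grid in stack.scale_variants.items():
        p = write_ascii_grid(grid, outdir / f"{name}_{radius}m.asc")
        lines.append(f"scale_variant {name}@{radius} {p.name}")
    manifest = outdir / "stack_manifest.txt"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def points_to_geojson(df: pd.DataFrame, path: str | Path,
                      properties: list[str] | None = None) -> Path:
    """Write a point table (columns x, y, ...) as a GeoJSON FeatureCollection."""
    path = Path(path)
    props = properties or [c for c in df.columns if c not in ("x", "y")]
    features = [
        {"type": "Feature",
         "geometry": {"type": "Point",
                      "coordinates": [float(r["x"]), float(r["y"])]},
         "properties": {p: (r[p].item() if hasattr(r[p], "item") else r[p])
                        for p in props}}
        for _, r in df.iterrows()]
    path.write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))
    return path


def polygon_to_geojson(coords: list[tuple[float, float]], path: str | Path,
                       properties: dict | None = None) -> Path:
    path = Path(path)
    ring = [[float(x), float(y)] for x, y in coords]
    if ring[0] != ring[-1]:
        ring.append(ring[0])
    path.write_text(json.dumps({
        "type": "Feature",
        "geometry": {"type": "Polygon", "coordinates": [ring]},
        "properties": properties or {}}))
    return path


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_run_manifest(outdir: str | Path, config_text: str,
                       artifacts: list[Path]) -> Path:
    """Key-value manifest: the serialized config plus per-file SHA-256."""
    outdir = Path(outdir)
    lines = ["[config]", config_text.strip(), "", "[artifacts]"]
    for p in sorted(artifacts, key=lambda q: str(q)):
        lines.append(f"{Path(p).relative_to(outdir)} sha256={sha256_of(p)}")
    manifest = outdir / "run_manifest.txt"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
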