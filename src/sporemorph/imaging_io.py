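"""Calibrated tile-grid I/O and the object-table CSV schema.

A specimen is scanned as a rectangular grid of unstitched RGB tiles with a
known µm-per-pixel scale.  Tiles are stored as 8-bit TIFF (PNG accepted) and
named ``<sample>_r<row>_c<col>.<ext>`` with 0-based row/col.  Measured
objects are exchanged as a flat CSV whose column order follows the classic
particle-analyzer convention (shape features first, then per-channel RGB
statistics, then tile bookkeeping).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CalibratedImage", "TileGrid", "RECORD_COLUMNS",
    "scale_from_optics", "read_tile_grid", "write_tile_grid",
    "total_scanned_area", "write_records", "read_records", "write_overlay",
]

#: Column order of the object table (one row per measured object).
RECORD_COLUMNS = [
    "Indiv", "Label", "Area", "Perim.", "Major", "Minor", "Circ.", "AR",
    "Round", "Solidity",
    "Mean_r", "StdDev_r", "Mode_r", "Min_r", "Max_r",
    "Mean_g", "StdDev_g", "Mode_g", "Min_g", "Max_g",
    "Mean_b", "StdDev_b", "Mode_b", "Min_b", "Max_b",
    "X", "Y", "Index", "BScore", "Type",
]

_TILE_RE = re.compile(r"^(?P<sample>.+)_r(?P<row>\d+)_c(?P<col>\d+)\.(?P<ext>tif|tiff|png)$")


@dataclass
class CalibratedImage:
    """One RGB tile with its physical scale and grid position."""

    pixels: np.ndarray              # H x W x 3, uint8
    um_per_px: float
    tile: tuple[int, int]           # (row, col), 0-based
    sample_id: str = "sample"
    max_intensity: int = 255

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:                       # grayscale fallback
            self.pixels = np.stack([self.pixels] * 3, axis=-1)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if self.pixels.shape[0] <= 0 or self.pixels.shape[1] <= 0:
            raise ValueError("empty image")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    def grayscale(self) -> np.ndarray:
        """Unweighted RGB mean as float64 (the pipeline's grayscale mixing)."""
        return self.pixels.astype(np.float64).mean(axis=2)


@dataclass
class TileGrid:
    """Grid of tiles of one specimen; missing tiles are simply absent."""

    rows: int
    cols: int
    tiles: dict[tuple[int, int], CalibratedImage] = field(default_factory=dict)
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid dimensions must be > 0")
        ref = None
        for (r, c), img in self.tiles.items():
            if not (0 <= r < self.rows and 0 <= c < self.cols):
                raise ValueError(f"tile ({r}, {c}) outside {self.rows}x{self.cols} grid")
            if ref is None:
                ref = img
            else:
                if img.shape != ref.shape:
                    raise ValueError(
                        f"tile ({r}, {c}) has shape {img.shape}, "
                        f"expected {ref.shape}")
                if not math.isclose(img.um_per_px, ref.um_per_px):
                    raise ValueError(f"tile ({r}, {c}) has a different scale")

    @property
    def um_per_px(self) -> float:
        return next(iter(self.tiles.values())).um_per_px

    @property
    def tile_shape(self) -> tuple[int, int]:
        return next(iter(self.tiles.values())).shape

    def tile_index(self, row: int, col: int) -> int:
        """Serial tile number in row-major order (0-based)."""
        return row * self.cols + col

    def items(self):
        return sorted(self.tiles.items())


def scale_from_optics(camera_pixel_um: float, magnification: float) -> float:
    """Object-plane sampling in µm/pixel from sensor pitch and magnification.

    A 2.4 µm sensor pixel behind a 20x objective samples the object plane at
    2.4 / 20 = 0.12 µm/pixel.
    """
    if camera_pixel_um <= 0 or magnification <= 0:
        raise ValueError("camera_pixel_um and magnification must be > 0")
    return camera_pixel_um / magnification


def tile_filename(sample_id: str, row: int, col: int, ext: str = "tif") -> str:
    return f"{sample_id}_r{row}_c{col}.{ext}"


def write_tile_grid(grid: TileGrid, directory, ext: str = "tif") -> list[Path]:
    """Write every tile as 8-bit RGB TIFF (or PNG) with the grid naming scheme."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for (r, c), img in grid.items():
        path = directory / tile_filename(grid.sample_id, r, c, ext)
        try:
            if ext in ("tif", "tiff"):
                tifffile.imwrite(path, img.pixels.astype(np.uint8))
            else:
                iio.imwrite(path, img.pixels.astype(np.uint8))
        except OSError as exc:
            raise OSError(f"failed writing tile ({r}, {c}) to {path}: {exc}") from exc
        paths.append(path)
    return paths


def read_tile_grid(directory, um_per_px: float,
                   sample_id: str | None = None) -> TileGrid:
    """Read a tile grid from a directory of ``<sample>_r<row>_c<col>`` files.

    Grid dimensions are inferred from the maximum row/col index; gaps in the
    grid are recorded as absent tiles, not errors.  Tiles with inconsistent
    dimensions raise, naming the offending tile.
    """
    directory = Path(directory)
    found: dict[tuple[int, int], Path] = {}
    sid = sample_id
    for path in sorted(directory.iterdir()):
        m = _TILE_RE.match(path.name)
        if not m:
            continue
        if sid is None:
            sid = m.group("sample")
        elif m.group("sample") != sid:
            continue
        found[(int(m.group("row")), int(m.group("col")))] = path
    if not found:
        raise FileNotFoundError(f"no tiles matching '<sample>_r<row>_c<col>' in {directory}")
    rows = max(r for r, _ in found) + 1
    cols = max(c for _, c in found) + 1
    tiles: dict[tuple[int, int], CalibratedImage] = {}
    shape = None
    for (r, c), path in sorted(found.items()):
        pixels = np.asarray(iio.imread(path))
        if pixels.ndim == 2:
            pixels = np.stack([pixels] * 3, axis=-1)
        if pixels.shape[2] > 3:
            pixels = pixels[:, :, :3]
        if shape is None:
            shape = pixels.shape
        elif pixels.shape != shape:
            raise ValueError(
                f"tile ({r}, {c}) in {path.name} has shape {pixels.shape}, "
                f"expected {shape}")
        tiles[(r, c)] = CalibratedImage(pixels=pixels, um_per_px=um_per_px,
                                        tile=(r, c), sample_id=sid)
    return TileGrid(rows=rows, cols=cols, tiles=tiles, sample_id=sid)


def total_scanned_area(grid: TileGrid) -> float:
    """Total slide area covered by the grid, in mm² to 3 significant figures.

    Assumes negligible tile overlap, so the area is simply
    rows x cols x H x W x (µm/px)² / 1e6.
    """
    h, w = grid.tile_shape
    area_um2 = grid.rows * grid.cols * h * w * grid.um_per_px ** 2
    area_mm2 = area_um2 / 1e6
    if area_mm2 == 0:
        return 0.0
    ndigits = 2 - int(math.floor(math.log10(abs(area_mm2))))
    return round(area_mm2, ndigits)


# ---------------------------------------------------------------------------
# object tables
# ---------------------------------------------------------------------------

def write_records(records: pd.DataFrame, path) -> Path:
    """Write the object table with the canonical column order.

    Extra columns (centroid, diameter, reject reasons) are appended after
    the canonical ones so the file stays readable by downstream tools.
    """
    path = Path(path)
    if len(records) and records["Indiv"].nunique() > 1:
        raise ValueError("records must share one sample id (Indiv)")
    cols = [c for c in RECORD_COLUMNS if c in records.columns]
    extra = [c for c in records.columns if c not in RECORD_COLUMNS]
    out = records[cols + extra] if len(records) else pd.DataFrame(
        columns=RECORD_COLUMNS)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
    return path


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path)


def empty_records() -> pd.DataFrame:
    return pd.DataFrame(columns=RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# inspection overlays
# ---------------------------------------------------------------------------

def write_overlay(image: CalibratedImage, labelmask: np.ndarray,
                  ids: dict[int, str] | None = None, path=None) -> np.ndarray:
    """Draw object outlines and ID labels on a copy of the raw tile.

    This is the per-object audit view: every measured object can be traced
    back to its pixels.  ``ids`` maps mask labels to display strings
    (defaults to the label number).  Returns the overlay array; writes it
    when ``path`` is given.
    """
    from PIL import Image, ImageDraw
    from skimage.segmentation import find_boundaries

    labelmask = np.asarray(labelmask)
    if labelmask.shape != image.shape:
        raise ValueError(
            f"labelmask shape {labelmask.shape} does not match image {image.shape}")
    overlay = image.pixels.copy()
    if labelmask.max() > 0:
        edges = find_boundaries(labelmask, mode="inner")
        overlay[edges] = (255, 210, 0)
        pil = Image.fromarray(overlay)
        draw = ImageDraw.Draw(pil)
        for lab in np.unique(labelmask):
            if lab == 0:
                continue
            ys, xs = np.nonzero(labelmask == lab)
            text = str(ids.get(int(lab), str(lab))) if ids else str(int(lab))
            draw.text((float(xs.mean()), float(ys.mean())), text,
                      fill=(200, 30, 30))
        overlay = np.asarray(pil)
    if path is not None:
        iio.imwrite(Path(path), overlay)
    return overlay
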