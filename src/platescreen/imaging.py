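"""Montage stitching, overlapping-grid cropping, and channel handling.

A well is acquired as a 3x3 montage of equal-size 3-channel tiles.  The
tiles are stitched into one image (overlap strips averaged), then cut into a
4x4 grid of equal crops whose origins advance by a fixed stride
``floor((side - crop_size) / 3)`` per axis, so adjacent crops overlap
whenever the crop is larger than the stride.  The bottom-right grid cell is
discarded by default, leaving 15 crops per well, indexed row-major over the
kept cells.  Coordinates are row-major, 0-based, half-open everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .synthetic import CHANNEL_ROLES, ROLE_INDEX

__all__ = [
    "MontageSet",
    "CropImage",
    "CropGridSpec",
    "stitch_montage",
    "crop_grid",
    "crops_from_tiles",
    "split_channels",
    "merge_channels",
    "isolate_channel",
    "write_well_tiles",
    "read_well_tiles",
    "write_crops",
]


@dataclass
class MontageSet:
    """Nine 3-channel tiles of one well in row-major 3x3 order."""

    tiles: Sequence[np.ndarray]
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if len(self.tiles) != 9:
            raise ValueError(f"a montage has exactly 9 tiles, got {len(self.tiles)}")
        shapes = {t.shape for t in self.tiles}
        if len(shapes) != 1:
            raise ValueError(f"mismatched tile shapes: {sorted(shapes)}")
        shape = next(iter(shapes))
        if len(shape) != 3 or shape[2] != 3:
            raise ValueError(f"tiles must be HxWx3, got {shape}")
        if not 0.0 <= self.overlap_fraction < 0.5:
            raise ValueError("overlap_fraction must be in [0, 0.5)")


@dataclass
class CropImage:
    """One crop of a well with provenance and fixed channel roles."""

    pixels: np.ndarray
    plate_id: str
    well_id: str
    crop_index: int
    class_index: int = -1
    compound: str = ""
    dose: float = 0.0
    augmented: bool = False
    channel_roles: dict = field(default_factory=lambda: dict(CHANNEL_ROLES))

    def __post_init__(self) -> None:
        # 0..14 under the default discard; up to 15 when no cell is discarded
        if not 0 <= self.crop_index <= 15:
            raise ValueError(f"crop_index must be in 0..15, got {self.crop_index}")


@dataclass(frozen=True)
class CropGridSpec:
    """4x4 crop grid with a discarded cell set (default: bottom-right)."""

    crop_size: int = 256
    grid: int = 4
    discard: frozenset = frozenset({(3, 3)})

    def __post_init__(self) -> None:
        if self.crop_size < 1:
            raise ValueError("crop_size must be >= 1")
        for (r, c) in self.discard:
            if not (0 <= r < self.grid and 0 <= c < self.grid):
                raise ValueError(f"discard cell {(r, c)} outside the grid")

    @property
    def n_crops(self) -> int:
        return self.grid * self.grid - len(self.discard)


def stitch_montage(m: MontageSet) -> np.ndarray:
    """Combine the 3x3 tiles into one image, averaging overlap strips.

    With tile side t and overlap o = round(overlap_fraction * t), tile
    (r, c) is placed at origin (r*(t-o), c*(t-o)); the stitched side is
    3t - 2o per axis.
    """
    tiles = [np.asarray(t, dtype=np.float64) for t in m.tiles]
    h, w, _ = tiles[0].shape
    oy = int(round(m.overlap_fraction * h))
    ox = int(round(m.overlap_fraction * w))
    H, W = 3 * h - 2 * oy, 3 * w - 2 * ox
    acc = np.zeros((H, W, 3))
    weight = np.zeros((H, W, 1))
    for r in range(3):
        for c in range(3):
            y0, x0 = r * (h - oy), c * (w - ox)
            acc[y0:y0 + h, x0:x0 + w] += tiles[3 * r + c]
            weight[y0:y0 + h, x0:x0 + w] += 1.0
    return acc / weight


def grid_origins(side: int, spec: CropGridSpec) -> list[int]:
    """Crop origins along one axis: stride floor((side - crop)/3)."""
    if spec.crop_size > side:
        raise ValueError(f"crop_size {spec.crop_size} exceeds stitched side {side}")
    stride = (side - spec.crop_size) // (spec.grid - 1)
    return [i * stride for i in range(spec.grid)]


def crop_grid(
    stitched: np.ndarray,
    spec: CropGridSpec,
    plate_id: str = "",
    well_id: str = "",
    **provenance,
) -> list[CropImage]:
    """Cut the stitched image into the kept grid cells, row-major.

    Crop k of the default spec covers rows [oy_r, oy_r + crop) x cols
    [ox_c, ox_c + crop); the discarded bottom-right cell is skipped and
    crop_index runs 0..14 over kept cells.
    """
    H, W = stitched.shape[:2]
    ys = grid_origins(H, spec)
    xs = grid_origins(W, spec)
    crops = []
    idx = 0
    for r in range(spec.grid):
        for c in range(spec.grid):
            if (r, c) in spec.discard:
                continue
            y0, x0 = ys[r], xs[c]
            px = stitched[y0:y0 + spec.crop_size, x0:x0 + spec.crop_size]
            crops.append(
                CropImage(pixels=px.copy(), plate_id=plate_id, well_id=well_id,
                          crop_index=idx, **provenance)
            )
            idx += 1
    return crops


def crops_from_tiles(
    tiles: Sequence[np.ndarray],
    spec: CropGridSpec,
    overlap_fraction: float = 0.0,
    to_uint8: bool = True,
    **provenance,
) -> list[CropImage]:
    """Stitch one well's tiles and crop in one step.

    ``to_uint8`` converts the [0, 1] float crops to the raw 0-255 integer
    scale the preprocessing stage expects.
    """
    stitched = stitch_montage(MontageSet(tiles=list(tiles), overlap_fraction=overlap_fraction))
    crops = crop_grid(stitched, spec, **provenance)
    if to_uint8:
        for c in crops:
            c.pixels = np.clip(np.rint(c.pixels * 255.0), 0, 255).astype(np.uint8)
    return crops


def split_channels(c: CropImage) -> dict[str, np.ndarray]:
    """Separate a 3-channel crop into single-channel planes keyed by role."""
    if c.pixels.ndim != 3 or c.pixels.shape[2] != 3:
        raise ValueError(f"expected HxWx3 pixels, got shape {c.pixels.shape}")
    return {role: c.pixels[:, :, i].copy() for role, i in ROLE_INDEX.items()}


def merge_channels(planes: dict[str, np.ndarray]) -> np.ndarray:
    """Recombine role-keyed planes back into an HxWx3 array (split inverse)."""
    return np.stack([planes[role] for role in ("microglia", "neuron", "nucleus")], axis=-1)


def isolate_channel(c: CropImage, role: str) -> CropImage:
    """Copy of the crop with every channel except ``role`` zero-filled.

    This is how single-channel screening variants reuse the 3-channel
    pipeline unchanged.
    """
    if role not in ROLE_INDEX:
        raise ValueError(f"unknown channel role {role!r}")
    px = np.zeros_like(c.pixels)
    i = ROLE_INDEX[role]
    px[:, :, i] = c.pixels[:, :, i]
    out = CropImage(pixels=px, plate_id=c.plate_id, well_id=c.well_id,
                    crop_index=c.crop_index, class_index=c.class_index,
                    compound=c.compound, dose=c.dose, augmented=c.augmented)
    return out


# ---------------------------------------------------------------------------
# file I/O (TIFF tiles and crops + CSV manifests)


def _as_uint8(img: np.ndarray) -> np.ndarray:
    if img.dtype == np.uint8:
        return img
    return np.clip(np.rint(np.asarray(img, dtype=np.float64) * 255.0), 0, 255).astype(np.uint8)


def write_well_tiles(out_dir: Path, plate_id: str, well_id: str,
                     tiles: Sequence[np.ndarray]) -> list[Path]:
    """Write the 9 montage tiles as <plate>/<well>_m<r><c>.tif (r, c in 1..3)."""
    plate_dir = Path(out_dir) / plate_id
    plate_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, tile in enumerate(tiles):
        r, c = divmod(k, 3)
        p = plate_dir / f"{well_id}_m{r + 1}{c + 1}.tif"
        tifffile.imwrite(p, _as_uint8(tile))
        paths.append(p)
    return paths


def read_well_tiles(out_dir: Path, plate_id: str, well_id: str) -> list[np.ndarray]:
    """Read the 9 tiles of a well back as [0, 1] floats (16-bit rescaled by max)."""
    tiles = []
    for k in range(9):
        r, c = divmod(k, 3)
        p = Path(out_dir) / plate_id / f"{well_id}_m{r + 1}{c + 1}.tif"
        raw = tifffile.imread(p)
        denom = 255.0 if raw.dtype == np.uint8 else float(np.iinfo(raw.dtype).max)
        tiles.append(np.asarray(raw, dtype=np.float64) / denom)
    return tiles


def write_crops(out_dir: Path, crops: Sequence[CropImage]) -> pd.DataFrame:
    """Write crops as <plate>/<well>_crop<00-14>.tif and return the manifest."""
    rows = []
    for c in crops:
        plate_dir = Path(out_dir) / c.plate_id
        plate_dir.mkdir(parents=True, exist_ok=True)
        p = plate_dir / f"{c.well_id}_crop{c.crop_index:02d}.tif"
        tifffile.imwrite(p, _as_uint8(c.pixels))
        rows.append({
            "plate_id": c.plate_id, "well_id": c.well_id, "crop_index": c.crop_index,
            "path": str(p), "class_index": c.class_index,
            "compound": c.compound, "dose": c.dose,
        })
    return pd.DataFrame(rows)
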