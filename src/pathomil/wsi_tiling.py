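"""Whole-slide tissue segmentation and tile-grid extraction.

The pipeline mirrors the standard weakly-supervised WSI preprocessing recipe:
the slide is converted to HSV, the saturation channel is median-filtered
(kernel ``median_kernel``) and binarized (fixed threshold or Otsu), the mask
is morphologically closed, and artifact filters remove white background
(low saturation at high brightness) and over-stained black regions (low RGB
mean). Tiles of ``tile_size`` px are enumerated on a row-major grid at level 0
and kept when probe points around the tile center fall inside the tissue mask
(the ``four_pt`` rule).

Coordinates are 0-based, half-open ``[x, x+tile_size) × [y, y+tile_size)`` in
level-0 pixel units, row-major (y outer, x inner).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.morphology import closing, footprint_rectangle

__all__ = [
    "SlideImage",
    "SegmentationParams",
    "TissueMask",
    "TileSpec",
    "TileCoordinates",
    "NormalizationParams",
    "segment_tissue",
    "extract_tile_grid",
    "preprocess_tile",
    "read_tile",
    "save_coordinates",
    "load_coordinates",
]

#: ImageNet channel statistics, the fallback when no encoder-specific values
#: are supplied (encoders define their own normalization).
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

#: Longest mask side used for segmentation on pyramidal slides; bounds memory.
MAX_MASK_SIDE = 4096


@dataclass
class SlideImage:
    """An RGB slide held in memory, with optional pyramid metadata.

    ``pixel_data`` is the level-0 (native) image, H×W×3 uint8.
    ``microns_per_pixel`` defaults to 0.25 µm/px (40× objective).
    """

    pixel_data: np.ndarray
    level_downsamples: list[float] = field(default_factory=lambda: [1.0])
    microns_per_pixel: float = 0.25
    slide_id: str = "slide"

    def __post_init__(self):
        arr = np.asarray(self.pixel_data)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"expected H×W×3 RGB array, got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("empty slide")
        self.pixel_data = arr.astype(np.uint8, copy=False)
        if not self.level_downsamples or self.level_downsamples[0] != 1.0:
            raise ValueError("level 0 downsample must be 1.0")

    @property
    def dimensions(self) -> tuple[int, int]:
        """(width, height) at level 0."""
        return self.pixel_data.shape[1], self.pixel_data.shape[0]

    @property
    def tile_physical_size_um(self) -> float:
        """Physical edge length of a 256 px tile: 256 × 0.25 µm = 64 µm."""
        return 256 * self.microns_per_pixel

    @classmethod
    def from_file(cls, path, microns_per_pixel: float = 0.25) -> "SlideImage":
        """Read a flat RGB image (PNG/TIFF/JPEG)."""
        img = Image.open(path).convert("RGB")
        return cls(
            np.asarray(img),
            microns_per_pixel=microns_per_pixel,
            slide_id=Path(path).stem,
        )


@dataclass
class SegmentationParams:
    median_kernel: int = 7  # mthresh
    sat_threshold: int = 8  # sthresh, on the 0-255 saturation scale
    use_otsu: bool = False
    close_kernel: int = 4
    white_sat_max: int = 15  # white filter: sat below this AND bright => background
    white_value_min: int = 200
    black_rgb_mean_min: int = 50  # black filter: RGB mean below this => artifact

    def validate(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")
        for name in ("sat_threshold", "white_sat_max", "black_rgb_mean_min"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must lie in [0, 255]")
        if self.close_kernel < 0:
            raise ValueError("close_kernel must be >= 0")


@dataclass
class TissueMask:
    mask: np.ndarray  # binary, uint8
    downsample_factor: float = 1.0

    def __post_init__(self):
        self.mask = (np.asarray(self.mask) > 0).astype(np.uint8)

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class TileSpec:
    tile_size: int = 256
    stride: int = 256
    level: int = 0
    validity_rule: str = "four_pt_any"  # or "four_pt_all"
    output_size: int = 224

    def validate(self, n_levels: int = 1) -> None:
        if min(self.tile_size, self.stride, self.output_size) <= 0:
            raise ValueError("tile_size, stride and output_size must be positive")
        if self.validity_rule not in ("four_pt_any", "four_pt_all"):
            raise ValueError(f"unknown validity_rule {self.validity_rule!r}")
        if not 0 <= self.level < n_levels:
            raise ValueError(f"level {self.level} outside pyramid (0..{n_levels - 1})")


@dataclass
class TileCoordinates:
    """Kept tile top-left corners (x, y) at level 0, row-major order."""

    coords: np.ndarray  # (n, 2) int
    tile_size: int = 256
    slide_id: str = "slide"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.coords)

    def __iter__(self):
        return iter(map(tuple, self.coords))


@dataclass
class NormalizationParams:
    channel_mean: tuple[float, float, float] = IMAGENET_MEAN
    channel_std: tuple[float, float, float] = IMAGENET_STD
    interpolation: str = "bicubic"

    def validate(self) -> None:
        if any(s <= 0 for s in self.channel_std):
            raise ValueError("std components must be positive")
        if self.interpolation != "bicubic":
            raise ValueError("only bicubic interpolation is supported")


def _segmentation_level(slide: SlideImage) -> int:
    """Coarsest pyramid level whose longest side is <= MAX_MASK_SIDE.

    Flat images (single level) always segment at native resolution.
    """
    w, h = slide.dimensions
    best = 0
    for lvl, ds in enumerate(slide.level_downsamples):
        if max(w, h) / ds <= MAX_MASK_SIDE:
            return lvl
        best = lvl
    return best


def segment_tissue(
    slide: SlideImage, params: SegmentationParams | None = None
) -> TissueMask:
    """Segment tissue on the saturation channel with artifact filtering."""
    params = params or SegmentationParams()
    params.validate()
    rgb = slide.pixel_data
    ds = 1.0
    if len(slide.level_downsamples) > 1:
        lvl = _segmentation_level(slide)
        ds = slide.level_downsamples[lvl]
        if ds > 1.0:
            step = int(round(ds))
            rgb = rgb[::step, ::step]
            ds = float(step)
    if params.median_kernel > min(rgb.shape[:2]):
        raise ValueError("median kernel larger than image")

    hsv = rgb2hsv(rgb)  # float in [0, 1]
    sat = hsv[:, :, 1] * 255.0
    val = hsv[:, :, 2] * 255.0
    sat_f = ndimage.median_filter(sat, size=params.median_kernel)

    if params.use_otsu:
        thresh = threshold_otsu(sat_f)
    else:
        thresh = float(params.sat_threshold)
    mask = sat_f > thresh

    if params.close_kernel > 1:
        mask = closing(
            mask, footprint_rectangle((params.close_kernel, params.close_kernel))
        )

    # white filter: bright, unsaturated pixels are background glass
    white = (sat < params.white_sat_max) & (val >= params.white_value_min)
    # black filter: very dark pixels are pen / over-stain artifacts
    black = rgb.mean(axis=2) < params.black_rgb_mean_min
    mask = mask & ~white & ~black
    return TissueMask(mask=mask.astype(np.uint8), downsample_factor=ds)


def extract_tile_grid(
    slide: SlideImage, mask: TissueMask, spec: TileSpec | None = None
) -> TileCoordinates:
    """Enumerate the level-0 tile grid and keep tiles passing the four_pt rule.

    Four probe points are placed at ``center ± tile_size/4`` in x and y and
    mapped into mask space; ``four_pt_any`` keeps a tile when at least one
    probe hits tissue, ``four_pt_all`` when all four do.
    """
    spec = spec or TileSpec()
    spec.validate(n_levels=len(slide.level_downsamples))
    w, h = slide.dimensions
    ts, stride = spec.tile_size, spec.stride
    xs = np.arange(0, w - ts + 1, stride, dtype=np.int64)
    ys = np.arange(0, h - ts + 1, stride, dtype=np.int64)
    if len(xs) == 0 or len(ys) == 0 or mask.mask.sum() == 0:
        return TileCoordinates(
            np.empty((0, 2), dtype=np.int64), tile_size=ts, slide_id=slide.slide_id
        )
    gx, gy = np.meshgrid(xs, ys)  # row-major: y outer, x inner
    gx, gy = gx.ravel(), gy.ravel()
    cx, cy = gx + ts // 2, gy + ts // 2
    quarter = ts // 4
    m = mask.mask
    ds = mask.downsample_factor
    hits = np.zeros(len(gx), dtype=np.int64)
    for dx in (-quarter, quarter):
        for dy in (-quarter, quarter):
            px = np.clip(((cx + dx) / ds).astype(np.int64), 0, m.shape[1] - 1)
            py = np.clip(((cy + dy) / ds).astype(np.int64), 0, m.shape[0] - 1)
            hits += m[py, px]
    keep = hits >= (4 if spec.validity_rule == "four_pt_all" else 1)
    coords = np.stack([gx[keep], gy[keep]], axis=1)
    return TileCoordinates(coords, tile_size=ts, slide_id=slide.slide_id)


def read_tile(slide: SlideImage, xy: tuple[int, int], tile_size: int) -> np.ndarray:
    x, y = int(xy[0]), int(xy[1])
    return slide.pixel_data[y : y + tile_size, x : x + tile_size]


def preprocess_tile(
    tile_pixels: np.ndarray,
    norm: NormalizationParams | None = None,
    spec: TileSpec | None = None,
) -> np.ndarray:
    """Resize (bicubic) → scale to [0, 1] → per-channel standardization."""
    norm = norm or NormalizationParams()
    spec = spec or TileSpec()
    norm.validate()
    tile = np.asarray(tile_pixels)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError(f"expected H×W×3 tile, got shape {tile.shape}")
    if tile.shape[0] != spec.tile_size or tile.shape[1] != spec.tile_size:
        raise ValueError(
            f"expected {spec.tile_size}×{spec.tile_size} tile, got {tile.shape[:2]}"
        )
    out = spec.output_size
    # per-channel float resize: avoids the 8-bit quantization a uint8
    # round-trip through the resampler would introduce
    resized = np.stack(
        [
            np.asarray(
                Image.fromarray(tile[:, :, c].astype(np.float32), mode="F")
                .resize((out, out), Image.BICUBIC),
                dtype=np.float64,
            )
            for c in range(3)
        ],
        axis=2,
    )
    scaled = resized / 255.0
    mean = np.asarray(norm.channel_mean, dtype=np.float64)
    std = np.asarray(norm.channel_std, dtype=np.float64)
    return (scaled - mean) / std


def save_coordinates(coords: TileCoordinates, path, spec: TileSpec, csv_path=None):
    """Write kept-tile coordinates to an HDF5 container (and optionally CSV)."""
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("coords", data=coords.coords.astype(np.int32))
        d.attrs["tile_size"] = spec.tile_size
        d.attrs["stride"] = spec.stride
        d.attrs["level"] = spec.level
        d.attrs["slide_id"] = coords.slide_id
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x", "y"])
            writer.writerows(coords.coords.tolist())


def load_coordinates(path) -> tuple[TileCoordinates, TileSpec]:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["coords"]
        spec = TileSpec(
            tile_size=int(d.attrs["tile_size"]),
            stride=int(d.attrs["stride"]),
            level=int(d.attrs["level"]),
        )
        coords = TileCoordinates(
            d[...], tile_size=spec.tile_size, slide_id=str(d.attrs["slide_id"])
        )
    return coords, spec
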