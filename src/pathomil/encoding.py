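"""Tile encoders and per-slide feature bags.

Pretrained histopathology foundation encoders are accessed through the
:class:`EncoderContract` interface only; no weights ship with the package.
A deterministic :class:`SyntheticEncoder` (seeded random projection of
per-channel tile summary statistics) exercises the identical code paths at
desk scale. Bags persist to HDF5, one file per slide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .wsi_tiling import TileCoordinates

__all__ = [
    "EncoderContract",
    "FeatureBag",
    "SyntheticEncoder",
    "synthetic_encoder",
    "encode_slide",
    "save_bag",
    "load_bag",
]


class EncoderContract:
    """Interface every tile encoder must satisfy.

    ``encode`` maps a batch of normalized tiles (B×H×W×3 float) to B×dim
    features and must be deterministic given fixed encoder state.
    """

    name: str = "abstract"
    dim: int = 0

    def encode(self, tiles: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class SyntheticEncoder(EncoderContract):
    """Seeded linear projection of 12 per-channel tile statistics.

    For each tile, the statistics vector is (mean, std, min, max) per RGB
    channel; a fixed seeded ``dim×12`` Gaussian matrix projects it to the
    output space, so distinct tile appearances map to distinct, reproducible
    feature vectors.
    """

    def __init__(self, seed: int = 7, dim: int = 64):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.name = f"synthetic-{seed}-{dim}"
        self.dim = dim
        rng = np.random.default_rng(seed)
        self.projection = rng.standard_normal((dim, 12)) / np.sqrt(12.0)

    @staticmethod
    def tile_statistics(tiles: np.ndarray) -> np.ndarray:
        tiles = np.asarray(tiles, dtype=np.float64)
        if tiles.ndim == 3:
            tiles = tiles[None]
        flat = tiles.reshape(tiles.shape[0], -1, 3)
        stats = np.concatenate(
            [flat.mean(1), flat.std(1), flat.min(1), flat.max(1)], axis=1
        )
        return stats  # (B, 12)

    def encode(self, tiles: np.ndarray) -> np.ndarray:
        return self.tile_statistics(tiles) @ self.projection.T


def synthetic_encoder(seed: int = 7, dim: int = 64) -> SyntheticEncoder:
    return SyntheticEncoder(seed=seed, dim=dim)


@dataclass
class FeatureBag:
    """The MIL bag for one slide: N×D tile features with aligned coordinates."""

    slide_id: str
    patient_id: str
    site: str  # "primary" | "metastatic"
    features: np.ndarray
    coords: TileCoordinates
    encoder_name: str = "unknown"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float32)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("features must be a non-empty N×D matrix")
        if len(self.coords) != self.features.shape[0]:
            raise ValueError(
                f"features ({self.features.shape[0]}) and coords "
                f"({len(self.coords)}) must align row-for-row"
            )
        if not np.isfinite(self.features).all():
            raise ValueError("features contain non-finite values")
        if self.site not in ("primary", "metastatic"):
            raise ValueError(f"unknown site {self.site!r}")

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


def encode_slide(
    tiles,
    coords: TileCoordinates,
    encoder: EncoderContract,
    slide_id: str,
    patient_id: str,
    site: str = "primary",
) -> FeatureBag:
    """Encode each tile in order; row i of the bag is encoder(tiles[i])."""
    tiles = np.asarray(tiles, dtype=np.float64)
    if tiles.ndim == 3:
        tiles = tiles[None]
    if len(tiles) == 0:
        raise ValueError("cannot encode an empty tile list")
    if len(tiles) != len(coords):
        raise ValueError("tiles and coords must have equal length")
    features = np.asarray(encoder.encode(tiles))
    if features.shape != (len(tiles), encoder.dim):
        raise ValueError(
            f"encoder {encoder.name!r} returned shape {features.shape}, "
            f"expected ({len(tiles)}, {encoder.dim})"
        )
    return FeatureBag(
        slide_id=slide_id,
        patient_id=patient_id,
        site=site,
        features=features,
        coords=coords,
        encoder_name=encoder.name,
    )


def save_bag(bag: FeatureBag, store_path) -> None:
    with h5py.File(store_path, "w") as f:
        f.create_dataset("features", data=bag.features.astype(np.float32))
        f.create_dataset("coords", data=bag.coords.coords.astype(np.int32))
        f.attrs["slide_id"] = bag.slide_id
        f.attrs["patient_id"] = bag.patient_id
        f.attrs["site"] = bag.site
        f.attrs["encoder_name"] = bag.encoder_name
        f.attrs["tile_size"] = bag.coords.tile_size


def load_bag(store_path) -> FeatureBag:
    with h5py.File(store_path, "r") as f:
        if "features" not in f or "coords" not in f:
            raise ValueError(f"{store_path}: missing features/coords datasets")
        features = f["features"][...]
        coords = f["coords"][...]
        if features.shape[0] != coords.shape[0]:
            raise ValueError(
                f"{store_path}: features/coords length mismatch "
                f"({features.shape[0]} vs {coords.shape[0]})"
            )
        return FeatureBag(
            slide_id=str(f.attrs["slide_id"]),
            patient_id=str(f.attrs["patient_id"]),
            site=str(f.attrs["site"]),
            features=features,
            coords=TileCoordinates(
                coords,
                tile_size=int(f.attrs["tile_size"]),
                slide_id=str(f.attrs["slide_id"]),
            ),
            encoder_name=str(f.attrs["encoder_name"]),
        )
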