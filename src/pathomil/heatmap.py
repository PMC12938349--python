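"""Attention heatmap rendering.

Per-slide attention weights are min–max normalized to [0, 1], mapped through
a perceptually uniform colormap and alpha-blended over the (optionally
downsampled) slide inside each kept tile's footprint; pixels outside kept
tiles are left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

from .model import AttentionWeights
from .wsi_tiling import SlideImage, TileCoordinates

__all__ = ["HeatmapRendering", "render_heatmap"]


@dataclass
class HeatmapRendering:
    downsample: int = 1
    colormap: str = "viridis"
    overlay_alpha: float = 0.5

    def __post_init__(self):
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")
        if not 0.0 <= self.overlay_alpha <= 1.0:
            raise ValueError("overlay_alpha must lie in [0, 1]")


def render_heatmap(
    alpha: AttentionWeights | np.ndarray,
    coords: TileCoordinates,
    slide: SlideImage | np.ndarray,
    rendering: HeatmapRendering | None = None,
) -> np.ndarray:
    """Overlay attention onto the slide; returns an RGB uint8 image."""
    rendering = rendering or HeatmapRendering()
    a = alpha.alpha if isinstance(alpha, AttentionWeights) else np.asarray(alpha)
    a = np.asarray(a, dtype=np.float64).ravel()
    if len(a) != len(coords):
        raise ValueError("attention weights and coords must align")
    base = slide.pixel_data if isinstance(slide, SlideImage) else np.asarray(slide)
    h, w = base.shape[:2]
    ts = coords.tile_size
    for x, y in coords:
        if x < 0 or y < 0 or x + ts > w or y + ts > h:
            raise ValueError(f"tile ({x}, {y}) outside slide bounds {w}×{h}")
    span = a.max() - a.min()
    norm = (a - a.min()) / span if span > 0 else np.zeros_like(a)
    cmap = colormaps[rendering.colormap]
    ds = rendering.downsample
    canvas = base[::ds, ::ds].astype(np.float64).copy()
    blend = rendering.overlay_alpha
    for (x, y), v in zip(coords, norm):
        color = np.array(cmap(float(v))[:3]) * 255.0
        x0, y0 = x // ds, y // ds
        x1, y1 = (x + ts + ds - 1) // ds, (y + ts + ds - 1) // ds
        patch = canvas[y0:y1, x0:x1]
        canvas[y0:y1, x0:x1] = (1 - blend) * patch + blend * color
    return np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
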