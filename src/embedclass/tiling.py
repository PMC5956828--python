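"""Tiling, lesional gating, tile-budget sampling and CAM reassembly.

A slide is cut into a non-overlapping grid of fixed-size tiles (partial edge
tiles dropped — the classifier expects fixed-size input). Tiles are then
gated on lesional probability, at most a fixed budget is sampled, and a
minimum-tile rule decides whether the slide is classified at all. Class
activation maps are rendered by painting each tile's footprint with its
class color.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._types import OUTLIER, GateResult, GateStatus, TileGeometry, TileRecord

__all__ = [
    "tile_image",
    "gate_lesional",
    "sample_tiles",
    "check_min_tiles",
    "render_cam",
    "default_palette",
]

#: Number of top-scoring lesional tiles handed to the pathologist when a
#: slide fails the minimum-tile rule.
N_REVIEW_TILES = 5


def tile_image(image: np.ndarray, tile_size: int) -> list[TileGeometry]:
    """Grid an image into full, non-overlapping tiles in row-major order.

    Pixel bounds are half-open ``[r*s, (r+1)*s)``; remainders at the right
    and bottom edges are dropped. An image smaller than one tile in either
    dimension yields an empty list and a warning.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    h, w = image.shape[:2]
    if h < 1 or w < 1:
        raise ValueError("image must be at least 1x1")
    n_rows, n_cols = h // tile_size, w // tile_size
    if n_rows == 0 or n_cols == 0:
        warnings.warn(
            f"image {w}x{h} is smaller than tile_size {tile_size}; no tiles produced",
            stacklevel=2,
        )
        return []
    return [
        TileGeometry(
            row=r,
            col=c,
            y0=r * tile_size,
            x0=c * tile_size,
            y1=(r + 1) * tile_size,
            x1=(c + 1) * tile_size,
        )
        for r in range(n_rows)
        for c in range(n_cols)
    ]


def gate_lesional(tiles: list[TileRecord], lesional_threshold: float) -> list[TileRecord]:
    """Keep tiles with ``p_lesional`` strictly greater than the threshold."""
    return [t for t in tiles if t.p_lesional > lesional_threshold]


def sample_tiles(
    lesional: list[TileRecord], max_tiles_per_slide: int, seed: int
) -> list[TileRecord]:
    """Sample up to the per-slide budget, uniformly without replacement.

    If the input fits the budget it is returned unchanged; otherwise exactly
    ``max_tiles_per_slide`` tiles are drawn (seed-determined) and returned in
    their original order.
    """
    if max_tiles_per_slide < 1:
        raise ValueError("max_tiles_per_slide must be >= 1")
    if len(lesional) <= max_tiles_per_slide:
        return list(lesional)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(lesional), size=max_tiles_per_slide, replace=False))
    return [lesional[i] for i in idx]


def check_min_tiles(sampled: list[TileRecord], min_lesional_tiles: int) -> GateResult:
    """Minimum-lesional-tile rule: PROCEED iff the count reaches the minimum.

    A failing slide is not classified; the result carries up to
    :data:`N_REVIEW_TILES` of its highest-``p_lesional`` tiles for manual
    review instead.
    """
    n = len(sampled)
    if n >= min_lesional_tiles:
        return GateResult(status=GateStatus.PROCEED, n_tiles=n)
    review = sorted(sampled, key=lambda t: (-t.p_lesional, t.tile_id))[:N_REVIEW_TILES]
    return GateResult(
        status=GateStatus.INSUFFICIENT_LESIONAL, n_tiles=n, review_tiles=review
    )


def default_palette(labels: list[str]) -> dict[str, tuple[int, int, int]]:
    """Deterministic class -> RGB palette (tab20), OUTLIER in gray."""
    from matplotlib import colormaps

    cmap = colormaps["tab20"]
    palette = {
        lab: tuple(int(round(255 * v)) for v in cmap(i % 20)[:3])
        for i, lab in enumerate(labels)
    }
    palette.setdefault(OUTLIER, (80, 80, 80))
    return palette


def render_cam(
    geometries: list[TileGeometry],
    calls: dict[tuple[int, int], str],
    palette: dict[str, tuple[int, int, int]],
    image_shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Reassemble classified tiles into a class-activation overlay.

    ``calls`` maps ``(row, col)`` to a class label (or OUTLIER); geometries
    without a call are left black (ungated). Returns the RGB overlay and the
    per-class area fractions over called tiles (summing to 1).
    """
    if image_shape is None:
        if not geometries:
            return np.zeros((0, 0, 3), dtype=np.uint8), pd.DataFrame(columns=["class", "fraction"])
        image_shape = (max(g.y1 for g in geometries), max(g.x1 for g in geometries))
    h, w = image_shape
    canvas = np.zeros((h, w, 3), dtype=np.uint8)
    counts: dict[str, int] = {}
    for g in geometries:
        if g.y1 > h or g.x1 > w or g.y0 < 0 or g.x0 < 0:
            raise ValueError(f"tile ({g.row},{g.col}) footprint exceeds image bounds {w}x{h}")
        call = calls.get((g.row, g.col))
        if call is None:
            continue
        if call not in palette:
            raise ValueError(f"no palette color for class {call!r}")
        canvas[g.y0 : g.y1, g.x0 : g.x1] = palette[call]
        counts[call] = counts.get(call, 0) + 1
    total = sum(counts.values())
    fractions = pd.DataFrame(
        [(k, counts[k] / total) for k in sorted(counts)] if total else [],
        columns=["class", "fraction"],
    )
    return canvas, fractions
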