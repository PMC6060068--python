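"""Single-hologram inference: run the network on a back-propagated field."""

from __future__ import annotations

import numpy as np

from ..optics import ComplexField
from .data import stitch_tiles
from .model import MultiScaleNet
from .train import from_channels, to_channels

__all__ = ["infer"]


def infer(
    model: MultiScaleNet,
    field: ComplexField,
    reference_amplitude: float = 1.0,
    max_tile: int | None = None,
    tile_overlap: int = 16,
    batch_size: int = 8,
) -> ComplexField:
    """Reconstruct a twin-image-free complex field from a back-propagated
    single-hologram field.

    The input is normalized by ``reference_amplitude`` (background ~ 1 + 0i,
    matching training), padded by reflection to a size the multi-scale model
    accepts, tiled with feather-blended stitching when larger than
    ``max_tile``, and denormalized on output. Output size equals input size.
    """
    if reference_amplitude <= 0:
        raise ValueError("reference_amplitude must be > 0")
    values = field.values / reference_amplitude
    h, w = values.shape
    div = 2 ** (model.config.n_scales - 1)

    if max_tile is not None and (h > max_tile or w > max_tile):
        out = _tiled_infer(model, values, max_tile, tile_overlap, div, batch_size)
    else:
        out = _run_padded(model, values[None], div)[0]

    if not np.all(np.isfinite(out)):
        raise RuntimeError("inference produced non-finite values")
    return ComplexField(values=out * reference_amplitude, config=field.config, z=field.z)


def _run_padded(model: MultiScaleNet, values: np.ndarray, div: int) -> np.ndarray:
    """Run a batch of complex (N, H, W) tiles, reflect-padding to a valid size."""
    n, h, w = values.shape
    ph = (-h) % div
    pw = (-w) % div
    x = np.stack([to_channels(v) for v in values])
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
    y = model(x)
    y = y[:, :, :h, :w]
    return np.stack([from_channels(c) for c in y])


def _tiled_infer(model, values, max_tile, overlap, div, batch_size):
    h, w = values.shape
    rows = _tile_starts(h, max_tile, overlap)
    cols = _tile_starts(w, max_tile, overlap)
    tiles, positions = [], []
    for r in rows:
        for c in cols:
            tiles.append(values[r : r + max_tile, c : c + max_tile])
            positions.append((r, c))
    outs = []
    for k in range(0, len(tiles), batch_size):
        batch = np.stack(tiles[k : k + batch_size])
        outs.extend(_run_padded(model, batch, div))
    return stitch_tiles(outs, positions, (h, w), overlap)


def _tile_starts(extent: int, size: int, overlap: int) -> list[int]:
    if size >= extent:
        return [0]
    stride = size - overlap
    if stride <= 0:
        raise ValueError("tile overlap must be smaller than the tile size")
    starts = list(range(0, extent - size, stride))
    starts.append(extent - size)
    return sorted(set(starts))
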