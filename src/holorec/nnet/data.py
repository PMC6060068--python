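"""Dataset tiling, splitting and stitching for network training.

Full field-of-view (FOV) complex image pairs — (back-propagated single
hologram, gold-standard reconstruction) — are divided into a g x g grid of
sub-tiles with a fixed overlap per dimension (defaults: 5 x 5 grid, 400-px
overlap), then assigned to train/validation/test splits with default
fractions (2/3, 1/6, 1/6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("holorec.nnet")

__all__ = [
    "TilePairSet",
    "tile_dataset",
    "split_dataset",
    "stitch_tiles",
    "DEFAULT_GRID",
    "DEFAULT_OVERLAP",
    "DEFAULT_FRACTIONS",
]

DEFAULT_GRID = 5
DEFAULT_OVERLAP = 400
DEFAULT_FRACTIONS = (2.0 / 3.0, 1.0 / 6.0, 1.0 / 6.0)

SPLITS = ("train", "validation", "test")


@dataclass
class TilePairSet:
    """Paired (network input, target) complex tiles with split assignment."""

    inputs: list
    targets: list
    fov_ids: list
    positions: list  # (row0, col0) of each tile in its FOV
    grid: int
    overlap: int
    split: list = field(default_factory=list)  # per-tile label or None

    def __post_init__(self) -> None:
        n = len(self.inputs)
        if not (len(self.targets) == len(self.fov_ids) == len(self.positions) == n):
            raise ValueError("inconsistent tile pair bookkeeping")
        for a, b in zip(self.inputs, self.targets):
            if a.shape != b.shape:
                raise ValueError("input and target tiles must be congruent")
        if not self.split:
            self.split = [None] * n

    def __len__(self) -> int:
        return len(self.inputs)

    def indices(self, split: str) -> list[int]:
        return [i for i, s in enumerate(self.split) if s == split]


def _tile_geometry(width: int, grid: int, overlap: int) -> tuple[int, int]:
    """Largest usable extent and tile size for a grid/overlap tiling."""
    # tile size s satisfies g*s - (g-1)*overlap = W  =>  s = (W + (g-1)*ov) / g
    usable = width
    while (usable + (grid - 1) * overlap) % grid != 0:
        usable -= 1
    s = (usable + (grid - 1) * overlap) // grid
    if s <= overlap:
        raise ValueError(
            f"overlap {overlap} >= tile size {s} for width {width}, grid {grid}"
        )
    return usable, s


def tile_dataset(
    full_pairs: list[tuple[np.ndarray, np.ndarray]],
    grid: int = DEFAULT_GRID,
    overlap: int = DEFAULT_OVERLAP,
) -> TilePairSet:
    """Divide FOV-sized complex pairs into a ``grid x grid`` set of sub-tiles
    overlapping by ``overlap`` pixels in each dimension.

    FOVs whose size is incompatible with the geometry are symmetrically
    cropped to the largest compatible size (logged). Tiles are ordered
    row-major within each FOV.
    """
    if grid < 1 or overlap < 0:
        raise ValueError("grid must be >= 1 and overlap >= 0")
    inputs, targets, fov_ids, positions = [], [], [], []
    for fov_id, (inp, tgt) in enumerate(full_pairs):
        inp = np.asarray(inp)
        tgt = np.asarray(tgt)
        if inp.shape != tgt.shape or inp.ndim != 2:
            raise ValueError(f"FOV {fov_id}: pair must be two congruent 2-D images")
        h, w = inp.shape
        uh, sh = _tile_geometry(h, grid, overlap)
        uw, sw = _tile_geometry(w, grid, overlap)
        if (uh, uw) != (h, w):
            logger.info(
                "FOV %d cropped from %s to (%d, %d) for tiling", fov_id, inp.shape, uh, uw
            )
            r0, c0 = (h - uh) // 2, (w - uw) // 2
            inp = inp[r0 : r0 + uh, c0 : c0 + uw]
            tgt = tgt[r0 : r0 + uh, c0 : c0 + uw]
        stride_h, stride_w = sh - overlap, sw - overlap
        for i in range(grid):
            for j in range(grid):
                r, c = i * stride_h, j * stride_w
                inputs.append(inp[r : r + sh, c : c + sw])
                targets.append(tgt[r : r + sh, c : c + sw])
                fov_ids.append(fov_id)
                positions.append((r, c))
    return TilePairSet(
        inputs=inputs,
        targets=targets,
        fov_ids=fov_ids,
        positions=positions,
        grid=grid,
        overlap=overlap,
    )


def split_dataset(
    tiles: TilePairSet,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> TilePairSet:
    """Assign train/validation/test splits in place (and return the set).

    Validation and test counts are ``round(fraction * N)``; the remainder
    goes to training. Assignment interleaves FOVs (seeded within-FOV order)
    and deals splits proportionally, so every FOV contributes to each split
    where counts permit.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(tiles)
    if n < 3:
        raise ValueError("need at least 3 tiles to split")
    n_val = round(fractions[1] * n)
    n_test = round(fractions[2] * n)
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("degenerate split counts")

    rng = np.random.default_rng(seed)
    by_fov: dict = {}
    for idx, fid in enumerate(tiles.fov_ids):
        by_fov.setdefault(fid, []).append(idx)
    for fid in by_fov:
        rng.shuffle(by_fov[fid])
    # round-robin over FOVs (order reshuffled each round so the assignment
    # pattern cannot alias with the FOV count) -> FOV-stratified order
    order = []
    queues = list(by_fov.values())
    while any(queues):
        live = [q for q in queues if q]
        for qi in rng.permutation(len(live)):
            order.append(live[qi].pop(0))

    remaining = {"train": n_train, "validation": n_val, "test": n_test}
    acc = {s: 0.0 for s in SPLITS}
    labels: list = [None] * n
    for idx in order:
        for s in SPLITS:
            acc[s] += remaining[s]
        # largest-accumulator scheduling with exact quotas
        choice = max((s for s in SPLITS if remaining[s] > 0), key=lambda s: acc[s])
        acc[choice] -= sum(remaining.values())
        remaining[choice] -= 1
        labels[idx] = choice
    tiles.split = labels
    return tiles


def stitch_tiles(
    tiles: list[np.ndarray],
    positions: list[tuple[int, int]],
    shape: tuple[int, int],
    overlap: int,
) -> np.ndarray:
    """Blend overlapping tiles back into a full image with linear feathering.

    Feathering ramps are complementary across shared overlaps (a separable
    partition of unity), so stitching unmodified tiles reproduces the
    original image exactly.
    """
    out = np.zeros(shape, dtype=np.result_type(*[t.dtype for t in tiles]))
    wsum = np.zeros(shape)
    for tile, (r0, c0) in zip(tiles, positions):
        th, tw = tile.shape
        wy = _ramp(th, overlap, r0 > 0, r0 + th < shape[0])
        wx = _ramp(tw, overlap, c0 > 0, c0 + tw < shape[1])
        w = wy[:, None] * wx[None, :]
        out[r0 : r0 + th, c0 : c0 + tw] += w * tile
        wsum[r0 : r0 + th, c0 : c0 + tw] += w
    if np.any(wsum == 0):
        raise ValueError("tiles do not cover the full image")
    return out / wsum


def _ramp(size: int, overlap: int, ramp_head: bool, ramp_tail: bool) -> np.ndarray:
    w = np.ones(size)
    if overlap > 0:
        up = np.arange(1, overlap + 1) / (overlap + 1.0)
        if ramp_head:
            w[:overlap] = np.minimum(w[:overlap], up)
        if ramp_tail:
            w[-overlap:] = np.minimum(w[-overlap:], up[::-1])
    return w
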