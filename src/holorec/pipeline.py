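"""End-to-end helpers wiring simulation, recovery and network training together."""

from __future__ import annotations

import numpy as np

from .classical import MultiHeightParams, recover_subset
from .nnet.data import TilePairSet, split_dataset, tile_dataset
from .optics import ComplexField, OpticalConfig, back_propagate, simulate_hologram
from .phantom import DEFAULT_BASE_Z, Phantom, generate_phantom, generate_stack

__all__ = ["simulate_pair", "make_training_set"]


def simulate_pair(
    phantom: Phantom,
    z: float = DEFAULT_BASE_Z,
    reference_amplitude: float = 1.0,
    target: str = "truth",
    n_iterations: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Produce one (network input, gold standard) complex image pair.

    The input is the free-space back-propagation of a single hologram at
    ``z`` (normalized to a unit reference). The target is the ground-truth
    transmittance (``target="truth"``) or the 8-height classical
    reconstruction (``target="classical"``).
    """
    scattered = ComplexField(
        values=reference_amplitude * phantom.scattered, config=phantom.config, z=0.0
    )
    holo = simulate_hologram(scattered, reference_amplitude, z)
    inp = back_propagate(holo, z, reference_amplitude).values / reference_amplitude

    if target == "truth":
        tgt = phantom.transmittance
    elif target == "classical":
        heights = tuple(z + off for off in (0, 15, 30, 45, 60, 75, 90, 180))
        stack = generate_stack(phantom, heights, reference_amplitude)
        params = MultiHeightParams(n_iterations=n_iterations)
        tgt = recover_subset(stack, len(heights), params, phantom.config).values
    else:
        raise ValueError(f"unknown target {target!r}")
    return inp, tgt


def make_training_set(
    n_fovs: int,
    sample_type: str = "tissue",
    grid_size: int = 64,
    seed: int = 0,
    config: OpticalConfig | None = None,
    z: float = DEFAULT_BASE_Z,
    target_rms_ratio: float = 0.28,
    target: str = "truth",
    grid: int = 1,
    overlap: int = 0,
    fractions: tuple[float, float, float] = (2.0 / 3.0, 1.0 / 6.0, 1.0 / 6.0),
) -> tuple[TilePairSet, list[Phantom]]:
    """Simulate ``n_fovs`` phantoms, tile their image pairs and assign splits.

    With the default ``grid=1`` each FOV contributes a single tile pair
    (suitable for small training grids); larger grids exercise the full
    overlapped tiling path.
    """
    cfg = config or OpticalConfig()
    phantoms = [
        generate_phantom(sample_type, grid_size, seed=seed + i, target_rms_ratio=target_rms_ratio, config=cfg)
        for i in range(n_fovs)
    ]
    pairs = [simulate_pair(p, z=z, target=target) for p in phantoms]
    tiles = tile_dataset(pairs, grid=grid, overlap=overlap)
    split_dataset(tiles, fractions=fractions, seed=seed)
    return tiles, phantoms
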