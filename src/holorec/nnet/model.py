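"""Multi-scale residual convolutional network for complex-field restoration.

The network maps a 2-channel (real/imaginary) tile to a 2-channel tile of
the same size. Parallel branches process the input at successively pooled
resolutions through stacks of residual blocks, are upsampled back to full
resolution and summed; a merge head produces a correction that is added to
the input (global residual connection), so an untrained network is the
identity map.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .core import (
    Adam,
    AvgPool2,
    Conv2d,
    Parameter,
    ReLU,
    ResidualBlock,
    Sequential,
    Upsample2,
)

__all__ = ["NetworkConfig", "PRESETS", "MultiScaleNet", "build_network"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``feature_maps=16`` is the sample-type-specific preset; ``32`` is the
    universal preset (one network for all specimen classes).
    """

    feature_maps: int = 16
    n_residual_blocks: int = 4
    n_scales: int = 3
    channels: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_maps < 1 or self.n_residual_blocks < 0:
            raise ValueError("feature_maps must be >= 1, n_residual_blocks >= 0")
        if self.n_scales < 2:
            raise ValueError("need >= 2 parallel scales")
        if self.channels != 2:
            raise ValueError("network operates on 2 channels (real, imaginary)")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        return cls(**json.loads(text))


PRESETS = {
    "sample-type-specific": NetworkConfig(feature_maps=16),
    "universal": NetworkConfig(feature_maps=32),
}


class MultiScaleNet:
    """Parallel multi-scale residual network with a global input skip."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f, c = config.feature_maps, config.channels

        self.branches: list[Sequential] = []
        for s in range(config.n_scales):
            layers: list = [AvgPool2() for _ in range(s)]
            layers += [Conv2d(c, f, 3, rng), ReLU()]
            layers += [ResidualBlock(f, rng) for _ in range(config.n_residual_blocks)]
            for _ in range(s):
                layers += [Upsample2(), Conv2d(f, f, 3, rng), ReLU()]
            self.branches.append(Sequential(*layers))

        # zero-initialized output conv: the untrained network is the identity
        self.merge = Sequential(
            Conv2d(f, f, 3, rng), ReLU(), Conv2d(f, c, 3, rng=rng, zero_init=True)
        )

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[Parameter]:
        params = [p for b in self.branches for p in b.parameters()]
        return params + self.merge.parameters()

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state length does not match parameter count")
        for p, v in zip(params, state):
            if p.value.shape != v.shape:
                raise ValueError("state shape mismatch")
            p.value[...] = v

    # -- forward / backward --------------------------------------------------

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != self.config.channels:
            raise ValueError(
                f"expected (N, {self.config.channels}, H, W) input, got {x.shape}"
            )
        div = 2 ** (self.config.n_scales - 1)
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"spatial size {x.shape[2:]} must be divisible by {div}"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._check_input(x)
        branch_sum = None
        for b in self.branches:
            y = b(x)
            branch_sum = y if branch_sum is None else branch_sum + y
        return x + self.merge(branch_sum)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dsum = self.merge.backward(dy)
        dx = dy.copy()
        for b in self.branches:
            dx += b.backward(dsum)
        return dx

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    # -- persistence ----------------------------------------------------------

    def save(self, path: str) -> None:
        """Write parameters as an .npz checkpoint with a JSON sidecar config."""
        arrays = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        np.savez(path, **arrays)
        sidecar = str(path)
        sidecar = sidecar if sidecar.endswith(".npz") else sidecar + ".npz"
        with open(sidecar + ".json", "w") as fh:
            fh.write(self.config.to_json())

    @classmethod
    def load(cls, path: str) -> "MultiScaleNet":
        p = str(path)
        p = p if p.endswith(".npz") else p + ".npz"
        with open(p + ".json") as fh:
            config = NetworkConfig.from_json(fh.read())
        model = cls(config)
        with np.load(p) as data:
            model.set_state([data[f"p{i}"] for i in range(len(model.parameters()))])
        return model


def build_network(config: NetworkConfig) -> MultiScaleNet:
    """Construct a seeded :class:`MultiScaleNet` from a config."""
    return MultiScaleNet(config)
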