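"""Seeded synthetic specimens and multi-height hologram stacks.

Generates dense, strongly scattering transmissive phantoms (schematic blood
smears, Pap smears, tissue texture and calibration discs) whose
scattered-wave RMS modulus is calibrated to a configurable fraction of the
reference wave, then simulates hologram stacks at the standard eight
relative heights ``{0, 15, 30, 45, 60, 75, 90, 180}`` um above a base
sample-to-sensor distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .optics import (
    ComplexField,
    IntensityImage,
    OpticalConfig,
    back_propagate,
    simulate_hologram,
)

__all__ = [
    "SAMPLE_TYPES",
    "DEFAULT_HEIGHT_OFFSETS",
    "DEFAULT_BASE_Z",
    "DEFAULT_PHOTONS",
    "Phantom",
    "HologramStack",
    "generate_phantom",
    "measure_rms_ratio",
    "generate_stack",
    "default_heights",
    "twin_energy",
]

SAMPLE_TYPES = ("blood_smear", "pap_smear", "tissue", "discs")

#: Relative sensor heights (um) of the eight-hologram acquisition protocol.
DEFAULT_HEIGHT_OFFSETS = (0.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0, 180.0)

#: Default base sample-to-sensor distance (um), < 1 mm.
DEFAULT_BASE_Z = 300.0

#: Default photon budget per pixel for shot noise.
DEFAULT_PHOTONS = 10_000.0


@dataclass(frozen=True)
class Phantom:
    """Ground-truth complex transmittance of a synthetic specimen.

    ``transmittance`` is the total field under unit illumination;
    ``scattered`` is ``transmittance - 1``. ``labels`` is an integer
    segmentation grid (0 = background) for cell-wise metrology.
    """

    transmittance: np.ndarray
    scattered: np.ndarray
    sample_type: str
    seed: int
    config: OpticalConfig
    labels: np.ndarray | None = None
    target_rms_ratio: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.transmittance, dtype=np.complex128)
        s = np.asarray(self.scattered, dtype=np.complex128)
        if t.shape != s.shape:
            raise ValueError("transmittance and scattered grids must match")
        if not np.allclose(s, t - 1.0, atol=1e-12):
            raise ValueError("scattered must equal transmittance - 1")
        if np.any(np.abs(t) > 1.0 + 1e-6):
            raise ValueError("|transmittance| must not exceed 1 (passive specimen)")
        object.__setattr__(self, "transmittance", t)
        object.__setattr__(self, "scattered", s)

    @property
    def shape(self) -> tuple[int, int]:
        return self.transmittance.shape


@dataclass(frozen=True)
class HologramStack:
    """Ordered multi-height hologram intensities with strictly increasing z."""

    images: tuple[IntensityImage, ...]
    heights: tuple[float, ...]
    noise_model: str = "none"
    noise_param: float | None = None
    reference_amplitude: float = 1.0

    def __post_init__(self) -> None:
        images = tuple(self.images)
        heights = tuple(float(h) for h in self.heights)
        if len(images) != len(heights) or len(images) < 1:
            raise ValueError("need the same nonzero number of images and heights")
        if any(b <= a for a, b in zip(heights, heights[1:])):
            raise ValueError("heights must be strictly increasing")
        if self.noise_model not in ("none", "shot", "gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        object.__setattr__(self, "images", images)
        object.__setattr__(self, "heights", heights)

    def __len__(self) -> int:
        return len(self.images)


def default_heights(base_z: float = DEFAULT_BASE_Z) -> tuple[float, ...]:
    """Absolute sensor heights of the 8-position protocol (um)."""
    return tuple(base_z + off for off in DEFAULT_HEIGHT_OFFSETS)


# ----------------------------------------------------------------------
# texture models (schematic; only the RMS scattering ratio is calibrated)
# ----------------------------------------------------------------------


def _soft_disc(shape, cy, cx, ry, rx, theta, edge=1.0):
    ny, nx = shape
    y = np.arange(ny)[:, None] - cy
    x = np.arange(nx)[None, :] - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (x * ct + y * st) / rx
    v = (-x * st + y * ct) / ry
    r = np.sqrt(u**2 + v**2)
    scale = min(rx, ry)
    return np.clip((1.0 - r) * scale / edge + 0.5, 0.0, 1.0)


def _blood_smear(n: int, rng: np.random.Generator):
    """Dense field of small round cells with a central phase dip."""
    phase = np.zeros((n, n))
    absorb = np.zeros((n, n))
    labels = np.zeros((n, n), dtype=np.int32)
    n_cells = max(4, int(0.0012 * n * n))
    cid = 0
    for _ in range(n_cells):
        r = rng.uniform(3.0, 5.5)
        cy, cx = rng.uniform(r, n - r, size=2)
        mask = _soft_disc((n, n), cy, cx, r, r, 0.0, edge=1.2)
        phi0 = rng.uniform(0.8, 1.6)
        # biconcave-like profile: rim higher than the centre
        dip = _soft_disc((n, n), cy, cx, 0.45 * r, 0.45 * r, 0.0, edge=1.2)
        phase += phi0 * (mask - 0.35 * dip)
        absorb += 0.06 * mask
        cid += 1
        labels[mask > 0.5] = cid
    return phase, absorb, labels


def _pap_smear(n: int, rng: np.random.Generator):
    """Large ellipsoidal cells with a denser nucleus."""
    phase = np.zeros((n, n))
    absorb = np.zeros((n, n))
    labels = np.zeros((n, n), dtype=np.int32)
    n_cells = max(2, int(0.00018 * n * n))
    cid = 0
    for _ in range(n_cells):
        ry, rx = rng.uniform(0.09 * n, 0.2 * n, size=2)
        cy = rng.uniform(0.1 * n, 0.9 * n)
        cx = rng.uniform(0.1 * n, 0.9 * n)
        theta = rng.uniform(0, np.pi)
        cyto = _soft_disc((n, n), cy, cx, ry, rx, theta, edge=2.0)
        nuc = _soft_disc((n, n), cy, cx, 0.28 * ry, 0.28 * rx, theta, edge=1.5)
        phase += rng.uniform(0.3, 0.7) * cyto + rng.uniform(0.8, 1.3) * nuc
        absorb += 0.05 * cyto + 0.12 * nuc
        cid += 1
        labels[cyto > 0.5] = cid
    return phase, absorb, labels


def _tissue(n: int, rng: np.random.Generator):
    """Connected filtered-noise texture emulating a stained tissue section."""
    # fixed (grid-independent) texture scales; coarse enough to look tissue-
    # like, fine enough that the phase spectrum stays axially measurable at
    # sub-mm sample-to-sensor distances. Phase and absorption use independent
    # textures so defocus-induced phase contrast cannot masquerade as the
    # true amplitude pattern.
    def _texture() -> np.ndarray:
        base = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma=3.0)
        fine = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma=1.2)
        tex = base / (np.std(base) + 1e-12) + 0.4 * fine / (np.std(fine) + 1e-12)
        return (tex - tex.min()) / (np.ptp(tex) + 1e-12)

    # stained-section balance: absorption-dominant with a moderate
    # (~1 rad peak) phase delay
    phase = 0.9 * _texture()
    absorb = 0.45 * _texture()
    labels = np.zeros((n, n), dtype=np.int32)
    return phase, absorb, labels


def _discs(n: int, rng: np.random.Generator):
    """Sparse uniform-phase discs for metrology tests (pure phase)."""
    phase = np.zeros((n, n))
    labels = np.zeros((n, n), dtype=np.int32)
    n_cells = max(2, int(0.0003 * n * n))
    cid = 0
    for _ in range(n_cells):
        r = rng.uniform(4.0, 8.0)
        cy, cx = rng.uniform(r + 2, n - r - 2, size=2)
        mask = _soft_disc((n, n), cy, cx, r, r, 0.0, edge=0.8)
        phase += 1.0 * mask
        cid += 1
        labels[mask > 0.5] = cid
    return phase, np.zeros((n, n)), labels


_TEXTURES = {
    "blood_smear": _blood_smear,
    "pap_smear": _pap_smear,
    "tissue": _tissue,
    "discs": _discs,
}


def generate_phantom(
    sample_type: str,
    grid_size: int = 256,
    seed: int = 0,
    target_rms_ratio: float = 0.3,
    config: OpticalConfig | None = None,
) -> Phantom:
    """Generate a seeded synthetic specimen with a calibrated scattering ratio.

    The scattered wave ``t - 1`` is rescaled by fixed-point iteration
    (<= 20 steps) until its RMS modulus is within +/-2% (absolute) of
    ``target_rms_ratio`` times the unit reference RMS, while keeping the
    specimen passive (|t| <= 1).
    """
    if sample_type not in _TEXTURES:
        raise ValueError(f"unknown sample_type {sample_type!r}; expected one of {SAMPLE_TYPES}")
    if not 0 < target_rms_ratio < 1:
        raise ValueError(f"target_rms_ratio must be in (0, 1), got {target_rms_ratio}")
    if grid_size < 64:
        raise ValueError(f"grid_size must be >= 64, got {grid_size}")
    cfg = config or OpticalConfig()

    rng = np.random.default_rng(seed)
    phase, absorb, labels = _TEXTURES[sample_type](int(grid_size), rng)
    amplitude = np.clip(1.0 - absorb, 0.05, 1.0)
    t = amplitude * np.exp(1j * phase)
    s = t - 1.0

    for _ in range(20):
        rms = float(np.sqrt(np.mean(np.abs(s) ** 2)))
        if rms == 0.0:
            break
        if abs(rms - target_rms_ratio) <= 0.5 * 0.02:
            break
        s = s * (target_rms_ratio / rms)
        t = 1.0 + s
        mod = np.abs(t)
        over = mod > 1.0
        if np.any(over):
            t = np.where(over, t / mod, t)
            s = t - 1.0

    return Phantom(
        transmittance=t,
        scattered=s,
        sample_type=sample_type,
        seed=int(seed),
        config=cfg,
        labels=labels,
        target_rms_ratio=float(target_rms_ratio),
    )


def measure_rms_ratio(phantom: Phantom) -> float:
    """RMS modulus of the scattered wave relative to the unit reference."""
    return float(np.sqrt(np.mean(np.abs(phantom.scattered) ** 2)))


def generate_stack(
    phantom: Phantom,
    heights: tuple[float, ...] | None = None,
    reference_amplitude: float = 1.0,
    noise_model: str = "none",
    noise_param: float | None = None,
    seed: int = 0,
) -> HologramStack:
    """Simulate one hologram per height for a phantom.

    Noise is applied to the formed intensities: ``"shot"`` draws Poisson
    counts at ``noise_param`` photons per unit intensity (default 10,000);
    ``"gaussian"`` adds zero-mean noise of absolute std ``noise_param``.
    """
    if heights is None:
        heights = default_heights()
    heights = tuple(float(h) for h in heights)
    if len(heights) == 0:
        raise ValueError("heights must be non-empty")
    if any(h <= 0 for h in heights):
        raise ValueError("all heights must be > 0")
    if any(b <= a for a, b in zip(heights, heights[1:])):
        raise ValueError("heights must be strictly increasing")
    if noise_model not in ("none", "shot", "gaussian"):
        raise ValueError(f"unknown noise_model {noise_model!r}")

    scattered = ComplexField(
        values=reference_amplitude * phantom.scattered, config=phantom.config, z=0.0
    )
    rng = np.random.default_rng(seed)
    images = []
    for h in heights:
        holo = simulate_hologram(scattered, reference_amplitude, h)
        vals = holo.values
        if noise_model == "shot":
            photons = DEFAULT_PHOTONS if noise_param is None else float(noise_param)
            vals = rng.poisson(vals * photons).astype(np.float64) / photons
        elif noise_model == "gaussian":
            sigma = 0.01 if noise_param is None else float(noise_param)
            vals = np.maximum(vals + rng.normal(0.0, sigma, vals.shape), 0.0)
        images.append(IntensityImage(values=vals, config=phantom.config, z=h))
    return HologramStack(
        images=tuple(images),
        heights=heights,
        noise_model=noise_model,
        noise_param=noise_param,
        reference_amplitude=float(reference_amplitude),
    )


def twin_energy(
    recovered: ComplexField,
    truth: Phantom,
    baseline: ComplexField | None = None,
    z: float = DEFAULT_BASE_Z,
) -> float:
    """Residual artifact energy of a reconstruction, normalized to 1 for the
    raw single-hologram back-propagation.

    ``energy(recovered - t) / energy(back_propagated_input - t)`` where ``t``
    is the true transmittance. Fields are assumed normalized to a unit
    reference. Because intensity-only measurements leave a global phase
    undetermined, both fields are rotated by the truth-optimal global phase
    before the energies are computed (a gauge-invariant artifact measure).
    When ``baseline`` is omitted it is computed by simulating a noiseless
    hologram of the phantom at ``z`` and back-propagating it.
    """
    if recovered.shape != truth.shape:
        raise ValueError(
            f"grid mismatch: recovered {recovered.shape} vs truth {truth.shape}"
        )
    if baseline is None:
        scattered = ComplexField(values=truth.scattered, config=truth.config, z=0.0)
        holo = simulate_hologram(scattered, 1.0, z)
        baseline = back_propagate(holo, z, 1.0)
    if baseline.shape != truth.shape:
        raise ValueError("baseline grid does not match truth")

    def _aligned_energy(vals: np.ndarray) -> float:
        inner = np.sum(vals * np.conj(truth.transmittance))
        phase = inner / abs(inner) if abs(inner) > 0 else 1.0
        return float(np.sum(np.abs(vals / phase - truth.transmittance) ** 2))

    num = _aligned_energy(recovered.values)
    den = _aligned_energy(baseline.values)
    if den == 0.0:
        return 0.0
    return num / den
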