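"""Scalar diffraction engine for lens-free in-line holography.

Implements free-space propagation by the (band-limited) angular spectrum
method, in-line hologram formation ``I = |A + a_z|**2`` and free-space
back-propagation of a single hologram intensity.

Conventions
-----------
* ``z`` increases from the sample toward the sensor; back-propagation uses
  negative propagation distances.
* Grids are row-major with the origin at the top-left pixel centre.
* All lengths are in micrometres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger("holorec.optics")

__all__ = [
    "OpticalConfig",
    "ComplexField",
    "IntensityImage",
    "propagate",
    "simulate_hologram",
    "back_propagate",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Optical sampling parameters shared by fields and intensity images.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength in micrometres (vacuum).
    pixel_pitch : float
        Sampling pitch of the grid in micrometres.
    medium_index : float
        Refractive index of the propagation medium (>= 1).
    pad_factor : int
        Linear zero-padding factor applied around the grid before the FFT
        used for propagation (1 = no padding, i.e. periodic boundaries).
    evanescent_policy : str
        ``"zero"`` suppresses evanescent spatial frequencies (default,
        power non-increasing); ``"keep"`` passes them through unchanged and
        exists to make round-trip propagation exactly unitary in tests.
    """

    wavelength: float = 0.532
    pixel_pitch: float = 1.0
    medium_index: float = 1.0
    pad_factor: int = 2
    evanescent_policy: str = "zero"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.wavelength) and self.wavelength > 0):
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")
        if not (np.isfinite(self.pixel_pitch) and self.pixel_pitch > 0):
            raise ValueError(f"pixel_pitch must be positive, got {self.pixel_pitch}")
        if not (np.isfinite(self.medium_index) and self.medium_index >= 1):
            raise ValueError(f"medium_index must be >= 1, got {self.medium_index}")
        if int(self.pad_factor) != self.pad_factor or self.pad_factor < 1:
            raise ValueError(f"pad_factor must be an integer >= 1, got {self.pad_factor}")
        if self.evanescent_policy not in ("zero", "keep"):
            raise ValueError(
                f"evanescent_policy must be 'zero' or 'keep', got {self.evanescent_policy!r}"
            )

    @property
    def wavenumber(self) -> float:
        """Wavenumber in the medium, 2*pi*n/lambda (rad/um)."""
        return 2.0 * np.pi * self.medium_index / self.wavelength


def _check_grid(values: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 2-D grid, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class ComplexField:
    """2-D complex optical field sampled on a regular grid.

    ``z`` is the axial position (um) of the plane relative to the sample.
    """

    values: np.ndarray
    config: OpticalConfig
    z: float = 0.0

    def __post_init__(self) -> None:
        arr = _check_grid(self.values, "field values").astype(np.complex128, copy=False)
        object.__setattr__(self, "values", arr)
        if not np.isfinite(self.z):
            raise ValueError("z must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    def power(self) -> float:
        """Total power, sum |u|^2 * pitch^2."""
        return float(np.sum(np.abs(self.values) ** 2) * self.config.pixel_pitch**2)


@dataclass(frozen=True)
class IntensityImage:
    """2-D nonnegative intensity image recorded at axial position ``z``."""

    values: np.ndarray
    config: OpticalConfig
    z: float = 0.0

    def __post_init__(self) -> None:
        arr = _check_grid(self.values, "intensity values").astype(np.float64, copy=False)
        if np.any(arr < 0):
            raise ValueError("intensity values must be nonnegative")
        object.__setattr__(self, "values", arr)
        if not np.isfinite(self.z):
            raise ValueError("z must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _transfer_function(
    shape: tuple[int, int], config: OpticalConfig, dz: float
) -> np.ndarray:
    """Angular-spectrum transfer function on an (already padded) grid."""
    ny, nx = shape
    lam = config.wavelength / config.medium_index  # wavelength in the medium
    fy = np.fft.fftfreq(ny, d=config.pixel_pitch)[:, None]
    fx = np.fft.fftfreq(nx, d=config.pixel_pitch)[None, :]
    ft2 = (lam * fx) ** 2 + (lam * fy) ** 2
    propagating = ft2 <= 1.0

    kz = np.zeros(shape)
    np.sqrt(np.maximum(1.0 - ft2, 0.0), out=kz)
    kz *= 2.0 * np.pi / lam

    # Phase referenced to the on-axis plane wave (kz - k): a constant field is
    # an exact eigenfunction with eigenvalue 1, and the zero-phase-reference
    # hologram gauge |A + a_z|^2 stays consistent with propagation of the
    # total field A + a.
    k = 2.0 * np.pi / lam
    H = np.zeros(shape, dtype=np.complex128)
    H[propagating] = np.exp(1j * (kz[propagating] - k) * dz)
    if config.evanescent_policy == "keep":
        # Pass evanescent components through untouched: keeps the round trip
        # propagate(z) o propagate(-z) exactly unitary (test-only mode).
        H[~propagating] = 1.0
    else:
        # Band limit of Matsushima & Shimobaba (2009) against kernel
        # undersampling over long propagation distances. Only applied when
        # the grid is padded: with pad_factor=1 the periodic model is exact
        # and the limit would make propagation steps mutually inconsistent.
        ly = ny * config.pixel_pitch
        lx = nx * config.pixel_pitch
        if dz != 0.0 and config.pad_factor > 1:
            fy_lim = 1.0 / (lam * np.sqrt((2.0 * dz / ly) ** 2 + 1.0))
            fx_lim = 1.0 / (lam * np.sqrt((2.0 * dz / lx) ** 2 + 1.0))
            H[(np.abs(fy) > fy_lim) | (np.abs(fx) > fx_lim)] = 0.0

    # Aliasing diagnostic: warn when the kernel phase step between adjacent
    # frequency samples exceeds pi anywhere in the propagating band.
    phase = (kz - k) * dz
    step = 0.0
    if ny > 1:
        dphi = np.abs(np.diff(phase, axis=0))[propagating[1:, :] & propagating[:-1, :]]
        if dphi.size:
            step = max(step, float(dphi.max()))
    if nx > 1:
        dphi = np.abs(np.diff(phase, axis=1))[propagating[:, 1:] & propagating[:, :-1]]
        if dphi.size:
            step = max(step, float(dphi.max()))
    if step > np.pi:
        logger.warning(
            "propagation kernel undersampled: max phase step %.2f rad > pi "
            "(dz=%g um, grid %dx%d, pitch %g um)",
            step,
            dz,
            ny,
            nx,
            config.pixel_pitch,
        )
    return H


def propagate(field: ComplexField, dz: float) -> ComplexField:
    """Propagate ``field`` by a signed axial distance ``dz`` (um).

    Uses the angular spectrum method on a grid padded by
    ``config.pad_factor`` (edge replication) to suppress wrap-around;
    evanescent frequencies are handled per ``config.evanescent_policy``.
    """
    if not np.isfinite(dz):
        raise ValueError(f"dz must be finite, got {dz}")
    cfg = field.config
    if dz == 0.0:
        return replace(field, values=field.values.copy())

    ny, nx = field.shape
    py = (cfg.pad_factor - 1) * ny
    px = (cfg.pad_factor - 1) * nx
    if py or px:
        padded = np.pad(
            field.values,
            ((py // 2, py - py // 2), (px // 2, px - px // 2)),
            mode="edge",
        )
    else:
        padded = field.values

    H = _transfer_function(padded.shape, cfg, dz)
    out = np.fft.ifft2(np.fft.fft2(padded) * H)
    if py or px:
        out = out[py // 2 : py // 2 + ny, px // 2 : px // 2 + nx]
    return ComplexField(values=out, config=cfg, z=field.z + dz)


def simulate_hologram(
    object_field: ComplexField, reference_amplitude: float, z: float
) -> IntensityImage:
    """Form an in-line hologram intensity ``I = |A + a_z|**2``.

    ``object_field`` holds the scattered wave ``a`` (total transmitted field
    minus the reference) at its own plane; it is propagated to the sensor
    plane at ``z`` and interfered with the plane reference of amplitude
    ``reference_amplitude`` (zero phase at the detection plane).
    """
    if not (np.isfinite(reference_amplitude) and reference_amplitude > 0):
        raise ValueError(f"reference_amplitude must be > 0, got {reference_amplitude}")
    if not np.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    a_z = propagate(object_field, z - object_field.z)
    intensity = np.abs(reference_amplitude + a_z.values) ** 2
    return IntensityImage(values=intensity, config=object_field.config, z=z)


def back_propagate(
    holo: IntensityImage, z: float, reference_amplitude: float = 1.0
) -> ComplexField:
    """Free-space back-propagation of a single hologram intensity.

    ``sqrt(I)`` is treated as a real field with zero phase at the sensor and
    propagated by ``-z`` to the sample plane. The result carries the
    twin-image and self-interference artifacts of the lost phase.
    """
    if not (np.isfinite(reference_amplitude) and reference_amplitude > 0):
        raise ValueError(f"reference_amplitude must be > 0, got {reference_amplitude}")
    if not np.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    if np.any(holo.values < 0):  # defensive: IntensityImage already enforces this
        raise ValueError("hologram contains negative intensities")
    sensor = ComplexField(
        values=np.sqrt(holo.values).astype(np.complex128),
        config=holo.config,
        z=holo.z,
    )
    return propagate(sensor, -z)
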