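"""Multi-height iterative phase retrieval with a TIE initial guess.

The gold-standard reconstruction pipeline: the holograms at the 1st, 7th and
8th heights seed a transport-of-intensity phase estimate at the 7th height;
the complex guess is then refined by the amplitude-update iteration over all
heights (descending sweeps, 50 iterations by default) and finally
back-propagated to the sample plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import ComplexField, IntensityImage, OpticalConfig, propagate
from .phantom import HologramStack

__all__ = [
    "TIEInput",
    "MultiHeightParams",
    "tie_phase",
    "multiheight_recover",
    "recover_subset",
]

#: Relative intensity floor applied before square roots and divisions.
INTENSITY_FLOOR = 1e-6


@dataclass(frozen=True)
class TIEInput:
    """Three-plane intensity input for the TIE initial phase estimate."""

    I_first: IntensityImage
    I_seventh: IntensityImage
    I_eighth: IntensityImage
    z_first: float
    z_seventh: float
    z_eighth: float
    # relative to the max Laplacian eigenvalue; 1e-4 measurably improves
    # low-frequency phase recovery of the full pipeline over 1e-3
    regularization_eps: float = 1e-4

    def __post_init__(self) -> None:
        if not (self.z_first < self.z_seventh < self.z_eighth):
            raise ValueError("heights must satisfy z_first < z_seventh < z_eighth")
        shapes = {self.I_first.shape, self.I_seventh.shape, self.I_eighth.shape}
        if len(shapes) != 1:
            raise ValueError(f"intensity shapes differ: {shapes}")
        if self.regularization_eps <= 0:
            raise ValueError("regularization_eps must be > 0")


@dataclass
class MultiHeightParams:
    """Iteration controls and the per-visit residual log."""

    n_iterations: int = 50
    subset: tuple[int, ...] | None = None
    convergence_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.subset is not None:
            sub = tuple(self.subset)
            if len(sub) == 0 or list(sub) != sorted(set(sub)):
                raise ValueError("subset must be non-empty, sorted, unique")
            self.subset = sub


def _mirror_pad(arr: np.ndarray) -> np.ndarray:
    ny, nx = arr.shape
    return np.pad(arr, ((0, ny), (0, nx)), mode="symmetric")


def _inv_laplacian(rhs: np.ndarray, pitch: float, eps: float) -> np.ndarray:
    """Regularized spectral inverse Laplacian on a mirror-padded domain."""
    padded = _mirror_pad(rhs)
    ny, nx = padded.shape
    ky = 2 * np.pi * np.fft.fftfreq(ny, d=pitch)[:, None]
    kx = 2 * np.pi * np.fft.fftfreq(nx, d=pitch)[None, :]
    k2 = ky**2 + kx**2
    reg = eps * float(k2.max())
    out = np.fft.ifft2(np.fft.fft2(padded) * (-1.0) / (k2 + reg)).real
    return out[: rhs.shape[0], : rhs.shape[1]]


def _spectral_gradient(arr: np.ndarray, pitch: float) -> tuple[np.ndarray, np.ndarray]:
    padded = _mirror_pad(arr)
    ny, nx = padded.shape
    ky = 2 * np.pi * np.fft.fftfreq(ny, d=pitch)[:, None]
    kx = 2 * np.pi * np.fft.fftfreq(nx, d=pitch)[None, :]
    F = np.fft.fft2(padded)
    gy = np.fft.ifft2(1j * ky * F).real[: arr.shape[0], : arr.shape[1]]
    gx = np.fft.ifft2(1j * kx * F).real[: arr.shape[0], : arr.shape[1]]
    return gy, gx


def _spectral_divergence(gy: np.ndarray, gx: np.ndarray, pitch: float) -> np.ndarray:
    py, px = _mirror_pad(gy), _mirror_pad(gx)
    ny, nx = py.shape
    ky = 2 * np.pi * np.fft.fftfreq(ny, d=pitch)[:, None]
    kx = 2 * np.pi * np.fft.fftfreq(nx, d=pitch)[None, :]
    div = (
        np.fft.ifft2(1j * ky * np.fft.fft2(py)).real
        + np.fft.ifft2(1j * kx * np.fft.fft2(px)).real
    )
    return div[: gy.shape[0], : gy.shape[1]]


def tie_phase(inp: TIEInput, config: OpticalConfig) -> np.ndarray:
    """Solve the transport-of-intensity equation for the phase at the 7th height.

    Axial derivative stencil ``(I8 - I1) / (z8 - z1)``, in-plane intensity
    ``I7``; the elliptic problem ``div(I grad phi) = -k dI/dz`` is solved by
    two regularized spectral Poisson inversions (Teague's auxiliary
    function). The returned phase is zero-mean (piston removed).
    """
    I1, I7, I8 = inp.I_first.values, inp.I_seventh.values, inp.I_eighth.values
    floor = INTENSITY_FLOOR * float(I7.max())
    if floor <= 0:
        raise ValueError("seventh-height intensity is identically zero")
    I7c = np.maximum(I7, floor)

    dz = inp.z_eighth - inp.z_first
    dIdz = (I8 - I1) / dz
    k = config.wavenumber
    pitch = config.pixel_pitch

    psi = _inv_laplacian(-k * dIdz, pitch, inp.regularization_eps)
    gy, gx = _spectral_gradient(psi, pitch)
    div = _spectral_divergence(gy / I7c, gx / I7c, pitch)
    phi = _inv_laplacian(div, pitch, inp.regularization_eps)
    return phi - phi.mean()


def _amplitude_update(field_vals: np.ndarray, intensity: np.ndarray):
    """Average the field amplitude with the measured one; keep phase."""
    meas = np.sqrt(np.maximum(intensity, 0.0))
    amp = np.abs(field_vals)
    residual = float(np.sqrt(np.mean((amp - meas) ** 2)))
    new_amp = 0.5 * (amp + meas)
    phase = np.angle(field_vals)
    return new_amp * np.exp(1j * phase), residual


def multiheight_recover(
    stack: HologramStack,
    init_phase: np.ndarray,
    params: MultiHeightParams,
    config: OpticalConfig,
) -> ComplexField:
    """Iterative multi-height amplitude-update phase retrieval.

    The initial guess ``sqrt(I[-2]) * exp(i init_phase)`` at the
    second-highest plane is refocused to the top plane, its amplitude is
    averaged with the measured one (phase kept), and the update sweeps down
    through every lower plane — one iteration. Subsequent iterations restart
    by propagating from the lowest plane back to the top. After
    ``params.n_iterations`` the field is back-propagated to the sample plane.
    Per-visit residuals RMS(|field| - sqrt(I)) are appended to
    ``params.convergence_log`` as ``(iteration, plane_index, residual)``.
    """
    indices = params.subset if params.subset is not None else tuple(range(len(stack)))
    if any(i < 0 or i >= len(stack) for i in indices):
        raise ValueError("subset indices out of stack range")
    if len(indices) < 2:
        raise ValueError(
            "multi-height recovery needs >= 2 heights; use back_propagate for one"
        )
    heights = [stack.heights[i] for i in indices]
    intensities = [stack.images[i].values for i in indices]
    n = len(indices)

    if init_phase.shape != intensities[0].shape:
        raise ValueError("init_phase shape does not match stack images")

    params.convergence_log.clear()
    vals = np.sqrt(np.maximum(intensities[n - 2], 0.0)) * np.exp(1j * init_phase)
    fld = ComplexField(values=vals, config=config, z=heights[n - 2])
    cur = n - 2

    for it in range(params.n_iterations):
        fld = propagate(fld, heights[n - 1] - heights[cur])
        cur = n - 1
        new_vals, res = _amplitude_update(fld.values, intensities[cur])
        params.convergence_log.append((it, indices[cur], res))
        fld = ComplexField(values=new_vals, config=config, z=heights[cur])
        for j in range(n - 2, -1, -1):
            fld = propagate(fld, heights[j] - heights[cur])
            cur = j
            new_vals, res = _amplitude_update(fld.values, intensities[cur])
            params.convergence_log.append((it, indices[cur], res))
            fld = ComplexField(values=new_vals, config=config, z=heights[cur])

    out = propagate(fld, -heights[0])
    if stack.reference_amplitude != 1.0:
        out = ComplexField(
            values=out.values / stack.reference_amplitude, config=config, z=out.z
        )
    return out


def recover_subset(
    stack: HologramStack,
    n_holo: int,
    params: MultiHeightParams | None = None,
    config: OpticalConfig | None = None,
) -> ComplexField:
    """Recover from the first ``n_holo`` heights of a stack.

    Uses the TIE triplet (1st/7th/8th heights) for the initial phase when the
    full 8-height protocol is available; otherwise starts from zero phase.
    """
    if n_holo < 2:
        raise ValueError("n_holo must be >= 2")
    if n_holo > len(stack):
        raise ValueError(f"n_holo={n_holo} exceeds stack size {len(stack)}")
    cfg = config or stack.images[0].config
    params = params or MultiHeightParams()
    params.subset = tuple(range(n_holo))

    if n_holo == 8:
        inp = TIEInput(
            I_first=stack.images[0],
            I_seventh=stack.images[6],
            I_eighth=stack.images[7],
            z_first=stack.heights[0],
            z_seventh=stack.heights[6],
            z_eighth=stack.heights[7],
        )
        init_phase = tie_phase(inp, cfg)
    else:
        init_phase = np.zeros(stack.images[0].shape)
    return multiheight_recover(stack, init_phase, params, cfg)
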