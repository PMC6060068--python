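"""Quantitative readouts: per-channel SSIM, cell phase integrals, defocus sweep."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

from .nnet.infer import infer
from .nnet.model import MultiScaleNet
from .optics import ComplexField, IntensityImage, back_propagate

__all__ = [
    "SSIMParams",
    "CellPhaseStats",
    "ssim_channels",
    "amplitude_ssim",
    "phase_integral",
    "compare_cell_integrals",
    "defocus_sweep",
]


@dataclass(frozen=True)
class SSIMParams:
    """Windowed SSIM parameters (Gaussian window, standard constants)."""

    window: int = 11
    k1: float = 0.01
    k2: float = 0.03
    sigma: float = 1.5
    dynamic_range: float | None = None  # None -> observed max - min per channel

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be > 0")


@dataclass
class CellPhaseStats:
    """Per-cell phase integrals (rad*um^2) against a background reference."""

    labels: np.ndarray
    per_cell_integral: list  # (cell_id, integral)
    background_phase: float

    def as_dict(self) -> dict[int, float]:
        return dict(self.per_cell_integral)


def _ssim_single(a: np.ndarray, b: np.ndarray, params: SSIMParams) -> float:
    if params.dynamic_range is not None:
        dr = params.dynamic_range
    else:
        both = np.concatenate([a.ravel(), b.ravel()])
        dr = float(both.max() - both.min())
        if dr == 0.0:
            dr = 1.0
    return float(
        structural_similarity(
            a,
            b,
            win_size=params.window,
            gaussian_weights=True,
            sigma=params.sigma,
            K1=params.k1,
            K2=params.k2,
            use_sample_covariance=False,
            data_range=dr,
        )
    )


def ssim_channels(
    candidate: ComplexField | np.ndarray,
    reference: ComplexField | np.ndarray,
    params: SSIMParams | None = None,
) -> tuple[float, float]:
    """SSIM computed separately on the real and imaginary parts."""
    params = params or SSIMParams()
    a = candidate.values if isinstance(candidate, ComplexField) else np.asarray(candidate)
    b = reference.values if isinstance(reference, ComplexField) else np.asarray(reference)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return (
        _ssim_single(a.real, b.real, params),
        _ssim_single(a.imag, b.imag, params),
    )


def amplitude_ssim(
    candidate: ComplexField, reference: ComplexField, params: SSIMParams | None = None
) -> float:
    """SSIM between the amplitude (modulus) images of two fields."""
    params = params or SSIMParams()
    if candidate.shape != reference.shape:
        raise ValueError("shape mismatch")
    return _ssim_single(candidate.amplitude(), reference.amplitude(), params)


def phase_integral(
    phase_image: np.ndarray, labels: np.ndarray, pixel_pitch: float
) -> CellPhaseStats:
    """Background-relative phase integral per labelled cell, in rad*um^2.

    The background (label 0) phase is estimated by its median; each cell's
    integral is ``sum(phase - background) * pitch**2`` over its pixels.
    """
    phase_image = np.asarray(phase_image, dtype=np.float64)
    labels = np.asarray(labels)
    if phase_image.shape != labels.shape:
        raise ValueError("phase image and label grids must match")
    bg = labels == 0
    if bg.sum() < 0.01 * labels.size:
        raise ValueError("background (label 0) must cover >= 1% of pixels")
    background_phase = float(np.median(phase_image[bg]))
    area = pixel_pitch**2
    integrals = []
    for cid in np.unique(labels):
        if cid == 0:
            continue
        mask = labels == cid
        integrals.append(
            (int(cid), float(np.sum(phase_image[mask] - background_phase) * area))
        )
    return CellPhaseStats(
        labels=labels, per_cell_integral=integrals, background_phase=background_phase
    )


def compare_cell_integrals(stats_a: CellPhaseStats, stats_b: CellPhaseStats) -> dict:
    """Pair per-cell integrals by cell id and report their Pearson correlation."""
    da, db = stats_a.as_dict(), stats_b.as_dict()
    if set(da) != set(db):
        raise ValueError("cell id sets differ between the two statistics")
    ids = sorted(da)
    a = np.array([da[i] for i in ids])
    b = np.array([db[i] for i in ids])
    if len(ids) >= 2 and np.std(a) > 0 and np.std(b) > 0:
        r = float(stats.pearsonr(a, b).statistic)
    else:
        r = 1.0 if np.allclose(a, b) else 0.0
    return {"cell_ids": ids, "values_a": a, "values_b": b, "pearson_r": r}


def defocus_sweep(
    model: MultiScaleNet,
    holo: IntensityImage,
    z_center: float,
    reference: ComplexField,
    z_range: float = 20.0,
    dz: float = 1.0,
    reference_amplitude: float = 1.0,
    params: SSIMParams | None = None,
) -> dict:
    """Amplitude SSIM of the network output versus a reference reconstruction
    as a function of back-propagation defocus.

    For each defocus delta in ``[-z_range, +z_range]`` with step ``dz``
    (41 points at the defaults) the hologram is back-propagated to
    ``z_center + delta``, fed to the network, and the amplitude SSIM against
    ``reference`` is recorded.
    """
    if dz <= 0:
        raise ValueError("dz must be > 0")
    n = int(round(z_range / dz))
    deltas = np.arange(-n, n + 1) * dz
    ssims = []
    for d in deltas:
        bp = back_propagate(holo, z_center + d, reference_amplitude)
        out = infer(model, bp, reference_amplitude=reference_amplitude)
        ssims.append(amplitude_ssim(out, reference, params))
    ssims = np.asarray(ssims)
    if not np.all(np.isfinite(ssims)):
        raise RuntimeError("defocus sweep produced non-finite SSIM values")
    return {"defocus_um": deltas, "ssim": ssims}
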