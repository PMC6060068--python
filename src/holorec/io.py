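"""Readers and writers for holograms (TIFF/PNG), complex fields and stacks (HDF5)."""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .optics import ComplexField, IntensityImage, OpticalConfig
from .phantom import DEFAULT_BASE_Z, DEFAULT_HEIGHT_OFFSETS, HologramStack, Phantom

__all__ = [
    "RunConfig",
    "read_hologram",
    "write_hologram",
    "read_complex",
    "write_complex",
    "write_stack",
    "read_stack",
    "write_phantom",
    "read_phantom",
]


@dataclass
class RunConfig:
    """Serializable run configuration (defaults mirror the standard protocol)."""

    wavelength: float = 0.532
    pixel_pitch: float = 1.0
    medium_index: float = 1.0
    pad_factor: int = 2
    evanescent_policy: str = "zero"
    base_z: float = DEFAULT_BASE_Z
    height_offsets: tuple = DEFAULT_HEIGHT_OFFSETS
    n_iterations: int = 50
    tile_grid: int = 5
    tile_overlap: int = 400
    split_fractions: tuple = (2.0 / 3.0, 1.0 / 6.0, 1.0 / 6.0)
    network_preset: str = "sample-type-specific"
    seed: int = 0
    log_level: str = "INFO"

    def optics(self) -> OpticalConfig:
        return OpticalConfig(
            wavelength=self.wavelength,
            pixel_pitch=self.pixel_pitch,
            medium_index=self.medium_index,
            pad_factor=self.pad_factor,
            evanescent_policy=self.evanescent_policy,
        )

    def heights(self) -> tuple[float, ...]:
        return tuple(self.base_z + off for off in self.height_offsets)

    def to_yaml(self, path: str) -> None:
        data = asdict(self)
        data["height_offsets"] = list(self.height_offsets)
        data["split_fractions"] = list(self.split_fractions)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "height_offsets" in data:
            data["height_offsets"] = tuple(data["height_offsets"])
        if "split_fractions" in data:
            data["split_fractions"] = tuple(data["split_fractions"])
        return cls(**data)

    def write_provenance(self, path: str, **extra) -> None:
        """Dump the config snapshot plus run metadata next to an output."""
        record = asdict(self)
        record.update(extra)
        with open(path, "w") as fh:
            json.dump(record, fh, indent=2, default=str)


# ----------------------------------------------------------------------
# intensity images
# ----------------------------------------------------------------------


def read_hologram(path: str, config: OpticalConfig | None = None, z: float = 0.0) -> IntensityImage:
    """Load a grayscale TIFF/PNG hologram as a float intensity image.

    Integer inputs are converted to float counts unchanged. RGB images are
    rejected; pitch/wavelength must come from ``config``.
    """
    if config is None:
        raise ValueError("an OpticalConfig (pixel pitch, wavelength) is required")
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"expected a grayscale image, got shape {arr.shape}")
    return IntensityImage(values=arr.astype(np.float64), config=config, z=z)


def write_hologram(image: IntensityImage, path: str) -> None:
    """Write an intensity image as 32-bit float grayscale TIFF (or PNG/16-bit)."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, image.values.astype(np.float32))
    else:
        vals = image.values
        top = vals.max() if vals.max() > 0 else 1.0
        iio.imwrite(path, np.round(vals / top * 65535).astype(np.uint16))


# ----------------------------------------------------------------------
# complex fields (HDF5 with real/imag datasets and optics attributes)
# ----------------------------------------------------------------------

_ATTRS = ("wavelength_um", "pitch_um", "z_um")


def write_complex(fld: ComplexField, path: str) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("real", data=fld.values.real)
        fh.create_dataset("imag", data=fld.values.imag)
        fh.attrs["wavelength_um"] = fld.config.wavelength
        fh.attrs["pitch_um"] = fld.config.pixel_pitch
        fh.attrs["z_um"] = fld.z
        fh.attrs["medium_index"] = fld.config.medium_index


def read_complex(path: str) -> ComplexField:
    with h5py.File(path, "r") as fh:
        for key in _ATTRS:
            if key not in fh.attrs:
                raise ValueError(f"missing attribute {key!r} in {path}")
        values = fh["real"][()] + 1j * fh["imag"][()]
        config = OpticalConfig(
            wavelength=float(fh.attrs["wavelength_um"]),
            pixel_pitch=float(fh.attrs["pitch_um"]),
            medium_index=float(fh.attrs.get("medium_index", 1.0)),
        )
        return ComplexField(values=values, config=config, z=float(fh.attrs["z_um"]))


# ----------------------------------------------------------------------
# hologram stacks and phantoms
# ----------------------------------------------------------------------


def _write_optics(group, config: OpticalConfig) -> None:
    group.attrs["wavelength_um"] = config.wavelength
    group.attrs["pitch_um"] = config.pixel_pitch
    group.attrs["medium_index"] = config.medium_index
    group.attrs["pad_factor"] = config.pad_factor
    group.attrs["evanescent_policy"] = config.evanescent_policy


def _read_optics(group) -> OpticalConfig:
    return OpticalConfig(
        wavelength=float(group.attrs["wavelength_um"]),
        pixel_pitch=float(group.attrs["pitch_um"]),
        medium_index=float(group.attrs["medium_index"]),
        pad_factor=int(group.attrs["pad_factor"]),
        evanescent_policy=str(group.attrs["evanescent_policy"]),
    )


def write_stack(stack: HologramStack, path: str) -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("stack")
        g.create_dataset("images", data=np.stack([im.values for im in stack.images]))
        g.create_dataset("heights_um", data=np.asarray(stack.heights, dtype=np.float64))
        g.attrs["noise_model"] = stack.noise_model
        g.attrs["noise_param"] = -1.0 if stack.noise_param is None else stack.noise_param
        g.attrs["reference_amplitude"] = stack.reference_amplitude
        _write_optics(g, stack.images[0].config)


def read_stack(path: str) -> HologramStack:
    with h5py.File(path, "r") as fh:
        g = fh["stack"]
        config = _read_optics(g)
        heights = tuple(float(h) for h in g["heights_um"][()])
        images = tuple(
            IntensityImage(values=img, config=config, z=h)
            for img, h in zip(g["images"][()], heights)
        )
        noise_param = float(g.attrs["noise_param"])
        return HologramStack(
            images=images,
            heights=heights,
            noise_model=str(g.attrs["noise_model"]),
            noise_param=None if noise_param < 0 else noise_param,
            reference_amplitude=float(g.attrs["reference_amplitude"]),
        )


def write_phantom(phantom: Phantom, path: str) -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("phantom")
        g.create_dataset("real", data=phantom.transmittance.real)
        g.create_dataset("imag", data=phantom.transmittance.imag)
        if phantom.labels is not None:
            g.create_dataset("labels", data=phantom.labels)
        g.attrs["sample_type"] = phantom.sample_type
        g.attrs["seed"] = phantom.seed
        if phantom.target_rms_ratio is not None:
            g.attrs["target_rms_ratio"] = phantom.target_rms_ratio
        _write_optics(g, phantom.config)


def read_phantom(path: str) -> Phantom:
    with h5py.File(path, "r") as fh:
        g = fh["phantom"]
        t = g["real"][()] + 1j * g["imag"][()]
        labels = g["labels"][()] if "labels" in g else None
        ratio = float(g.attrs["target_rms_ratio"]) if "target_rms_ratio" in g.attrs else None
        return Phantom(
            transmittance=t,
            scattered=t - 1.0,
            sample_type=str(g.attrs["sample_type"]),
            seed=int(g.attrs["seed"]),
            config=_read_optics(g),
            labels=labels,
            target_rms_ratio=ratio,
        )
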