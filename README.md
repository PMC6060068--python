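# holorec

Lens-free digital in-line holography toolkit: simulate holograms of
strongly scattering transmissive specimens, reconstruct them with the
classical TIE-initialized multi-height phase-retrieval algorithm, and
train/apply a convolutional network that recovers twin-image-free phase and
amplitude from a **single** back-propagated hologram.

## What's inside

| Module | Purpose |
| --- | --- |
| `holorec.optics` | Angular-spectrum propagation (band-limited, padded), in-line hologram formation `I = \|A + a_z\|²`, single-hologram back-propagation |
| `holorec.phantom` | Seeded synthetic specimens (blood smear / Pap smear / tissue / discs) with calibrated scattered-wave RMS ratio, multi-height stacks (heights {0, 15, 30, 45, 60, 75, 90, 180} µm above a base distance), twin-artifact energy metric |
| `holorec.classical` | Transport-of-intensity (TIE) initial phase from heights 1/7/8, 8-height amplitude-update iteration (50 iterations default), N_holo = 2…8 subsets |
| `holorec.nnet` | Pure-NumPy multi-scale residual CNN (16 / 32 feature-map presets), 5×5 / 400-px tile pipeline, 100/25/25 splitting, training with early stopping, feather-stitched inference |
| `holorec.evaluation` | Per-channel (real/imag) SSIM, per-cell phase integrals (rad·µm²), ±20 µm defocus sweep |
| `holorec.cli` / `holorec.io` | `holorec` command-line interface, TIFF/PNG holograms, HDF5 complex fields/stacks/phantoms, YAML run config, provenance records |

The network is implemented directly on NumPy (conv/residual/pooling/
upsampling layers with manual backprop, Adam, MSE loss); no deep-learning
framework is required.

## CLI quick start

```bash
# simulate an 8-height hologram stack of a seeded tissue phantom
holorec simulate --type tissue --seed 7 --rms 0.28 --out stack.h5 --phantom-out truth.h5

# classical gold standard: TIE init + 50 amplitude-update iterations
holorec recover-classical --stack stack.h5 --nholo 8 --iters 50 --out recon.h5

# train a reconstruction network on simulated tile pairs
holorec train --preset sample-type-specific --type blood_smear --seed 1 --out model.npz

# single-hologram reconstruction with the trained network
holorec infer --model model.npz --holo holo.tif --z 300 --out recon.h5

# per-channel SSIM (+ per-cell phase integrals when labels are available)
holorec evaluate --recon recon.h5 --reference ref.h5 --phantom truth.h5 --report out/

# defocus tolerance curve (±20 µm, 1 µm steps)
holorec defocus-sweep --model model.npz --holo holo.tif --z 300 \
    --reference recon.h5 --out sweep.csv
```

Every command writes a `*.provenance.json` snapshot (config + seed) next to
its output. Defaults follow the standard protocol: wavelength 0.532 µm,
pixel pitch 1.0 µm, base sample-to-sensor distance 300 µm, heights
{0, 15, 30, 45, 60, 75, 90, 180} µm, 50 iterations, 5×5 tiling with 400-px
overlap, (2/3, 1/6, 1/6) splits, 16-feature-map ("sample-type-specific") or
32-feature-map ("universal") presets.

## Notes

- Axial convention: z increases from sample toward sensor; back-propagation
  uses negative distances. The propagation kernel is referenced to the
  on-axis plane wave so a uniform reference stays real at every plane.
- `pad_factor=1` selects exactly unitary periodic propagation (used by the
  self-consistent simulation/recovery tests); `pad_factor=2` (default)
  suppresses wrap-around via edge-padding and a band-limited kernel.
- Pixel super-resolution, autofocus preprocessing and GPU acceleration are
  out of scope; z positions are taken as known.
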