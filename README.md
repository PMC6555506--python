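# snakuscules

Energy-minimizing concentric-sphere active contours ("snakuscules") for
automated localization of bright blobs — typically cell nuclei — in 2D
images and 3D microscopy stacks.

A snake is a pair of concentric balls parameterized by two points `p`, `q`
collinear along the x axis.  Its energy contrasts the weighted intensity of
the annulus against the core (radius ratio `2^(-1/3)` in 3D so both have
equal volume), normalized by `(2R)^3` so a snake is penalized for growing
past a blob.  Detection works by covering the volume with a lattice of
snakes (pitch `1.5 R0`), evolving each independently by gradient descent
with a decaying learning rate `eps0 / n`, culling snakes whose energy
exceeds a threshold, and resolving overlapping survivors in favor of the
lower-energy snake.  Per-snake image integrals are estimated either by
exhaustive voxel summation or by seeded Monte-Carlo sampling with a fixed
per-snake budget (error `~ 1/sqrt(N)`).

## Layout

| module                      | contents                                               |
| --------------------------- | ------------------------------------------------------ |
| `snakuscules.model`         | snake geometry, radial weight profile, closed-form blob energy, discrete energy, analytic gradients |
| `snakuscules.sampling`      | grid and Monte-Carlo integration backends              |
| `snakuscules.evolution`     | gradient-descent evolution (serial / vectorized, bit-identical) |
| `snakuscules.pipeline`      | lattice init, energy culling, overlap competition, `detect` |
| `snakuscules.phantoms`      | sphere phantoms with ground truth and SNR-calibrated noise |
| `snakuscules.evaluation`    | center matching, precision / recall / F / Jaccard      |
| `snakuscules.io`            | TIFF I/O, normalization, axial resampling              |
| `snakuscules.cli`           | `snakuscules` command-line interface                   |
| `snakuscules.experiments`   | reproducible benchmark studies used by the acceptance suite |

## CLI

```bash
# generate a synthetic phantom + ground truth
snakuscules phantom -o phantom.tif --truth truth.csv --shape 128 --shape 128 --shape 128 \
    --n-spheres 20 --seed 1

# detect blobs (multi-page TIFF in, CSV out); --spacing triggers isotropic
# axial resampling
snakuscules detect phantom.tif -o detections.csv --r0 12 --seed 1

# score detections against ground-truth centers
snakuscules evaluate detections.csv truth.csv

# end-to-end demo: phantom -> detect -> evaluate
snakuscules demo --seed 1 --outdir demo/
```

All commands accept `--seed`; fixed seeds give byte-identical outputs.
`--config file.yaml` overrides the defaults with flat key/value pairs
(keys match the long option names with underscores, e.g. `n_samples`).

Intensities are min–max normalized to [0, 1] before energy evaluation; the
default energy threshold (−0.05) is on that scale, where a well-fit
unit-contrast blob scores about −0.17.

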