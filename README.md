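# ibt — ion-beam tomography reconstruction toolkit

Secondary-ion mass spectrometry (NanoSIMS/MIBI) builds 3D maps of single
cells by rastering a focused ion beam across the specimen: each scan
etches a few nm of material, and the emitted secondary ions are
mass-analyzed pixel by pixel across up to ~1000 depth scans and many mass
channels (¹²⁷I-dU-labeled replication sites, ⁸¹Br-rU-labeled transcripts,
endogenous ³¹P, ³⁴S, ...).  The raw slices are noisy, blurred by the
100–200 nm beam width and by ions extracted from below the ablated
layer.  This package implements the computational pipeline that turns
those stacks into quantitative 3D reconstructions — for SIMS
practitioners and image-analysis developers who want a tested, scriptable
reference implementation.

Three reconstruction routes are provided, plus the quantification layers
around them:

- **Deconvolution route** — sliding-window depth binning (sum n
  consecutive slices, advance one at a time, so SNR improves without
  losing axial sampling) followed by per-section Lucy–Richardson
  deconvolution with a *blind PSF* whose width is set from the recorded
  beam current (100–200 nm over 0.2–4 pA), and a light 2×2 post-filter:

  Oⁿ⁺¹ = Oⁿ · [ (I / (Oⁿ ⊗ PSF)) ⊛ PSF ]

- **SILM route** (secondary ion-beam localization microscopy) — per-slice
  sub-pixel localization of isolated ion events (3× bilinear upsampling,
  robust median + k·MAD thresholding, bounded 2D Gaussian fits) and
  Gaussian rendering of the accumulated localizations over 20–100-slice
  windows, reaching sub-beam-width precision the same way localization
  microscopy beats the diffraction limit.
- **Forward simulator** — the full image-formation model
  I = (P_out/P_in)·[O ⊗ PSF]·N with multiplicative gamma noise (mean 1),
  ~3 % ion extraction efficiency and 100 nm sub-surface axial mixing, plus
  every validation fixture: the six-molecule 200 nm array, sharp edges,
  isotope-doped ~110 nm nanotag spheres, drifting fiducial beads.

Quantification: fiducial-based drift registration, the 20·log₁₀ SNR
metric, per-depth 2D correlation with rank-sum condition comparisons,
global/windowed SSIM, 88–12 % erf-fit edge resolution (= 2.350 σ of the
effective PSF), fuzzy C-means chromatin-state segmentation, 3D K-means
with z-score heatmap export, block-wise peak statistics, pairwise peak
distances, hierarchical voxel clustering, channel correlation/association
matrices, and Delaunay block-neighborhood analysis.

## Worked example

Simulate the six-molecule validation target (six point sources 200 nm
apart, imaged by a 120 nm FWHM beam at 50 nm pixels with gamma noise and
3 % extraction efficiency), reconstruct it, and count the resolved
molecules:

```python
import numpy as np
from ibt import (six_point_geometry, six_point_fixture, PSFModel,
                 NoiseModel, simulate_stack, deconvolve_stack,
                 profile_maxima)

geom = six_point_geometry(n_pixels=64, pixel_nm=50.0, beam_width_nm=120.0)
psf = PSFModel(lateral_fwhm_nm=120.0)
noise = NoiseModel(gamma_shape=3.0, extraction_efficiency=0.03, seed=1)

stack = simulate_stack(six_point_fixture(geom), psf, noise, geom, n_slices=40)
recon = deconvolve_stack(stack, window_n=10, n_iter=5, psf_override=psf)

profile = recon.counts[:, 0].sum(axis=0)[geom.n_pixels_y // 2]
peaks = profile_maxima(profile, rel_height=0.5, smooth_sigma_px=0.8)
print(f"resolved molecules: {len(peaks)}")
print(f"mean spacing: {np.diff(peaks).mean() * geom.dx_nm:.0f} nm")
```

Output:

```
resolved molecules: 6
mean spacing: 200 nm
```

Six maxima above half-max, spaced 200 nm — the simulated array is
recovered despite the beam blur and noise.  The same stages are available
from the shell:

```sh
ibt simulate --fixture six-point --seed 1 --out run/sim --n-slices 40
ibt deconv --in run/sim --out run/deconv --window 10 --iters 5 --psf-nm 120
ibt silm --in run/sim --out run/silm --psf-nm 120 --render-sigma-nm 15
```

Each stage writes TIFF + JSON-sidecar stacks and appends to a
`manifest.json` recording parameters and seeds, so identical configs
reproduce identical outputs.

## Layout

```
src/ibt/stack.py       data model, geometry, TIFF + sidecar I/O
src/ibt/simulate.py    forward model and validation fixtures
src/ibt/preprocess.py  binning, SNR, drift registration
src/ibt/deconv.py      blind-PSF Lucy–Richardson pipeline
src/ibt/silm.py        localization reconstruction
src/ibt/metrics.py     correlation, SSIM, edge resolution
src/ibt/spatial.py     clustering, peaks, neighborhoods
src/ibt/cli.py         `ibt` command-line entry points
docs/methods.md        model assumptions, parameters, limitations
```
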