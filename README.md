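# octmoco

Higher-order-regression 3D motion compensation for volumetric OCT corneal
imaging, with a synthetic acquisition simulator so every stage is verifiable
by parameter recovery without hardware or clinical data.

The acquisition protocol first records a few slow-axis reference B-scans at
fixed fast-axis positions, then a raster C-scan. Each fast-axis B-scan is
segmented (smoothing, mean-line saturation removal, adaptive thresholding,
connected components, gradient refinement, order-4 polynomial fit), aligned
laterally to the first B-scan by variance minimization of the fitted
surfaces, and corrected axially by interpolating its offsets to the
reference planes with a quadratic. A closed-form accuracy model predicts the
optimal reference spacing ratio α = d/L.

## Layout

| module | role |
|---|---|
| `octmoco.datamodel` | core types, coordinate conventions, TIFF/CSV/JSON I/O |
| `octmoco.preprocess` | per-B-scan corneal surface segmentation |
| `octmoco.lateral` | lateral shift estimation/removal, border crop |
| `octmoco.axial` | axial offset estimation, quadratic motion model, volume driver |
| `octmoco.refplan` | reference-placement accuracy theory (R, Y, E, W, α*) |
| `octmoco.synth` | phantom surfaces, motion traces, speckled B-scan simulator |
| `octmoco.metrics` | surface error (MAE/RMSE), motion spectra, order sweeps |
| `octmoco.experiments` | standard scaled-down end-to-end experiments |
| `octmoco.cli` | `octmoco simulate / compensate / theory / evaluate` |

Conventions: B-scans are depth-major (row 0 = shallowest), indices 0-based,
depths stored in pixels (3.6 μm/px axial for corneal tissue by default) and
converted to μm only in reports. Volumes are multi-page TIFFs (reference
pages first) with a JSON sidecar holding the scan protocol.

## CLI

```sh
octmoco theory --sigma 123 --m 1023 --grid-step 0.002 --out out/theory
octmoco simulate  --config config.yaml --seed 1 --out out/sim
octmoco compensate out/sim/volume.tiff --config config.yaml --out out/comp
octmoco evaluate out/a/volume.tiff out/b/volume.tiff --config config.yaml --out out/eval
```

Minimal config (YAML; unknown keys are rejected, the resolved config is
written next to every output):

```yaml
seed: 1
protocol: {n_depth: 512, n_fast: 256, n_slow: 128, axial_pitch_um: 3.6,
           fast_pitch_um: 39.0625, slow_pitch_um: 85.9375,
           bscan_rate_hz: 100.0, n_refs: 3, alpha: 0.33}
preprocess: {border_crop: 12}
lateral: {search_px: 50, crop_px: 12}
synth:
  surface: {kind: quartic, apex_px: 200.0, sag_px: 40.0}
  motion: {kind: sinusoid, params: {axial_amplitude_um: 700.0, axial_freq_hz: 1.0}}
  noise: {speckle_scale: 0.6}
```

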