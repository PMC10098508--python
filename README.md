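# qdsted

Quantitative analysis and simulation of STED nanoscopy of blinking
far-red quantum dots.

Far red-shifted CdTe quantum dots (emission ~740 nm) can be imaged with a
775 nm STED depletion beam, but two effects complicate the quantitation:
the depletion beam directly re-excites the dots, wrapping every emitter
in a donut-shaped halo, and the dots blink on sub-millisecond timescales,
carving dark stripes along the fast scan axis. `qdsted` implements the
measurement chain for such data — and a faithful synthetic microscope to
validate it against known ground truth:

- **Subtraction**: `STEDsub = STED − STEDonly` removes the
  direct-excitation halo (`sted_processing`);
- **Photophysics**: per-QD blinking maps, the blinking pixel ratio
  (OFF fraction of a QD's footprint), background-subtracted integrated
  brightness, Lorentzian/Gaussian line-profile FWHMs, resolution-vs-power
  curves following `d(I) = d_c/√(1 + I/I_sat)`, and rank-sum group
  comparisons (`qd_photophysics`, `imaging_model`);
- **Cluster and colocalization analysis**: single-vs-cluster
  classification from the central intensity of the saturated STEDonly
  donut (a single dot keeps a dark hole; unresolved clusters fill it),
  QD fraction inside vesicle masks (QDFI), the single fraction parameter
  (SFP = single fraction inside / outside), and nearest-microtubule
  distances (`cluster_and_coloc`);
- **Simulation**: two-state telegraph blinking with exponential dwells
  and depletion-induced suppression, line-by-line raster scanning with
  configurable dwell/repeat schedules, Poisson shot noise, and
  constructive cell-scene phantoms with exact colocalization ground
  truth (`synthetic_data`);
- **IO and orchestration**: YAML configs, TIFF/CSV round trips, a staged
  pipeline and a `qdsted` command-line tool (`cli_io`, `cli`).

Models, parameter defaults and their rationale are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

Simulate a 10×10 μm field of 20 blinking QDs acquired with the optimized
10 × 20 μs repeated-line schedule, recover the super-resolved image by
subtraction, and measure each detected dot:

```python
import numpy as np
from qdsted.imaging_model import ScanConfig
from qdsted.synthetic_data import BlinkingModel, generate_qd_field, simulate_acquisition
from qdsted.sted_processing import compute_stedsub
from qdsted.qd_photophysics import analyze_qd, detect_qds

scan = ScanConfig(pixel_size_nm=30.0, image_shape_px=(334, 334),
                  dwell_time_us=20.0, n_line_repeats=10)
field = generate_qd_field(20, scan, min_separation_nm=700.0, seed=1,
                          edge_margin_nm=400.0)
stack = simulate_acquisition(field, scan, blinking=BlinkingModel(), seed=2)

stedsub = compute_stedsub(stack.channels["STED"], stack.channels["STEDonly"])
variance = stack.channels["STED"] + stack.channels["STEDonly"]   # Poisson noise of the difference
qds = detect_qds(stedsub, min_distance_px=5, pixel_size_nm=30.0,
                 variance_image=variance, local_noise_window_px=15)
print(f"detected {len(qds)} of {field.n_sites} QDs")
measured = [analyze_qd(stedsub, q.center_px, 30.0) for q in qds]
print(f"mean blinking pixel ratio: {np.mean([m.blinking_pixel_ratio for m in measured]):.2f}")
print(f"mean integrated brightness: {np.mean([m.integrated_brightness_counts for m in measured]):.0f} counts")
widths = [m.fwhm_nm for m in measured if m.fwhm_nm is not None]
print(f"median fitted FWHM: {np.median(widths):.0f} nm")
```

Output:

```
detected 14 of 20 QDs
mean blinking pixel ratio: 0.10
mean integrated brightness: 692 counts
median fitted FWHM: 75 nm
```

Six dots were blinked-off too deeply to clear the 6σ detection threshold
during their scan — exactly the behaviour that makes blinking dots
vanish from fast acquisitions of real samples. The blinking pixel ratio
of 0.10 reflects the repeated-line averaging (a single 1 × 200 μs pass of
the same field gives ≈0.27), and the 75 nm median width of a 65 nm PSF
reflects the off-axis widening of one-pixel line profiles
(`docs/methods.md`).

The same workflow runs from the shell on TIFF/CSV/YAML artifacts:

```sh
qdsted full --config config.yml --seed 21 --out results/
qdsted process --sted sted.tif --stedonly stedonly.tif --out sub.tif
qdsted coloc --config config.yml --out results/
```

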