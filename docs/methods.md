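# Methods

`qdsted` models and analyses point-scanned STED acquisitions of blinking
far-red CdTe quantum dots (QDs). This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
data can and cannot stand in for.

## Imaging model

**Grid conventions.** Images are `[row, col]`, 0-based; the fast scan
axis is the column (x) axis; pixel `(i, j)` has its center at
`((j+0.5)p, (i+0.5)p)` for pixel size `p` (nm). Lengths are nm, times
are μs (blink traces use ms), powers are mW.

**PSF profiles** are analytic, peak-normalised to 1, and evaluated at
pixel centers (no integration over the pixel area — at the 25–30 nm
pixels used here the difference is well below shot noise):

- Gaussian `exp(−4 ln2 r²/w²)` (confocal channel), `w` = FWHM;
- Lorentzian `1/(1 + 4r²/w²)` (effective STED spot) — chosen because
  depleted QD spots show the heavy tails characteristic of saturated
  depletion;
- donut `(r²/s²) exp(1 − r²/s²)` (an LG01-like ring), exactly 0 at the
  center and 1 on the crest at radius `s`.

**Resolution law.** The FWHM under depletion power `I` follows the
standard STED scaling `d(I) = d_c / √(1 + I/I_sat)`. The instrument's
confocal FWHM is not a measurable constant of this package; it is a free
configuration parameter, default `d_c = 250 nm`, with `I_sat = 12 mW` so
that the law yields ≈65 nm at 168 mW — the regime the analysis targets.
`fit_resolution_curve` fits both parameters by unweighted least squares
(`scipy.optimize.curve_fit`, widths > 0 enforced by bounds).

**Scan clock.** Lines are scanned along x, each line repeated
`n_line_repeats` times (all repeats of a row complete before the next
row), each pass followed by a configurable flyback dead time (default
0). `pixel_clock` returns the absolute dwell start of every
`(row, repeat, col)` visit; the total duration is
`rows × repeats × (cols × dwell + flyback)`.

## Blinking model

Blinking is a stationary two-state renewal (telegraph) process with
exponential ON/OFF dwells. Defaults: `tau_off = 0.5 ms` (middle of the
0.1–1 ms dark-state lifetime range typical of these QDs),
`tau_on = 0.32 ms`, and a depletion suppression factor of 2 that
multiplies `tau_on` in the STED and STEDonly channels. With suppression
the OFF occupancy is `0.5/(0.5+0.64) ≈ 0.44`, matching the blinking
level measured for QDs in Mowiol under a single 200 μs pass. The initial
state is drawn from the stationary distribution (for exponential dwells
the plain occupancy, by memorylessness). Real QD dwell distributions are
heavy-tailed (power-law-like); the exponential choice is the simplest
model consistent with the lifetime bound and is exposed in the
configuration. Consequences of this simplification are listed under
Limitations.

## Acquisition simulator

For each channel, each emitter carries one independent continuous blink
trace spanning the whole scan; expected photons in a pixel visit are
`rate × dwell × PSF × (ON fraction of the visit window)`, plus uniform
dark counts (default 5×10⁻⁴ μs⁻¹); counts are Poisson per pixel per
repeat and repeats are summed. One seed fans out via
`numpy.random.SeedSequence` to per-channel and per-emitter substreams,
so runs are bit-reproducible and single emitters can be re-simulated in
isolation.

Channel compositions: confocal = Gaussian(250 nm); STED =
Lorentzian(65 nm) + `background_fraction` × halo; STEDonly =
`background_fraction` × halo, with `background_fraction = 0.35` (the
halo is visibly dimmer than the super-resolved spot but far from
negligible).

**Saturated halo.** The halo is direct excitation by the intense
depletion donut and is modelled as a saturating response,
`(1 − e^{−S·d(r)}) / (1 − e^{−S})` with `d` the donut profile and
`S = 4.5` the peak optical depth. Saturation flattens the crest and —
critically — narrows the central dark hole to ~60 nm half-rise (2 px),
which is what makes the STEDonly image sensitive to sub-resolution QD
clusters: emitters offset by tens of nm fill each other's holes. `S = 0`
recovers a linear halo, under which cluster classification is
essentially impossible (a 20 nm offset adds ~3% of crest intensity).

**Clusters** are multiplicity-`k` sites whose members sit at independent
uniform offsets within `cluster_radius_nm = 75 nm` — the spread expected
for several QDs co-encapsulated in one endocytic vesicle. They stay
merged through detection (one peak) yet fill the saturated donut hole.

## Subtraction and photophysics

**STEDsub** = STED − `scale` × STEDonly, `scale` default 1 (equal
acquisition settings). Negatives are kept by default — shot noise makes
them inevitable and clipping before fitting biases widths; clipping to 0
is available for display and detection.

**Detection** smooths lightly (Gaussian σ = 1 px, matched-filter style)
and keeps local maxima exceeding the median by `threshold_sigma` (default
6) noise standard deviations. Shot noise is signal-dependent, so when a
per-pixel variance image is available (for STEDsub it is STED + STEDonly)
the threshold follows the local Poisson scale; otherwise a global robust
MAD estimate is used. Because blinking inflates fluctuations beyond the
Poisson level (the two subtraction channels blink independently), the
noise map can additionally be floored at a running local MAD estimate
(`local_noise_window_px`, on by default in the pipeline) — the cost is
that deeply blinked-off QDs stay undetected, just as they vanish from
fast acquisitions of real samples. Centers are refined by 3×3 center of
mass. The 6σ default keeps whole-image false positives at ~zero for the
334² rasters used here while recall on well-separated static QDs is
complete.

**Blink map.** The full-ON reference image of a QD is predicted from its
own ROI: the width comes from a Lorentzian fit to the radially averaged
profile (robust to dark runs, which rescale but do not reshape the
radial mean; a failed fit falls back to the half-maximum width, clamped
to ≥1 px), and the amplitude from the brightest rows — within rows whose
radial factor exceeds 0.5, the lightly smoothed row maximum divided by
that factor, maximised over rows, on the grounds that the brightest row
was scanned while the QD was ON. Footprint pixels (prediction ≥ 20% of
its peak) are ON when counts reach 25% of the local prediction; the
blinking pixel ratio is the OFF fraction of the footprint. Both cutoffs
are configurable; at study-like counts they misclassify ≤5% of pixels of
a non-blinking emitter.

**Integrated brightness** sums `max(counts − background, 0)` over the
footprint (default) or over ON pixels only (configurable).

**Line-profile FWHMs** are fitted on one-pixel-wide fast-axis profiles
(Lorentzian when depleted, Gaussian for confocal; offset optional; a
double-Lorentzian variant handles two-structure profiles). Note that a
row crossing a radial Lorentzian at vertical offset `dy` measures a
widened width `w√(1+4dy²/w²)`; the width-recovery study inverts this
exactly using the detected subpixel center. This is also why single-QD
STEDsub spots read ~70 nm when the underlying PSF is 65 nm.

**Group comparisons** use the two-sided Wilcoxon rank-sum test
(brightness and ratio distributions are strongly skewed) with the usual
four star levels, and report both the relative difference of means and
the ratio of means in percent.

## Cluster classification and colocalization

The donut central ratio is the background-subtracted mean within 1.5 px
of the center divided by the mean over the crest annulus (7–10 px at
30 nm pixels); the background is the ROI border median, so the
classification ROI must extend past the halo (half-width 24 px default).
Ratios ≤ 0.3 classify as single (ties single). QDFI is the fraction of
QD centers falling in true mask pixels (centroid-in-mask, no dilation; a
configurable dilation is available for membrane labels). SFP is the
single fraction inside divided by the single fraction outside — a
declared, tested definition; it is undefined (and reported as such) when
no singles exist outside. Tubulin distances are center-to-nearest-true-
pixel-center (exact, via a KD-tree; 0 when the center lies in the mask),
and "near tubulin" fractions use a strict `< 200 nm`. Bleed-through
ratios divide the background-subtracted mean structure signal in a
foreign channel by the same quantity in the fluorophore's own channel.

## Scene phantoms

`generate_cell_scene` is constructive, not probabilistic: QD pixels are
chosen per category (inside/outside vesicles × near/far from tubulin,
with a half-pixel guard band around the distance threshold), then
vesicle disks are drawn around the designated inside QDs, so the
realised QDFI and near fraction equal the requested fractions exactly
and the stored truth (membership flags, exact Euclidean distance
transform distances) holds by construction. Tubulin strands are random
lines dilated to 3 px. Infeasible geometry raises a placement error
rather than degrading silently.

## Reproduction studies and problem sizes

`qdsted.studies` packages the desk-scale experiments used by the test
suite and by `scripts/acceptance.py`: a 10⁴ ms telegraph trace against
the renewal-theory occupancy and its asymptotic standard error
`√(2τ_on²τ_off²/((τ_on+τ_off)³T))`; 50-seed STEDsub width recovery
(static emitters — the study isolates subtraction + fitting; blinking
biases apparent widths, which is the schedule study's subject); the
1×200 / 10×20 / 100×2 μs schedule comparison with 200 QDs per schedule,
each scanned in a compact 11-pixel ROI with zero flyback — in that
regime a repeated line pass takes ≤0.2 ms, shorter than the dark-state
lifetime, every schedule tiles the same ~2 ms span per row, and the two
repeated schedules are statistically
equivalent while the single 200 μs pass imprints dark periods directly;
an 8-point resolution sweep whose points are 10-QD means with 5% per-QD
scatter; 50+50 singles/clusters for classification; exact-truth
colocalization phantoms; and a 10% injected bleed-through recovery.
These sizes keep each study between milliseconds and ~1 minute.

## Limitations

- Exponential dwells understate the heavy (power-law) tails of real QD
  blinking; in particular, the gradual brightness decline the real
  instrument shows from 10 to 100 line repeats is not reproduced — under
  an exponential telegraph the two repeated schedules are statistically
  equivalent in the fast-line regime, so only the single-pass schedule
  stands apart (higher blinking ratio, higher apparent brightness).
- The blinking pixel ratio's absolute level depends on the blink-map
  cutoffs and on counts; the simulator reproduces orderings and
  occupancy trends, not the instrument's absolute ratios.
- The halo saturation depth `S` and the suppression factor are declared
  model parameters, not fitted to data.
- No photobleaching, triplet shelving beyond the two-state model, drift,
  detector dead time, or vectorial/3D PSF physics; vesicle masks are
  consumed as given; Richardson–Lucy deconvolution is out of scope
  (display-only upstream; all analysis runs on raw images).
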