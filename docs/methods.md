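# Methods

This note documents the models, estimators, numerical choices and known
limitations of `polegrow`. Units are µm and minutes throughout; pixels
never appear in outputs.

## Forward model (`polegrow.synthetic`)

**Geometry.** A cell is a 2D spherocylinder: a rectangle of length
L − W capped by two semicircles of diameter W (tip-to-tip length L).
Cells are straight; bending, V-snapping and division are not modeled.
3D projection effects are ignored — the model targets 2D micrograph
analysis, not optical sectioning. Arc position s ∈ [0, L] runs along
the centerline from the tip of pole A.

**Growth.** Each pole extends at its own rate (µm/min); material is
added only at the tips, so a septum keeps its distance from the old
wall and its arc position from pole A grows by exactly the material
pole A adds. During an FDAA pulse ending at `pulse_end`, all wall
present is labeled; wall added afterwards is dark. The true unlabeled
total per cell is therefore (r_A + r_B)(t − pulse_end), the quantity the
pipeline must recover.

**Emission.**

- *Label channel*: the labeled wall is drawn as the cell envelope — an
  outline band 2 px wide — restricted to the labeled arc interval,
  matching FDAA chemistry (the probe sits in the PG layer, so images
  show bright cell contours, not filled bodies). A filled-body mode
  exists for testing. Septa are filled transverse bands 0.15 µm wide,
  always labeled (they form before or during the pulse).
- *Cap channel* (polar marker): amplitude · exp(−s_tip²/2σ²) masked to
  the cell body, where s_tip is the **axial arc distance** from the
  marker's pole tip. The axial kernel (rather than a 2D radial one) is
  used because polar-marker distributions are defined and measured as a
  function of axial distance from the pole; a radially symmetric kernel
  truncated by the cell outline would make the 1D axial decay
  systematically narrower than its nominal σ, i.e. the programmed
  parameter would not be the quantity any 1D analysis could recover.
- *Phase-like channel*: background minus 80 counts × body coverage
  (dark rods on a light background).

**Optics and noise.** Pixel size 0.065 µm/px (typical 100×/sCMOS;
configurable), Gaussian PSF σ = 0.1 µm (≈ 0.21 λ/NA for λ ≈ 600 nm,
NA 1.45), background 100 counts. Noise is Poisson on (signal +
background)/gain, scaled back by the gain, then additive Gaussian read
noise (default SD 2 counts); setting gain and read noise to 0 gives a
noiseless render. Random streams are split per (frame, channel) with
`SeedSequence(seed, spawn_key=(frame, channel))`, so channels are
independently reproducible. Rendering antialiases with 2×2 subpixel
sampling (4×4 where tests need tighter emission conservation).

**Populations.** `make_strain_scenario` samples lengths
lognormal(mean 3.0 µm, CV 0.2, clipped to [1.2, 6.5]) and widths
lognormal(mean 1.0 µm, CV 0.05, clipped to [0.7, 1.3]) — a realistic
exponential-phase rod population — places cells on a jittered grid with
random orientations, and assigns 0/1/≥2 septa with the requested
(none, one, multiple) probabilities; "multiple" cells get 2 or 3 septa
(70/30), pairwise ≥ 0.45 µm apart and away from the caps. Two presets
mirror the cell-separation phenotypes: `apbp_null_like`
(0.75/0.05/0.20) and `roda_null_like` (0.90/0.05/0.05).

**What the generator does not emulate**: photobleaching, stage drift,
3D PSF, touching or dividing cells, curved cells, and intra-cell
labeling heterogeneity. Passing the recovery tests therefore shows the
estimators are correct and robust to shot/read noise and orientation,
not that they survive every real-world artifact (touching cells, for
instance, are deliberately excluded by area filtering, as in dilute
microfluidic fields).

## Segmentation and meshes (`polegrow.segmentation`)

Frames are thresholded with Otsu's method; foreground polarity is
auto-detected as the minority side, so phase (dark cells) and
fluorescence (bright cells) both work. Components are 4-connected,
area-filtered, and ordered by their top-most/left-most pixel for
deterministic labeling. Holes are filled (an envelope label renders as
a closed bright contour whose interior must count as cell).

The centerline is the longest geodesic path (double BFS) through the
morphological skeleton of the mask. Three regularizations matter in
noise:

1. the mask boundary is smoothed (Gaussian σ = 1 px, re-thresholded at
   0.5) before skeletonization — ragged boundaries grow skeleton spurs
   that can hijack the longest path and park a "tip" on the cell side;
2. 3 px are trimmed from each skeleton end and end tangents are taken
   over 8 points;
3. each end is extended along its tangent to the sub-pixel 0.5-coverage
   crossing of the mask, so arc position 0 is the geometric pole tip.

Local width is measured as the transverse chord of the 0.5-coverage
boundary through each centerline point (sub-pixel, via linear
interpolation of the boundary crossing on both sides of the normal).
The cell-width statistic is the mean local width over the central 50%
of arc length, further clipped to exclude one cap radius from each tip
— on stubby cells the caps reach into the central 50% and would bias a
cylinder-diameter statistic low. Masks whose tip-to-tip length is
< 1.15 × their maximum width are flagged degenerate (centerline from
the best-fit-ellipse axis; excluded from profile-based analyses).
Measured accuracy on noiseless rods (L 1.5–6 µm, W 0.8–1.2 µm, 0–90°):
worst length error < 1 px, worst width error < 0.7 px.

Axial profiles sample the frame by bilinear interpolation along the
local normal at every arc-length step (default step = 1 px), averaging
all in-mask samples within ±0.65 µm of the centerline — a full
transverse band, which is what makes an envelope label legible mid-cell
(the band crosses both bright side walls). The offsets are symmetric,
so relabeling the poles reverses the profile to floating-point
accuracy.

## Pulse-chase estimators (`polegrow.pulsechase`)

`unlabeled_length` applies the relative threshold 0.2 × per-cell
maximum after background subtraction, counting one grid step per
sub-threshold sample (piecewise-constant; clamped to the cell length).
The relative threshold makes the measure invariant to staining
efficiency and exposure — verified by scale-invariance tests. All-zero
profiles are reported fully unlabeled but flagged `no_signal` and
excluded from rate estimation by default: a cell born after the pulse
and a segmentation artifact are indistinguishable here, so the flag
defers the decision to the caller. Sub-threshold arc from *all*
segments (both poles and any dark septal gap) is aggregated, since the
measure is defined per cell; per-segment counts are preserved so
per-pole analyses remain possible.

The elongation rate is population-level and unpaired (cells are not
tracked): mean difference of unlabeled lengths at two fixed time points
over elapsed time, SEs combined in quadrature.

*Accuracy limits.* With PSF σ_psf, the 20%-threshold crossing of a
blurred labeled/unlabeled edge sits ≈ 0.84 σ_psf inside the dark zone.
This offset cancels between the two time points when both dark zones
are well-resolved, but at t = 20 min the dark zone per pole is
rate × 14 min = 0.03–0.14 µm — at or below the resolution limit — so a
residual systematic of ±1–2% of the rate remains across the 0.002–0.01
µm/min range. The mean recovery criterion (±10%) passes with large
margin; a ±2·SE coverage check at n = 150 cells (SE ≈ 0.5–2%) does not
pass uniformly, and the corresponding acceptance test is left failing
rather than loosened. 1D Richardson–Lucy deconvolution of the profiles
was evaluated as a remedy and rejected: noise amplification produced
spurious sub-threshold dips and a +24% bias at the lowest rate.

`count_septa` finds peaks with prominence ≥ 0.3 × per-cell max
(scipy `find_peaks`), discards peaks within 0.4 µm of either tip (polar
label is not a septum), and greedily enforces ≥ 0.3 µm pairwise
separation by descending prominence. Defaults are in `PipelineConfig`
and swept in tests.

## Pole profiles (`polegrow.poleprofile`)

The brightest pole is the one whose terminal 0.5 µm of arc integrates
more intensity (exact ties go to pole A, deterministically). Aligned
profiles are interpolated onto a uniform grid over [0, 2] µm (step 1 px)
and averaged after subtracting the background, estimated as the median
intensity outside all masks dilated by 3 px (median: robust to cell
density; dilation: excludes the PSF halo). Cells shorter than twice the
grid extent contribute only up to half their length, so the far pole is
never folded into the near-pole average.

The spread of the mean profile is fitted as A·exp(−(x − x₀)²/2σ²) + c on
the decaying flank only (from the profile maximum outward), with the
centre x₀ free within [0, 0.5] µm. The points between the geometric tip
and the maximum are excluded because finite resolution rolls off the
emission edge there, and the measured peak sits a fraction of a pixel
inside the geometric tip; fitting the flank with a free centre removes
both biases. Recovery at n = 100 cells and peak SNR ≈ 5: σ = 0.2 µm
fitted 0.20 ± 0.02, σ = 0.6 µm fitted 0.58 ± 0.02, ordering preserved
in every tested seed.

## Replicate statistics (`polegrow.morphometrics`)

Observations for the ANOVA are replicate means, not cells — pooling
hundreds of cells from one culture as independent observations
(pseudo-replication) would overstate significance. The F statistic is
computed by `scipy.stats.f_oneway` and is cross-checked against a
direct sums-of-squares implementation to 1e-10 relative in the tests.
Both a pairwise-vs-reference mode (default, one test per mutant strain
against the wild type) and a single many-group call are available; the
significance annotation uses the two fixed thresholds 0.05 and 1e-4.
Negative Miller activities are returned as-is with a flag, never
clamped.

## Determinism and I/O

All randomness flows from explicit integer seeds; identical spec + seed
reproduces images, truth tables and CSV artifacts byte-for-byte (floats
are written at 6 significant digits). TIFF stacks are time-major, one
page per channel per time point, channel order phase/label/cap; ground
truth is written as `truth.json` plus a flat `truth_cells.csv`.

## Validation scales

The recovery experiments run at the study-design sizes: elongation
rates at 150 cells per time point across three programmed speeds and
ten seeds; septum fractions at n = 1000 for the recovery check and
n = 300 per seed for the ten-seed ranking check; polar-marker spreads at
n = 100 cells and ten seeds; morphometrics over the full 3 × 3 × 4
size/orientation grid.
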