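# Methods

## The reduction problem

A NanoEDT acquisition records, at each goniometer tilt, a 2D grid of
diffraction patterns from a focused nanobeam (probe FWHM ~12 nm, scan step
40 nm, ~1 e⁻/Å² per frame at 300 kV).  Individual frames on an integrating
direct detector are sparse — a few thousand electrons spread over the
detector — so the reduction must (a) recover electron counts from analog
pixel values, (b) decide which scan positions belong to the crystal, and
(c) sum the selected patterns per tilt into series suitable for standard
crystallographic indexing.  This package implements that chain plus two
derived products: per-position thickness maps and Bragg-peak tables.

## Hybrid counting model

Detector model: pixel value = (electron arrivals) × g + dark + N(0, σ),
with g the single-electron gain in ADU and σ the Gaussian read noise.
Pipeline order is **align → dark → noise fit → quantize** (the order is a
package choice; the stages commute only approximately).

- *Alignment*: per frame, the centre of mass in a window around the
  brightest pixel (which must exceed the dark level by > 5σ, else the frame
  is flagged unalignable and left in place) is shifted by **integer**
  pixels onto the central detector pixel.  Integer shifts preserve counting
  statistics; subpixel interpolation would smear single-electron events.
- *Dark*: temporal per-pixel median across the scan.  Signal is sparse at
  any given pixel *except* under the primary beam, which sits on the same
  pixels in every frame; median values deviating from the bulk by more than
  5 robust widths (MAD, floored at 1 ADU against integer quantization) are
  therefore replaced by the bulk dark level.  This assumes the true dark
  map is smooth at the scale of the beam disc; for detectors with strong
  per-pixel dark structure, pass a genuine dark acquisition and
  `outlier_sigma=None`.  A spatial-median variant exists behind
  `method="spatial"`.
- *Noise fit*: a Gaussian is fitted to the central mode of the
  dark-subtracted histogram (bins within a robust-sigma window, so the
  positive electron tail is ignored).  Threshold = kσ with k = 4 by
  default.  If the gain is not supplied it is estimated as the mode of the
  above-threshold residuals — the single-electron peak; on the bundled
  simulations this recovers the configured gain within a few percent.
- *Quantization*: v ≤ kσ → 0; otherwise max(1, round(v/g)).  The max(1,·)
  guard means an above-threshold event always counts at least one electron
  even when v < g/2.  `binarize` (every above-threshold pixel → 1) is kept
  as the comparison baseline: with exact gain and no noise, hybrid counts
  equal true arrivals at any occupancy, while binary counting saturates —
  the coincidence-loss behaviour the acceptance suite checks.

## Virtual detectors and segmentation

A `VirtualDetector` is an annulus (inner ≤ r < outer) applied per scan
position.  Bright field (disc) + dark field (annulus to the edge) partition
the detector exactly, so their sum equals total counts — an integer
invariant used as a self-check.  The default ADF inner radius is 1.5× an
estimated beam radius.  The beam radius estimator walks azimuthal ring
*medians* of the aggregate pattern outward from the brightest pixel and
stops where the median falls to twice the background (outer-half ring
median, floored at half a count); medians make rings grazed by a few
Bragg-spot arcs still read as background.

Segmentation is Otsu thresholding (or an absolute threshold) of the
dark-field image, disc opening then closing (radius 1 by default),
8-connected labelling, and an area filter; regions are returned largest
first.  Manual polygon apertures (JSON vertex lists) are supported as the
hand-drawn alternative.

## Tilt series and dose arithmetic

Region-summed patterns are exact integer sums; the assembler sorts by tilt,
rejects duplicates and logs gaps for empty regions.  SMV export adds a
documented pedestal then clips to uint16, with the clip count logged.
OSC_RANGE defaults to 0 (stills); a discrete-angle series may set it to
the angular increment.

Exposure bookkeeping: probe area π(FWHM/2)², step area step², their ratio,
and nominal series dose n_tilts × dose/frame; for continuous-rotation
selected-area acquisition, dose = rate × range / angular-rate.  These are
closed-form and tested against the experiment's printed values (1600 nm²,
~113 nm², ~14×, 81 e⁻/Å², 3 e⁻/Å²).

`compare_magnitudes` matches reflections on identical (h,k,l) only —
symmetry merging belongs to external scaling software — filters at
I/σ > 2, rescales the matched sets to equal total intensity, and regresses
√I against √I.

## Thickness mapping

Z = λ ln(I₀/I) with λ = 332 nm (inelastic mean free path through the
peptide crystal).  I is the **transmitted** intensity: the raw,
dark-subtracted central-beam integral divided by the gain (the beam is too
coincident for hybrid counts to be honest there) plus hybrid counts in
discs (default radius 3 px) at Bragg peak positions — elastically
scattered electrons are transmitted electrons, and omitting them would
overstate thickness.  I₀ = mean − 2·std over a vacuum region; the 2σ
margin absorbs beam-current fluctuation at the cost of a small negative
thickness bias (pixels brighter than I₀ clamp to Z = 0, logged;
non-positive intensities are flagged invalid).  On simulations where
transmission is exp(−t/λ) by construction, the full route (noise fit →
counting → peak finding → transmission → inversion) recovers ground-truth
thickness to ~2% mean relative error; the residual comes from Bragg tails
outside the integration discs and the I₀ margin, which partially cancel.

`prepare_tilt_images` registers consecutive thickness maps by integer
phase correlation, crops to the common field of view, subtracts a flat
background from a vacuum strip and clips negatives — producing the stack an
external tomographic reconstruction would consume (reconstruction itself is
out of scope).  The real procedure aligned manually on support-film
features; cross-correlation is this package's stand-in.

## Peak localization

Patterns are block-summed by the bin factor (5 by default; counts conserved
on the cropped field), correlated with a flat circular template 6 binned px
in diameter (a Gaussian template is available), and local NCC maxima above
0.5 are kept with non-maximum suppression at one template diameter.  The
template sits in an odd window with a 2 px background margin — a disc
filling its whole window has zero variance and a degenerate score — and
NCC is set to 0 where the window hangs off the pattern edge, where it is
undefined.  Measured on synthetic data, spots ~1.2 binned px wide score
0.65–0.85 against this template while a pure-noise field tops out near
0.4–0.5, so the 0.5 threshold separates them; the threshold and suppression
radius are free parameters of the method (unstated in the source
experiment) and are exposed.

Coordinates map back to unbinned pixels at the bin centre
(binned·f + (f−1)/2).  Multi-crystal fields are separated without lattice
deconvolution: peaks are found independently in each region's summed
pattern, and each full-field peak is labelled with every region owning a
peak within a match radius ("unassigned" otherwise).

## Synthetic acquisition: what it emulates, and what not

The generator states the experimental world where values are on record:
40 nm step, 12 nm probe, 1 e⁻/Å²/frame, ±40° at 1° (the reduced 81-pattern
range; the raw acquisition spanned ±45°), 0.0197 Å wavelength, λ = 332 nm.
Free parameters the experiment does not pin down were chosen once as
plausible for a K2-class detector and peptide nanocrystals: gain 32 ADU/e⁻,
read noise 5 ADU, dark 100 ADU, background 0.005 e⁻/px/frame, 10% of
transmitted electrons diffracted into kinematically excited reflections,
Gaussian spots of σ 1.5 px, synthetic structure factors decaying with a
Debye–Waller-like envelope.  Diffraction is kinematic projection: a
reflection is excited when its tilted reciprocal vector's out-of-plane
component is below a tolerance (0.8 px); both beam and spots are attenuated
by exp(−t/λ), so the thickness model is exactly invertible up to counting
noise.  Coincidence is implicit: multiple arrivals in one pixel sum in the
analog value.

Scale: detector and scan sizes in tests are scaled far below the real
~1792 px K2-IS and 30×70×90 acquisition to fit CPU budgets; noise and dose
parameters are not scaled.  One consequence is geometric: the real bin-5 /
6-px-template peak-finder parameters presuppose spots tens of unbinned
pixels wide, as on the full detector.  The peak-finding validation world
therefore uses a 512 px detector with σ 6 px spots (≈1.2 binned px, the
regime those parameters imply); on small detectors, bin factor 1 with a
5 px template is the appropriate setting, as used in the thickness route.

Not modelled: dynamical scattering, partial coherence, detector MTF,
sample drift between tilts, support-film diffuse scattering.  A green test
therefore establishes the *reduction arithmetic* — counting, masking,
summation, inversion, localization — not the physics of real diffraction
intensities.

## Numerical choices

- Seeds fully determine output (single `default_rng` stream, fixed draw
  order); identical configs are bit-identical.
- Integer ADU: detector values are rounded to int; robust statistics use
  MAD with a 1 ADU floor against quantization collapse.
- Rounding in quantization is numpy's round-half-to-even.
- All count bookkeeping (region sums, binning, virtual images on counts)
  is exact integer arithmetic.
- The two-crystal default rotates the second lattice by 20°, which keeps
  the two reciprocal lattices ≥ 8 px apart at 24 px spacing (no
  near-coincident low-order reflections).

## Known limitations

- Temporal-median dark estimation needs the outlier guard (above) because
  the beam never moves in detector space; a measured dark reference is
  always preferable.
- `compare_magnitudes` does not merge symmetry equivalents.
- Thickness maps are only as good as the peak list: missing weak
  reflections biases Z upward by the missed elastic fraction.
- SMV export clips at 65535 after the pedestal; very strong summed
  patterns should be exported with a smaller pedestal or rescaled upstream.
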