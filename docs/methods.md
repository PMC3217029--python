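# Methods

## Physical model

The package treats a structurally colored tissue as a two-phase dielectric
(cuticle/chitin, n_high = 1.56 by default; air or embedding medium,
n_low = 1.0). Color arises from coherent scattering: a spatial-frequency
component *f* (cycles/nm) of the refractive-index variation constructively
back-scatters light of wavelength λ = 2 n̄/f at normal incidence, where
n̄ is the volume-weighted mean index of the analyzed region. The factor
2 n̄ is the round-trip optical path over one spatial period; with n̄
computed from the region's own fill fraction, the mapping reproduces the
ideal-bilayer thin-film fundamental 2(n₁d₁ + n₂d₂) identically for exact
periodic stacks, which is the anchor of the cross-module oracle tests.

Assumptions: normal incidence; non-absorbing, dispersion-free real indices;
a two-phase material (no partial-density voxels — the segmentation forces a
hard assignment); the analyzed crop is representative of the structure
producing the color. Off-normal (angle-resolved) reflectance, iridescence
suppression by curvature or perforation, and macro-scale effects such as
scale tilt or stacking are outside the model.

## Pipeline stages and numerical choices

**Segmentation.** Otsu's threshold by default (parameter-free, correct for
well-separated bimodal histograms); a fixed threshold is available for
low-contrast material. The brighter phase maps to high-index; an `invert`
flag handles the opposite contrast polarity. A constant image is rejected as
degenerate rather than guessed at.

**Power spectrum.** The mean is removed before the transform (the DC bin
carries no structural information and would dominate), the spectrum is
centered, and power is normalized as |F|²/N so that total power equals the
sum of squared mean-removed index values (Parseval). Input must be square;
crop first. No apodization by default — windowing changes peak widths, not
positions, and the peak position is the quantity of interest; a Hann window
is available as a flag.

**Radial average.** Annuli of width one frequency step (1/(N·pixel_size),
configurable) centered on integer multiples of that width, so an
axis-aligned harmonic of an exactly periodic structure falls on a bin
center. Mean power per annulus is the default statistic; the annulus sum is
available. Power is also expressed as percent of total so profiles from
crops of different sizes are comparable. Bins extend to the spectrum corner
so the percentages sum to 100.

**Peak extraction.** λ_max is found on the frequency axis (argmax of
annulus power) and refined by a parabola through the peak bin and its two
neighbors, clamped to ±half a bin; a raw-bin option disables refinement.
The refined frequency is then mapped to wavelength. λ_max is reported both
restricted to the visible band (350–700 nm — the headline value) and
unrestricted; structures whose fundamental lies in the near infrared
(e.g. 150/141 nm stacks peaking at 750 nm) are only visible through the
unrestricted value, while the restricted value picks up their second
harmonic.

**Color.** A single dominant wavelength has no unique RGB; three
conversions are averaged component-wise (rounding half-up): Dan Bruton's
piecewise-linear approximation (380–780 nm, edge intensity fall-off,
gamma 0.8); a CIE-based conversion using the analytic multi-lobe Gaussian
fit of the CIE 1931 2° color-matching functions (Wyman, Sloan & Shirley
2013), converted to linear sRGB with out-of-gamut components clipped to
zero, brightness-normalized, and sRGB-encoded; and the Bruton formula at
gamma 1.0 as a third, gamma-variant opinion. Outside 380–780 nm all methods
return black. Caveat: below ~470 nm the monochromatic locus lies far outside
the sRGB gamut, and clipping exposes the red lobe of the CIE x̄ function
that the piecewise formula lacks, so the two methods' component rank orders
agree only from the blue-green region upward; their dominant components
agree (up to ties at hue boundaries such as cyan at 490 nm) across
450–650 nm.

**Closed-form optics.** `ideal_multilayer_peak` gives the infinite-stack
fundamental 2(n₁d₁ + n₂d₂). `transfer_matrix_reflectance` evaluates the
standard characteristic-matrix product per layer (phase δ = 2π n d/λ,
matrix [[cos δ, i sin δ/n], [i n sin δ, cos δ]]) with real indices, giving
normal-incidence reflectance in [0, 1]; finite chitin/air stacks of ~5
bilayers peak at the design wavelength but well below 100% reflectance
(a non-ideal reflector), and the peak grows and sharpens with bilayer
count. `propagating_orders` counts the integers m ≠ 0 with
|sin θᵢ + mλ/d| ≤ 1 — existence of orders only, no efficiencies, which is
all the sub-wavelength argument needs.

**Replicate aggregation.** Zone λ_max is the arithmetic mean over replicate
images (median available); the report records all replicate values, their
range, and per-replicate n̄, so either summary can be recomputed.

## Synthetic data: what it emulates and what it does not

The generator emulates TEM cross-sections of the scale-lumen architecture:

* **Multilayers** — horizontal bands of alternating intensity with per-layer
  thicknesses in nm. Realistic lamina thicknesses for this system are
  93–124 nm (uppermost) thinning to 55–63 nm; air-gap thickness is a free
  parameter. Layer boundaries use cumulative rounding (running-sum in
  pixels) so period-length error never exceeds 1 px regardless of period
  count. Optional concave curvature displaces band midlines by the sagitta
  of a circular arc; Gaussian noise is added after geometry and clipped
  (not wrapped) at 0/255. The recorded ground truth includes the exact
  period, fill fraction, and ideal peak 2Σnⱼdⱼ.
* **Perforated laminae** — binary rasters with circular holes on a square
  grid (optionally jittered; a jitter that would push a hole across its
  grid cell is an error, not a clamp). Ground-truth open fraction is the
  rasterized pixel count, which converges to πr²/pitch² with resolution.

Not emulated: stain gradients, section-thickness and microtome artifacts,
partial-volume gray levels, 3-D photonic-crystal geometries, or the
bead-like inter-lamina spacers. Passing tests therefore demonstrate the
correctness of the computation on ideal two-phase geometry — segmentation
robustness on real TEM contrast must be judged per dataset (the fixed
threshold and invert flags exist for that reason).

All generators take an explicit integer seed (default 0) and are
bit-reproducible.

## Problem sizes and defaults

Synthetic validation stacks use 5 periods at 1 nm/px, giving square rasters
of roughly 900–1600 px per side — large enough that the fundamental sits
5 frequency bins from DC and the bin-to-wavelength tolerance is a few
nanometers, small enough that an analysis completes in well under a second.
Randomized oracle checks draw layer thicknesses uniformly from 40–160 nm.
The lamina fixtures (500×500 px, pitch 50/radius 16; 504×504 px, pitch
63/radius 8) give open fractions 0.325 and 0.050 against analytic values
0.322 and 0.051.

## Known limitations

* The frequency grid is coarse relative to wavelength at low f: one bin at
  f = 5Δf spans tens of nanometers in λ. Parabolic refinement mitigates
  this for dominant peaks; for noisy spectra with broad peaks, analyze a
  larger crop instead.
* n̄ from the crop's fill fraction is only as good as the segmentation;
  systematic thresholding bias shifts λ_max proportionally to the induced
  error in n̄ (at fill ≈ 0.5 a 1% fill error shifts n̄ by ~0.006, i.e.
  λ_max by ~0.5%).
* The visible-band restriction can report a harmonic when the fundamental
  lies outside 350–700 nm; always inspect the unrestricted value too.
* RGB output is a display approximation of a dominant wavelength, not a
  colorimetric rendering of the full predicted spectrum under an
  illuminant.
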