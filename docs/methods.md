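# Methods

This note documents the models implemented in `viffi`, the choices made
where the design was genuinely open, and what the synthetic-data studies do
and do not demonstrate.

## Optical-design constraint solver (`viffi.instrument`)

A polygon scanner placed in the Fourier plane of the fluorescence path
cancels the image motion of cells flowing at speed *v*. One facet can sweep
the image over at most

    L_max = 4 f_o M { 2π/N + asin[(−d_obj·M/d_poly + sin α) cos(π/N)]
                           − asin[( d_obj·M/d_poly + sin α) cos(π/N)] }

in the object plane: the full facet angle 2π/N minus the fractions lost
while the de-magnified beam footprint (diameter d_obj·M) enters and leaves
the facet at incidence α. Both arcsine arguments must lie in [−1, 1];
outside that range the geometry is infeasible and the solver raises rather
than clamping.

**Exposure cap.** The camera's field of view co-moves with the flow during
the exposure, so the scan range is shared between the scanned image and the
advancing flow; we define the exposure cap as `L_max/(2v)`. For the
reference design L_max = 838.5 µm and the cap is 419 µs (420 µs to the
nearest 10 µs), consistent with the operating exposure of 340 µs. The /2
convention is a modelling choice: it is the unique simple rule that
reconciles the scan-range equation with the instrument's stated exposure
limit, and it is documented here rather than hidden in the code.

**Magnification window.** Frame concatenation without dead area requires
M > v·T_s·N/(4π f_o); keeping the swept image on the sensor requires
M < L_x·N/(4π f_t). For the reference parameters the window is
(0.198, 0.205) and the chosen M = 0.2 sits inside it.

**Facet fit.** The facet width of a polygon characterized by its inscribed
(inner) diameter is d_poly·tan(π/N) = 7.89 mm; the beam footprint
d_obj·M = 2.7 mm must be strictly smaller. Only the qualitative constraint
is prescribed by the instrument concept; the inscribed-circle formula is
our geometric reading of "inner diameter".

**Timing budget.** Line-wise sensor readout takes
L_x·N_y/(f_p·d_pix) = 393 µs; readout + exposure must fit in the frame
period T_s = 800 µs, and the exposure must respect the scan cap. The
frame-to-frame overlap l₀ is not printed anywhere for the reference system;
we default it to 30 µm because that value makes
(FOV_x − l₀)/v = (830 − 30)/1 µs equal T_s exactly. It is an exposed
parameter, not a constant.

**Microfluidics.** The hydrodynamically focused sample core is modelled
with the equal-mean-velocity (plug) approximation: core area =
channel area × ratio/(1 + ratio), diameter of the equivalent circle. A
400×250 µm channel at 1:700 gives 13.5 µm (≈13 µm); at 1:3900, 5.7 µm.
Flow-speed uniformity across the core uses the rectangular-duct laminar
Fourier series (120 odd modes, expansion along the smaller half-dimension,
overflow-safe exponential form, convergence verified against a 40-mode
refinement at 10⁻⁶ relative tolerance); the relative variation
(v_max − v_min)/v_max over the centered core disk is 0.26% for the
reference chip — comfortably below the 1% level at which residual motion
would defeat the polygon cancellation.

## Throughput model (`viffi.throughput`)

The effective line rate v/p_x (3.08 MHz at 1 m/s and 0.325 µm) is the
spacing-independent speed metric; cell throughput is
f_th = p_x·f_x/l_cell (10,000 cells/s at 100-µm mean spacing; ~400 cells/s
for a TDI readout capped at 0.12 MHz — a factor of 26). The frame-period
identity

    (L_x/M − l₀)/v ≈ L_x·N_y/(f_p·d_pix) + t_exp1

is used both as a residual check of an operating point and, inverted over
integer N_y (ties broken downward, cap at the full sensor height), as the
FOV_y-vs-flow-speed trade-off. At the reference point the identity closes
to <1 µs with N_y = 88 and t_exp1 = 407 µs; note that 88 lines correspond
to a 407-µs transfer-limited exposure, while the 340-µs operating exposure
deliberately leaves headroom below both caps. Recording capacity divides
the acquisition storage (1 TB) by the frame size (2554×88 px × 2 B ≈
0.44 MB) and multiplies the resulting duration by the throughput: ≈18
million cells without interruption.

## Sensitivity model (`viffi.sensitivity`)

Per-pixel signal S ~ P·C⁻¹·T·n·s·η_yield·η_img·η_sensor (electrons) and
SNR = S/√(S + σ²). The virtual-freezing improvement factorizes as:

* exposure extension 1/(residual + fluctuation): the exposure can grow until
  accumulated image drift reaches a pixel. Residual image speed is ±1.5% of
  v with the beam scan, ≥±6% without; cell-to-cell flow fluctuation is
  ±1.5%. Hence ≈33 with the scan, ≈13 without.
* excitation confinement: a 26-µm beam in an 830-µm FOV concentrates the
  same excitation power into ~3% of the field, a gain of 1/0.03 ≈ 33. The
  confinement fraction is rounded to one significant figure before taking
  the reciprocal — the factor is order-of-magnitude by nature.

Together ≈1000 with the beam scan. The local exposure time of a scanned
beam is width/relative-speed = 26/2.54 ≈ 10 µs; the blur-free limit without
freezing is p_x/v ≈ 0.3 µs.

The modality comparison parameterizes exposure rules (fixed 340 µs for
frozen imaging with a 0.9 derating for scanner/relay losses; n_stages·p_x/v
for TDI, feasible only below the 0.12-MHz line-rate cap; p_x/v for
stroboscopic illumination). Exact sensor parameters of the commercial
comparators are not public; the shipped presets use documented typical
values (sCMOS: QE 0.6, σ = 2 e⁻; TDI-CCD: QE 0.6, σ = 30 e⁻) and every
field is overridable. Because the absolute photon scale P·s/C is a free
parameter, only ratio and limit statements are asserted anywhere in the
package — e.g. the frozen-vs-stroboscopic SNR ratio at 1 m/s is
√(0.9·340/0.325) ≈ 31 in the shot limit, and adding any common readout
noise only increases it.

## Frame renderer (`viffi.simulate`)

**Image formation.** Each emitter's photon flux is (i) weighted in time by
the excitation profile — uniform for full-field illumination, or a Gaussian
light sheet (e⁻² width 26 µm) scanned at 2.54 m/s relative to the cells,
normalized to conserve total excitation power relative to uniform
illumination, which is what makes the confinement gain emerge physically
rather than by fiat; (ii) translated at its residual image velocity;
(iii) convolved with an isotropic Gaussian PSF, σ = 0.21·λ/NA (148 nm at
λ = 530 nm, NA = 0.75) — a standard widefield approximation chosen because
no PSF model is prescribed for the instrument; (iv) detected with Poisson
photon statistics (exact below mean 1000, Gaussian approximation above),
quantum efficiency 0.6, Gaussian readout noise 2 e⁻ RMS, and 16-bit
quantization at unit gain.

**Residual motion.** Only the range of the residual image speed is known
(±1.5% of v with the beam scan, ±6% without). We model its spatial
structure as an odd linear ramp across the FOV (zero at center, ±amplitude
at the edges); the ramp shape is a modelling choice and is parameterizable.
Per-cell flow fluctuation is Gaussian with σ = bound/2, truncated at the
±1.5% bound. In modes without motion cancellation the image simply moves at
v(1 + fluctuation).

**Numerics.** Per emitter the drift is a uniform translation, so the
temporal integral collapses to a 1-D convolution of the static raster with
a drift kernel built from the excitation time-weights. Rasters are
supersampled 4× (81-nm subpixels); the time step is 0.5 µs, refined
automatically so no step moves the image more than half a subpixel (fast
streaks stay contiguous). Photon conservation holds to 10⁻⁶ relative for
emitters away from frame borders; emitters drifting out of the FOV are
clipped, not errors. With the scanned beam, an emitter's photons are
deposited around its position at *beam-passage time*, which differs from
its nominal position by drift × passage-time (up to several µm at the FOV
edges); the renderer therefore reports illumination-weighted ("rendered")
ground-truth positions alongside the nominal ones, and all validation is
against the rendered positions.

**Phantoms.** Three families, sized from the organisms they emulate:
lymphocyte-like (radius 3.8–5.2 µm, one round nucleus at 0.8× cell radius),
neutrophil-like (radius 4.2–5.8 µm, 3–4 nuclear lobes of 0.30× radius at
0.50× radius from center plus a small central bridge disk so the nucleus is
one connected component), and Euglena-like algae (ellipses 36–50 µm long,
8–12 µm wide, with BODIPY-like lipid droplets of radius 0.3–1.5 µm).
Droplets are solid lipid bodies and are placed with a hard-sphere
non-overlap constraint; their count per cell is Poisson (defaults 5 for the
nutrient-replete condition, 12 for the nitrogen-starved one). Scenes place
cells along the flow axis with i.i.d. exponential spacings (mean 100 µm by
default — a Poisson line process, matching the 50–100 µm operating regime);
fluorophore densities are arbitrary units since the absolute per-cell
photon budget is a free scale.

**What the generator does not emulate.** Cell rotation and deformation in
flow, 3-D defocus and depth-of-field, chromatic effects, polygon
facet-transition artifacts, autofluorescence background, and staining
heterogeneity. Passing the population-level tests therefore shows that the
*pipeline* recovers the generating parameters under the stated noise and
blur physics — not that it would do so on real cells, where these
unmodelled effects add variance.

## Image analysis (`viffi.analysis`)

* **Segmentation**: Otsu global threshold, morphological closing (radius
  1 px), hole filling, removal of components below 20 px — all
  configurable; "standard segmentation" is unspecified upstream, so these
  conservative defaults are our choice.
* **Enclosing-box ratio**: nucleus area over the area of the minimum-area
  *rotated* rectangle of the mask's pixel-corner point set (convex hull +
  rotating calipers via shapely). A brute-force 0.1°-step rotation search
  is kept in the test suite as an independent oracle (agreement < 10⁻³).
  Round nuclei score near π/4 ≈ 0.785; lobulated ones markedly lower. An
  axis-aligned reading of "smallest box" would not be rotation-invariant;
  the rotated rectangle is the default.
* **Droplet counting**: a pixel is a candidate if it is the maximum of the
  droplet-size window centered on it and exceeds the minimum over the
  surrounding annulus (1×–2× the window) by more than the contrast
  threshold; plateau ties resolve to the plateau centroid. The window
  should match the droplet scale — 8 px (2.6 µm) for the 0.6–3 µm droplets
  of the algal phantoms; a window much smaller than a droplet yields
  duplicate peaks, much larger merges neighbors. The intensity threshold is
  deliberately a required parameter of the CLI: no universal value exists.
* **Droplet areas**: the droplet channel is binarized at a fixed absolute
  threshold (set a priori together with the droplet size, like the count
  threshold) and split by marker-based watershed using the detected peaks,
  so two touching droplets separate along their intensity valley. Mean
  droplet area per cell is NaN — not 0 — when no droplet is found. Using a
  per-image adaptive threshold here would couple the area statistic to the
  droplet count and bias between-population comparisons; the fixed
  threshold avoids that.
* **PSF fitting**: 1-D Gaussian-with-offset least squares on the x and y
  profiles through the brightest pixel; initialization from image moments,
  offset initialized at the 5th percentile; non-convergence returns a
  flagged record. Widths are reported as FWe⁻¹M = 2√2·σ. On rendered bead
  fields (130 beads, frozen mode, ±1.5% residual ramp) the mean x−y width
  difference is well below one 325-nm pixel and the median localization
  error is <0.2 px.

## Problem sizes in the checked studies

The test suite renders 130–150 beads per bead-field study and 200 cells per
group in the two population studies (lobulated vs round nuclei on a
52×52 µm crop; droplet-count 5 vs 12 on a 110×65 µm crop). These sizes give
Mann–Whitney tests ample resolution at α = 0.01 for the simulated effect
sizes while keeping a full run of the suite under two minutes on one CPU.
Full-scale studies (10⁴ cells per group) are a matter of looping the same
per-cell function.

## Known limitations

* The /2 convention in the exposure cap is a reconstruction; a different
  reading of how the scan range is shared would rescale the cap by an O(1)
  factor.
* The residual-motion ramp is the simplest shape consistent with the known
  range; real field-dependent distortion will have structure the simulator
  does not reproduce.
* The droplet counter resolves droplets no closer than roughly the window
  size; counts in crowded cells are biased low, and droplet pairs with an
  unresolvable gap inflate the area statistic slightly even after
  watershed splitting.
* CNN-based cell classification and embedding are out of scope; the
  pipeline exports CNN-ready per-cell crops and feature tables instead.
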