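# Methods

This note documents the physical model, the numerical conventions, the
parameter choices that matter, and what the synthetic experiments do and
do not demonstrate.

## Optical geometry

The instrument modeled is a two-lens microscope (10x objective, NA 0.25,
200 mm tube lens) illuminated by a 16x24 LED matrix with 4.7 mm pitch.
The magnified pixel size is camera pitch / magnification (5.86 µm / 10 =
0.586 µm). The LED array is monochromatic red in hardware but has no
published emission wavelength; the toolkit defaults to **λ = 0.63 µm**,
configurable everywhere and recorded in every report.

An LED at lateral radius r and distance d illuminates the specimen at
NA = sin θ = r/√(r² + d²). The widely quoted small-angle form NA ≈ r/d
is available as a `paper_literal` mode for cross-checking published
numbers, but it exceeds 1 for r > d, so the exact sine is the default
and is used in all internal computations. The coherence parameter is
σ = NA_illumination/NA_objective.

**LED distance for the DPC studies.** The darkfield characterization
distance of this class of instrument is 110 mm. At 110 mm, however, the
16x24 grid's farthest (corner) LED reaches only σ ≈ 2.0, so the
operating point σ = 2.1 cannot be realized there. The simulated DPC
studies therefore place the same array at **d = 100 mm**, where integer
half-pattern radii of 6, 9 and 14 LEDs realize σ = 1.09, 1.56 and 2.17
for requested values of 1.0, 1.5 and 2.1 (`sigma_to_led_radius` always
rounds up, so a requested σ is a lower bound on the realized one).
Darkfield procedures keep the 110 mm default. Patterns whose nominal
radius overshoots the grid clip to the grid with a warning; the 16-row
direction clips before the 24-column direction, exactly as on the
physical array.

**Pattern conventions.** Half-patterns light LEDs strictly on one side
of the dividing axis; on the even 16x24 grid no LED sits on the axis, so
opposite halves are disjoint and union exactly to the full circle.
Annuli are half-open (inner ≤ radial index < outer) so adjacent annuli
tile without overlap. Radial index is the Euclidean distance from the
grid center in LED units. A lateral `center_offset` displaces the
physical LED positions (not the lit mask), which is how an uncentered
array is simulated.

## Image formation

Two forward models share one discretization:

* **Abbe (exact, the oracle).** Each lit LED contributes
  |IFT[P(u+u_j)·FT(t)]|², with t = exp(−μ)·exp(iφ) the complex
  transmittance, P the binary pupil (cutoff NA/λ), and u_j the LED's
  tilt frequency evaluated from its exact geometry. LEDs are mutually
  incoherent with equal radiance (no angular falloff — the thin beads
  and cells of interest sit near the axis, and measured LED panels are
  Lambertian enough over ±30° that the flat approximation is second
  order for these studies). LEDs outside the pupil contribute only
  scattered light, which is the physical darkfield signal; the empty
  field under such illumination is numerically zero.
* **Weak-object linearization.** For point-source illumination the
  absorption/phase transfer functions are discrete source–pupil
  correlations, h_abs = −Σ[P(u+u_j) + P(u−u_j)],
  h_ph = i·Σ[P(u+u_j) − P(u−u_j)], dc = number of in-pupil LEDs. No
  transfer-function formula is transcribed from anywhere: correctness is
  *defined* by agreement with the Abbe oracle, and the test suite checks
  the defining property — the discrepancy between the two models is
  second order (halving the specimen phase halves the AC-relative
  error).

All FFTs are unitary; frequency grids are cycles/µm in FFT layout,
derived from the pixel size. The Abbe model pads the field ~10% with an
edge-replicated, cosine-tapered extension (decaying to vacuum) and crops
after imaging, suppressing periodic wrap-around. Simulation is
monochromatic; LED spectral bandwidth is not modeled.

**Camera model.** Normalized intensity → Poisson shot noise at
`photons_at_unity` expected photons per unit background, plus Gaussian
read noise, plus a fixed offset, quantized to the configured bit depth.
All draws derive from explicit seeds; identical seeds give identical
frames. The defaults used in the characterization procedures (10⁴
photons, read sd 5 counts, offset 100 counts, 16 bit) describe a
well-exposed machine-vision camera.

## DPC phase retrieval

The four half-images pair into two axes (the `axis_angles` convention:
90° → top/bottom, 180° → left/right — the angle names the normal of the
dividing axis, and an orientation test pins the sign: a bead must
reconstruct with positive phase). Each pair forms the pixelwise
normalized signal DPC = (I_a − I_b)/(I_a + I_b); zero-sum pixels are
masked and reported. The camera offset (from the dark frame) is
subtracted first. Both axes are inverted jointly:

    φ = Re IFT[ Σ_k conj(H_k)·FT(DPC_k) / (Σ_k |H_k|² + reg2²) ],
    H_k = (h_ph,a − h_ph,b) / (dc_a + dc_b)

**Regularization convention.** The Tikhonov parameter enters the normal
equations squared — the textbook form of min ‖HΦ−D‖² + reg2²‖Φ‖².
With dc-normalized transfer functions (peak |H| ≈ 0.9 for half-circle
DPC), this means the operating values reg2 = 1e-3 (default) and 0.004
(used with the coherence sweep) suppress only frequencies where the
stacked transfer magnitude falls below ~reg2, leaving the bead band
intact; under the alternative reading (penalty added unsquared) those
same values would attenuate a 5 µm bead's optical volume by tens of
percent, which contradicts how these operating values are known to
behave on bead standards. Sweeping reg2 over 1e-4…1e-1 reproduces the
expected behavior: monotone shrinkage of recovered optical volume, with
a single best value balancing noise against bias.

**Null space.** H_k(0) = 0, so the absolute phase offset is not
recoverable; the retrieval leaves the field mean at zero and downstream
measurement subtracts the empty-region median instead. No phase
unwrapping is performed: the bead standards are designed so peak OPL
stays below λ/2 (a 5 µm bead with Δn = 0.023 peaks at 0.23 µm < 0.315
µm), and phantoms that would wrap trigger a warning at generation time.

## Phantoms

* **Beads** (the workhorse): non-overlapping spheres of n = 1.583
  (polystyrene) in n = 1.56 (NOA73), Δn = 0.023. OPL(ρ) =
  Δn·2√(R²−ρ²); analytic optical volume Δn·(4/3)πR³ = 12.04 µm³ for
  R = 5 µm. Pixels are sampled at their centers (origin at the top-left
  pixel center); bead edges are anti-aliased by 4x4 subpixel averaging,
  which brings the discrete OPL integral within 0.1% of the sphere
  identity at 20 px per diameter. The default radius of 5 µm and field
  of 512² px at 0.586 µm/px are free choices (several beads fit the
  field of view and the weak-phase criterion holds); bead diameter is a
  free parameter of these studies, not a reproduction of any particular
  bead lot.
* **Ruler**: absorption-only graduation lines (Gaussian profile) every
  10 µm, doubled at 100 µm multiples — a stage micrometer for the
  pixel-size calibration.
* **Cell-like blobs**: smooth compact random bumps capped below λ/2,
  for demonstration only.
* **Time series**: beads in cured polymer are static, so frames are
  pixel-identical before imaging; temporal variation enters through
  per-frame noise seeds spawned from one parent seed.

## Measurement

Segmentation thresholds the background-subtracted phase with Otsu's
method to find seeds, then grows each seed down to 10% of its own peak
phase. The hysteresis step matters quantitatively: a projected sphere's
phase profile is steep at the rim, so the Otsu contour of an ideal bead
sits at ≈0.87 R (biasing d_eq³ by ~35%), while the 10%-of-peak contour
sits at 0.995 R. With it, the equivalent-area diameter
d_eq = 2√(A/π) tracks the true diameter to a few tenths of a percent.
Components under 50 px or touching the border are removed.

Optical volume integrates OPL·pixel-area over each label after
subtracting the empty-region median. The refractive index is recovered
globally, n = n_medium + OV/((4/3)π(d_eq/2)³), rather than from the
center-pixel OPL — it uses every pixel and matches how optical volume
is validated. Bead tracking across frames matches nearest centroids
with a 5 px gate. Dry mass converts optical volume through the specific
refractive increment, OV/α with α = 0.18 µm³/pg (1.8·10⁻⁴ m³/kg).

Darkfield SNR is region-based: (μ_bead − μ_empty)/σ_empty, with the
bead mask from Otsu's threshold and the empty mask its complement
eroded by 5 px.

## Characterization procedures

* **Centering**: the four empty-field half-images must agree; pass
  means every half mean lies within ±1 dark-frame sd (the noise-floor
  definition: dark-frame mean ± one sd) of the combined mean, where the
  combined mean averages the four image means. A two-LED (9.4 mm)
  offset fails by three orders of magnitude, dominated by the offset
  axis.
* **Pixel calibration**: line profile perpendicular to the ruler
  graduations, mean removed, Hann window, dominant non-DC power
  spectrum peak with sub-bin parabolic interpolation; ties within 1% of
  the peak resolve to the lowest frequency (the fundamental). pixel
  size = known spacing × peak frequency (cycles/pixel). Recovery is
  within 0.01% on simulated rulers at 0.4/0.586/0.8 µm pixels; the
  procedure refuses profiles with no peak ≥ 5× the median spectral
  power or spanning fewer than 8 periods.
* **Coherence sweep**: optical volume vs σ at fixed reg2 = 0.004.
  Accuracy degrades sharply below σ ≈ 1.5 (at σ = 1.0 the error is 2–4x
  the σ = 1.5 error on the same phantom and seed): with less angular
  averaging the strong-phase nonlinearity of the 2.3 rad beads is
  exposed. σ ≥ 1.5 keeps the mean OV within 5% of the analytic value.
* **Regularization sweep**: one acquisition re-reconstructed across
  reg2 values; rows differ only in reg2.
* **Darkfield design**: empty-field annular background vs inner radius,
  against the dark-frame floor. The background collapses to the floor
  exactly at the first radius whose exact inner NA exceeds the
  objective NA (7 LEDs at 110 mm).

## Problem sizes and determinism

The validation experiments run at the instrument's native 512² frame;
unit tests use 64–256² fields, which the physics does not distinguish
(the transfer functions depend on physical frequencies, not on the
grid). Every stochastic step — bead placement, photon noise — draws
from numpy Generators seeded through `SeedSequence` spawning, so every
pipeline, sweep and CLI verb is bit-reproducible from one integer seed.

## Known limitations

* Thin-specimen (projection) approximation: no 3-D scattering, no
  defocus stacks; the linearization additionally assumes weak phase and
  is used only for retrieval, never as the simulation oracle.
* Ideal binary pupil: no aberrations, no apodization of the objective.
* Equal-radiance LEDs, monochromatic light.
* The recovered optical volume carries an irreducible few-percent
  deficit from the DC null space of DPC (partially offset, for strong
  phantoms, by the nonlinearity of the exact images); the refractive
  index, being a ratio of optical volume to mask-derived sphere volume,
  is far less sensitive and recovers to ≲0.1%.
* Synthetic phantoms have exactly known geometry and index; real bead
  lots have size and index dispersion, debris and mounting gradients.
  Passing these tests certifies the processing chain, not a physical
  instrument.
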