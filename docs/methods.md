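# Methods

This note documents the models, conventions and numerical choices behind
`wfpi`, in the spirit of the methods documentation of statsmodels or
msprime: what is computed, under which assumptions, and what the defaults
mean.

## Sensor model

The package treats the eye (or any transparent sample) geometrically: a
wavefront W(x, y), in metres of optical path over the pupil, tilts each ray
by ∇W, so a ray through pupil position q arrives at the acquisition planes
at q ∓ Δz·∇W(q)/s (in pixels; s is the pixel pitch, Δz the half-separation
between each plane and the conjugated pupil plane). I₁ is the plane at −Δz,
I₂ at +Δz. This is adequate when Δz is small compared with the Rayleigh
range of the aberration scales involved, which holds for ocular aberrations
at the millimetre plane separations used here; diffraction (wave-optical
propagation, speckle) is deliberately out of scope — the instrument class
this emulates uses incoherent light precisely to avoid speckle.

The conversion between a measured per-pixel displacement φ (pixels, between
the two planes) and the metric gradient is φ′ = s²/(2Δz)·φ, metres of
optical path per pixel step.

## Gradient recovery: directional cumulative-profile matching

For each of k angles uniformly covering (−π/2, π/2] (spacing π/k), the
image is sampled along the complete family of parallel lines at that
angle — one line per unit intercept along the minor axis, parameterised at
unit steps of the major axis to avoid the tan α singularity; samples are
bilinear. Cumulative sums along each line give non-decreasing profiles, and
the displacement between the I₁ and I₂ profiles of the same line is the
1-D optimal-transport map between the two flux distributions, computed by
monotone piecewise-linear inversion after normalising each pair to a common
total (per-line normalisation; flux may genuinely enter or leave a line
between planes).

Numerical conventions of the inversion:

* **Mass-centre convention.** Sample t's displacement is read at the
  half-mass quantile (F(t−1)+F(t))/2 with the CDF knots at half-integer
  positions. This makes identical profiles give exactly zero displacement
  at every sample, including at the profile total.
* **Flat segments.** Where the target profile is flat the inverse is an
  interval; its midpoint is used (unbiased under symmetric noise).
* **Validity.** Samples whose local flux is below 10⁻⁶ of the line total
  are flagged invalid; whole lines carrying less than 10⁻⁹ of the strongest
  line's flux are treated as numerical dust and skipped.

Each valid sample is converted to an arc-length displacement and deposited
by bilinear splatting at the *midpoint* between its source and destination
positions — for geometric propagation the midpoint is exactly the
pupil-plane position of the ray, which removes the apparent pupil-size
difference between the two defocused planes. Samples are weighted by the
flux they transport. Per pixel, the angular projections are combined by
weighted least squares: the accumulated cos α/sin α-weighted sums with the
exact 2×2 normal-matrix normalisation, which has unit gain for a rigid
shift by construction (a fixed uniform gain would otherwise have to be
calibrated once on a simulated tilt). A pixel is masked out when its
accumulated splat weight falls below 30 % of the median coverage or its
angular sampling is too one-sided to invert.

### Iterative refinement

A single application of this operator is exact for flux that moves rigidly
along each line family, but where flux converges or diverges *across*
lines — the radial flow of defocus is the canonical case — chords of the
pupil lengthen or shorten between the planes and the per-line transport
overestimates the displacement by a radially growing factor
⟨cos²θ/(1−ρ²sin²θ)⟩/⟨cos²θ⟩ (about +20 % averaged over a disk). The
recovery therefore iterates: both images are warped half-way toward the
pupil plane with the current estimate (mass-conserving bilinear transport,
with one Picard step so the displacement is evaluated at the displaced
position), the residual displacement between the warped images is
re-measured with the same operator, and the estimate is corrected.

Two details keep this fixed-point iteration stable:

* The warp field is **parametric**: the estimate projected onto the
  analytic gradient basis of the first 66 Zernike modes over the detected
  pupil. The raw per-pixel estimate carries chord-end artifacts at the
  pupil rim (standard deviations of a fraction of a pixel) which, fed into
  the warp, stretch every chord and rectify into a spurious low-order dome;
  the polynomial field is smooth across — and, being polynomial, defined
  beyond — the rim.
* **Tip/tilt is frozen** at the first pass. The one-shot operator is
  already exact for rigid shifts, and re-measuring images warped by an
  imperfect field rectifies its errors preferentially into a rigid
  component.

Corrections accumulate in coefficient space under relaxation 0.7 (chords
nearly tangent to the rim can more than double the local measurement gain,
so a full step is unstable there); the default 6 passes contract the
initial bias by well over two orders of magnitude. The full-resolution
first pass remains in the returned estimate, so structure outside the
66-mode correction basis is preserved. With defaults the package recovers
±6 D of defocus to better than 0.01 D and trial cylinders to ~0.02 D /
0.02° on a 256² grid with k = 60.

k = 120 is the default angle count for production use; the experiments here
use k = 60, and the test suite verifies that gradient error changes by less
than 5 % between k = 120 and k = 240 (precision saturates near 120, as
observed on the reference instrument).

## Integration

The phase is the exact minimiser of the staggered forward-difference
least-squares problem over all pixel pairs inside the mask; the normal
equations form a masked graph Laplacian solved by sparse factorisation,
with the piston nullspace pinned and the mean removed afterwards. This
handles arbitrary connected, non-circular pupils without boundary padding
heuristics, and is one of the "very similar results" family of least-squares
integrators; a Fourier-domain solver with mask extension was considered and
rejected as it only approximates the masked minimiser. A discrete-curl RMS
diagnostic is reported alongside (zero for exact gradient fields).

## Zernike machinery and refraction

OSA/ANSI single-index convention j = [n(n+2)+m]/2 with unit mean-square
normalisation over the disk; y increases upward so the astigmatic axis
follows the ophthalmic counter-clockwise-from-horizontal convention.
Fitting is ordinary least squares on the pixel samples inside the circle —
the common choice in aberrometry, where pupils are pixel-limited — and the
fitting circle is the largest circle inscribed in the (generally
non-circular) pupil support, found by distance transform (row-major first
occurrence on ties, radius reduced half a pixel so the circle is strictly
inscribed).

Band RMS: low j = 3–5, medium j = 6–14, high j = 15–65; total excludes
piston and tip/tilt. Refraction from the second-order coefficients:
M = −4√3·c₄/r², J0 = −2√6·c₅/r², J45 = −2√6·c₃/r² (coefficients in metres,
pupil radius r in metres, results in diopters), cylinder reported in the
minus convention with axis ½·atan2(J45, J0) mapped to [0, 180). The
spherical value reported is M itself — half the cylinder is deliberately
*not* folded into the sphere, so sphere and cylinder errors can be traced
independently. No vertex-distance transposition is applied.

## Forward simulator

`SimulationConfig` defaults mirror the reference bench: plane separation
2Δz = 13.33 mm and a 7 mm pupil (4 mm for the deformable-mirror
experiments). Grids are desk-scaled: by default the pixel pitch is chosen
so the pupil fills ~87 % of a 256² grid (≈31 µm pixels for a 7 mm pupil)
rather than the instrument's native 8.553 µm sampling (9 µm sensor pixels
behind a 1.0523× magnification), which would need ≥1024² grids; the
experiments below were verified insensitive to grid size between 128² and
512². Illumination is a uniform disk with a 2-pixel raised-cosine rim to
avoid aliasing at the edge. Propagation deposits each illuminated pixel at
its displaced position by bilinear splatting, conserving flux exactly, and
refuses phases steep enough to push rays off the grid.

Ground-truth generators:

* `phase_from_refraction` — exact second-order surface for a sphere S and
  cylinder C at a given axis, built from the power-vector components so the
  refraction round trip is closed-form exact.
* `random_dm_phase` — i.i.d. standard-normal coefficients on modes
  j = 3…65 (piston/tip/tilt excluded), the whole surface rescaled so its
  peak-to-valley equals the requested amplitude exactly; deterministic per
  seed. This mimics the deformable-mirror command maps of the reference
  validation (amplitudes 0.35…2.8 µm in 0.35 µm steps).
* `pattern_phase` — band-pass filtered white noise (difference of Gaussians
  at σ and 2σ, σ = half the correlation length; default correlation length
  0.5 mm, a free choice as the spatial scale of the in-vivo texture is not
  quantified), rescaled into a requested P–V range. A band-pass field is
  used because the phenomenon of interest is an oscillatory peak-and-valley
  texture that a 66-term fit cannot absorb; a low-pass random field mostly
  can.
* `add_noise` — Poisson photon noise at a configurable photons-per-unit
  scale plus Gaussian read noise, seeded; negative excursions clip at zero
  as a detector would after bias subtraction.

What the simulator does *not* model: retinal scattering and the double-pass
point-spread function, eye movements and accommodation, corneal
reflections, camera nonlinearity, and diffraction. Passing the in-silico
experiments therefore demonstrates the correctness and internal consistency
of the reconstruction and analysis chain under geometric optics — not the
full error budget of a physical instrument on real eyes.

## In-silico experiments

`run_experiment` replays the calibration/validation designs and formats
summaries as mean ± SD with [min max] ranges:

* `defocus_series` — 13 defocus values spanning −6…+6 D, 7 mm pupil.
* `cylinder_series` — +0.50/+1.00/+2.00/+3.00 D at 90/45/22°; recovered
  minus-cylinder results are transposed back to plus-cylinder form for
  comparison, and axis errors are circular (mod 180°).
* `dm_validation` — five random 66-term maps per amplitude 0.35…2.8 µm
  (40 maps; the physical validation used 800, and five per amplitude is
  enough to bound the worst case well below the instrument's), 4 mm pupil;
  residuals are RMS differences against ground truth over the inscribed
  analysis circle with piston removed.
* `repeatability` — repeated acquisitions of a fixed, slightly defocused
  eye under configurable photon/read noise; with noise disabled the
  pipeline is bitwise deterministic across repeats.

The experiments run at 256² with k = 60 by default — chosen as the smallest
configuration at which the recovered-parameter errors are already far
inside the physical instrument's calibration figures, so the runs complete
in minutes on one CPU.

## Analysis pipeline conventions

* Pupil auto-detection thresholds the mean of the two intensities at 5 % of
  the robust (99th percentile) maximum, keeps the largest connected
  component and fills holes; the reconstruction mask is additionally eroded
  by one pixel and intersected with the gradient validity mask.
* Per-eye analysis removes piston and tip/tilt over the inscribed circle
  before fitting. Tilt is image displacement, not wavefront shape, and all
  comparisons against ground truth are modulo piston/tip/tilt unless a
  specific experiment states otherwise (the DM validation removes piston
  only, matching its reference protocol).
* The high-pass view is phase minus its mask-aware Gaussian blur
  (normalised convolution, so the pupil rim is unbiased); σ is interpreted
  in pixels, default 0.5.
* A difference-map RMS above 0.2 µm is flagged as structure beyond the
  66-term representation — around the level reported as clinically
  significant for a human eye.
* Bilinear resampling for cross-sensor comparison propagates the mask
  conservatively: an output pixel is valid only if every contributing input
  pixel is valid.

## Known limitations

* The per-line transport measurement is tomographically incomplete: the
  refinement corrects its smooth bias on the span of the first 66 Zernike
  gradients, so bias on structure far outside that span (very
  high-frequency, high-amplitude fields) is only attenuated, not removed.
  The deformable-mirror experiment bounds this in practice.
* Recovered global tip/tilt carries a small systematic error for complex
  maps (rigid components rectified from per-line chord artifacts); it is
  excluded from every reported quantity.
* Steep wavefronts whose rays cross between the planes (caustics) violate
  the monotone-transport picture; the strongest random 2.8 µm maps at 4 mm
  pupils approach this regime, which is visible as their larger residuals.
* The simulator's uniform illumination is idealised; real pupils are
  apodised and textured, which mainly affects the flux-weighted validity
  masks near the rim.
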