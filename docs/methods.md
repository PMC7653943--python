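# Methods

## Motion model

The package models respiratory and cardiac motion as cyclic displacements
of amplitude `h`.  Gating the acquisition into `n` bins leaves each gate an
average over a fraction of the cycle; under the assumption that the bins
split the motion into equal intervals, the gate means span `h (n − 1)/n`,
measured between the two extreme gates (end-expiration vs peak-inspiration
for respiration; cycle ends vs mid-cycle for the heart).  The dual law adds
the two contributions, `g(r, p) = a (r−1)/r + b (p−1)/p`, because
respiratory and pulsatile blurring superpose in the image.  Both laws are
linear in their amplitude parameters, so the fits are closed-form least
squares (`c = Σ wᵢ yᵢ / Σ wᵢ²` with `wᵢ = (nᵢ−1)/nᵢ`, and a two-column
linear solve for `(a, b)`); negative fitted amplitudes are clamped to zero
with a warning, since they are physical lengths.  The exponential
alternative `a + b e^{c/r}` is fitted by Levenberg–Marquardt from the fixed
start `(max y, −max y, −1)` with a 500-evaluation cap, so it is
deterministic.

The optimal gate count captures the asymptotic motion `m_est` to within
half the scanner resolution `s` (5.2 mm FWHM by default): inverting the
capture law gives `n_opt = ⌈2 m_est / s⌉`, with `n_opt = 1` whenever
`m_est ≤ s/2` — motion below half the resolution needs no gating.  The
grid-based alternative picks, among measured (r, p) cells reaching a
threshold, the scheme minimising `r·p`; ties prefer fewer cardiac gates
(ECG gating discards less data), then fewer respiratory gates.  Threshold
comparisons carry a 1 ns-scale epsilon so decimal values like 12.7 survive
binary floats.

Two rounding conventions attach to the published linear
gates-versus-motion rules: ceiling for a total dual-gate budget (a budget
must cover the motion) and half-up nearest for per-mode counts.  Both are
explicit arguments, never implicit.

## Gate assignment

Respiratory gating is amplitude based: the amplitude range of the *valid*
samples is split into `r` equal-height bins; a value exactly on an interior
edge goes to the higher bin and the maximum to bin `r`, making labels
deterministic and order-independent.  Cardiac gating is phase based: each
R–R interval is split into `p` equal-duration bins, half-open at the next
R-peak; times outside any complete interval are rejected, as are samples
the spirometry system marked invalid.  A dual gate is the intersection; a
sample missing either label is rejected.  Indices are 1-based in all
interfaces, with −1 as the rejection sentinel in CSV output.

## Phantom simulator

The synthetic phantom emulates a mechanically driven two-balloon heart:
nested balloons (default radii 30/40 mm) filled with radioactive water,
translated axially by 20 mm for respiration, with a pulsatile inflation
changing the outer diameter by up to 7 mm, and 3 mm hot spots riding on the
outer surface as coronary-plaque stand-ins.  Key design choices:

* **Respiratory waveform.** Default is triangular (linear rise over 40% of
  the cycle, linear fall), i.e. the constant-speed drive of a mechanical
  phantom.  Linearity makes the amplitude dwell uniform, so equal-height
  bins have their means at bin centres and the measured motion follows the
  capture law exactly — the property the validation rests on.  A
  raised-cosine (sin²) option provides end-expiration dwell and unequal
  per-gate dwell times for stress-testing the count bookkeeping.
* **Cardiac kinematics.** Contraction is a uniform scaling about the
  balloon's base pole (its mount): the outer diameter changes by exactly
  the configured amount, and the apex-mounted hot spot — the brightest one,
  which the measurement tracks — travels that same distance, while
  equatorial points travel less.  The diameter modulation is
  `Δd·sin²(π·phase)`, zero at both cycle ends.
* **Clocks.** Respiratory period 4 s with 5% per-cycle jitter; mean R–R
  interval 0.95 s (~63 bpm) with 5% jitter.  The non-integer period ratio
  keeps the two clocks incommensurate, as in patients; a locked ratio would
  correlate respiratory and cardiac phase and bias gate means.
* **Activity.** Hot spot : balloon shell : interior ratio 200 : 4 : 1.
  Point sources are far more concentrated than the water background; after
  the 5.2 mm PSF dilutes a 3 mm spot roughly eightfold in 3-D, this ratio
  keeps the spots unambiguously brighter than the shell even in non-gated
  (motion-smeared) images, which is what makes hot-spot tracking possible
  at all.
* **Rendering.** Shell and interior are anti-aliased indicator fields
  blurred with the isotropic Gaussian PSF; hot spots are added analytically
  *after* the PSF (Gaussian⊛Gaussian closed form), since their pre-blur
  width is below the voxel size and grid sampling would alias them.
* **Gated acquisition.** Respiration is a rigid axial shift, so each dual
  gate's time average factorises into quantised cardiac-state renders (32
  levels, cached across schemes) combined with the gate's exact joint
  (cardiac level × axial offset) weight table; sub-voxel shifts are split
  linearly between neighbouring offsets, which preserves total intensity
  and centroids exactly.  Expected counts per gate equal the total count
  budget (default 10⁷) times the gate's dwell fraction; rejected samples
  carry no counts, so summed expected counts equal
  `total_counts × (1 − rejected fraction)`.
* **Noise.** Poisson per voxel on the expected counts, plus an additive
  Gaussian "reconstruction floor" with per-voxel s.d. equal to
  `recon_noise_floor` times the non-gated expected counts, clipped at
  zero.  Pure Poisson count-splitting leaves the summed-image SNR
  independent of the gate count; on real scanners the iterative
  reconstruction of low-count gates adds noise that does not average out,
  and this floor is its surrogate.  The default 0.02 was chosen once, from
  the analytic relation `SNR² ≈ Λ²/(Λ + G κ²Λ²)` for VOI mean counts Λ and
  G gates, to lose about 1.7 dB between 1 and 20 gates at the default count
  budget — the loss scale reported for dual-gated cardiac studies on this
  class of scanner.
* **Myocardium variant.** A hollow ellipsoidal shell (outer semi-axes
  32×32×45 mm, 10 mm wall) in faint lung background; respiration
  translates it, the cardiac phase thickens the wall inward symmetrically.
  It exists for centre-of-mass and wall-FWHM measurements on a
  patient-like object; it has no hot spots.

All randomness derives from one seed through named substreams (respiratory
signal, ECG, per-scheme noise), so every artefact is bit-reproducible and
schemes can be re-simulated independently.

What the simulator does *not* model: sinogram/list-mode physics, iterative
reconstruction and its spatially correlated noise, attenuation and scatter,
breathing-depth drift, arrhythmia, or non-rigid cardiac deformation.
Passing the validation here shows the estimation chain is correct under the
model's assumptions, not that a clinical scanner meets them.

## Motion measurement

Because individual dual gates are count-starved, motion is read from
averaged images: respiratory motion from cardiac-averaged images (one per
respiratory gate), cardiac motion from respiratory-averaged images, as
displacement of a tracked feature — first-vs-last gate for respiration,
mid-cycle vs the average of the end gates for the heart (for an even count
the later middle gate is used).  Motion is the full 3-D Euclidean
displacement.

Three locators are provided.  `local_max` is the maximum voxel.
`weighted90` is the intensity-weighted centroid of voxels at or above 90%
of the local maximum, evaluated on a cubic-spline-interpolated quarter-voxel
grid (on coarse grids the 90% set can be a single voxel, which would
quantise positions to the lattice) and restricted to a neighbourhood of
3× the scanner FWHM so neighbouring spots stay separate.  `cma` extracts
the largest connected component above a fractional threshold (default 0.5)
and returns its intensity-weighted centre of mass — the standard
myocardium measurement.

The default for motion tables is a fourth variant, `hotspot_component`:
the intensity centroid of the 26-connected component (≥ 50% of a
top-5-voxel reference level) *containing the global maximum*.  On averaged
images the residual motion smears a spot into a broad, nearly flat ridge
(up to 20 mm for the respiratory-averaged images used in cardiac
measurement); any near-maximum estimator then sits wherever dwell noise
tilts the ridge top and systematically compresses the measured
displacement, while a mean-based centroid over the whole component shifts
exactly with the gate-mean displacement.  Per scheme, the locator is
additionally confined to a box (±9 mm transaxial, ±18 mm axial) around the
spot found in the scheme-summed image, so Poisson noise cannot switch the
tracked spot's identity between gates.  With this estimator the noiseless
simulate→measure→fit chain recovers the configured amplitudes to ≈0.3 mm,
and within ≈1.3 mm at the 10⁷-count budget.

The start/end-vs-mid cardiac comparison is degenerate for `p = 2` with a
sinusoidal contraction (both halves of sin² average to the same state);
measured cardiac motion at `p = 2` is therefore near zero and scheme
families for fitting use the conventional `p ∈ {1, 4, 6, 8, 10}`.

## Image quality

SNR is `10·log₁₀(mean/SD)` over a homogeneous VOI, population SD by
default (the sample convention is a switch, since the choice is not
recoverable from the literature's corrupted formula; the printed
denominator `√((Σ(xᵢ−x̄))²)/N` is identically zero and is read as the
standard deviation the accompanying text describes).  A scheme's SNR is
that of the voxelwise sum of its gates; the gate-count dependence is
summarised by fitting `a + b·log₁₀(n)`, and a scheme passes when its SNR is
within 3 dB of the non-gated image.  The pipeline's automatic VOI is a
21 mm box at the scanner origin — sized to stay inside the inner balloon at
every respiratory position (the conventional 13³-voxel VOI at 3.27 mm
slices would leave it during motion).

Line profiles are trilinear, at half the smallest voxel dimension by
default.  FWHM takes the half level midway between the profile maximum and
its minimum (the baseline — profiles are expected to reach background on
both sides), locates each crossing by linear interpolation between the
bracketing samples nearest the peak, and errors on profiles that never
descend (open profiles).  The dual-gated vs non-gated comparison uses the
last gate of a scheme (peak inspiration, end diastole — the gate with the
best motion state) against the non-gated image, as a relative FWHM
difference in percent.

## Validation scale

Simulation-backed tests run on a 64×64×48 grid at 3 mm isotropic voxels
with 300 s acquisitions — large enough for the phantom plus its full
travel, small enough that the thirty-scheme family simulates in seconds.
The full-resolution geometry (192×192×47 at 1.82×1.82×3.27 mm, 1800 s) is
the default for the command-line pipeline.  Tolerances follow the
measurement physics: half a voxel for centroid positions, one voxel for
extent-based lengths, 1 mm (noiseless) / 2 mm (Poisson) for recovered
amplitudes.

## Known limitations

* The capture law presumes gate means spread uniformly over the cycle;
  strongly non-uniform breathing (long end-expiration dwell with
  phase-based gating, say) violates it — by design the package gates
  respiration by amplitude, where the law only needs a stable amplitude
  range.
* Measured cardiac amplitude depends on the tracked feature's geometry:
  a concentric contraction moves a surface point by only half the diameter
  change.  The phantom's base-anchored contraction makes the apex spot
  carry the full amplitude; real anatomies sit between the extremes.
* The reconstruction-noise floor is a surrogate with one free parameter,
  not a reconstruction model; SNR *trends* are meaningful, absolute dB
  values are not.
* `GateGrid` thresholding trusts the measured grid; measurement bias
  propagates directly into the chosen scheme.
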