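# Methods

`qsmfid` implements quantitative susceptibility mapping (QSM) for
automatic gold fiducial-marker detection in multi-echo T2\*-weighted
gradient-echo (GRE) MRI of the prostate, together with the digital
phantom used to validate it, the SBRT-frame coordinate conversion, and
the evaluation statistics. This note records the models, the defaults
and why they hold, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Signal model and phantom

Tissue magnetization shifts the local Larmor frequency through the
dipole field of the susceptibility distribution χ (ppm, expressed
relative to prostate tissue ≡ 0). In k-space the field along B0 is

    B(k) = D(k) · X(k),   D(k) = 1/3 − k_z²/|k|²,   D(0) ≡ 0,

(Lorentz-sphere convention, B0 along the slice axis of the axial
acquisition). The complex GRE signal per voxel and echo is

    s_j = A · exp(i φ0) · exp((i 2π f − R2*) TE_j),   f = γ̄ B0 · field.

The phantom rasterizes parametric inclusions (spheres, axis-aligned
cylinders, ellipsoids, boxes) with a partial-volume model: volume
fractions are sampled on an oversampled sub-grid with an antialiased
(signed-distance) coverage estimate and block-averaged, so integrated χ
is conserved to well under 1% at oversample 4. Susceptibility contrasts
follow the values measured for the materials of interest: gold
−36 ppm, calcification −21 ppm, air +0.024 ppm relative to tissue. The
air value is adopted as printed in the source measurements without
endorsement; it differs from commonly tabulated air–water differences.

Static dephasing from intra-voxel field spread is modeled as an extra
exponential rate R2′ = 2π γ̄ B0 · std(field) over each voxel's sub-grid,
which reproduces the signal voids "larger than the marker's actual
size" that clinical GRE shows around gold. Gold and air carry no proton
signal (m0 = 0); calcifications carry reduced signal (m0 = 0.3,
R2\* = 100 s⁻¹). No k-space acquisition effects (SENSE, trajectories,
coils) are simulated; the acquisition's −1 mm slice overlap is not
modeled (contiguous slices).

Default acquisition: 6 echoes, TE = 3.1–24.6 ms, ΔTE = 4.3 ms, 1.5 T,
1.0×1.0×2.0 mm voxels on a 160×160×48 grid — the internal-marker
protocol of the clinical workflow. Default pelvis: ellipsoidal body
(70×65×44 mm semi-axes) and prostate (20×17.5×15 mm), three gold
markers, one 2 mm prostatic calcification, one 10 mm rectal air pocket
(sizes are diameters), complex noise σ = 1% of the tissue signal.

**Marker geometry.** The clinical markers are ~0.3 mm diameter coils
that fold on implantation. A 0.3 mm inclusion in a 1×1×2 mm voxel
dilutes to a voxel-mean χ of a few ppm (volume-fraction arithmetic:
−36 · V_marker / 2 mm³ ≈ −9 ppm even at 1 mm diameter), which no
inversion can place at the material value — yet clinical candidate
regions present near −36 ± 4 ppm. The phantom therefore uses
slice-axis cylinders of radius 1 mm and length 6 mm: the smallest
geometry on this grid whose χ core is resolved (in-plane fraction
≥ 0.95 for sub-voxel-center placements) and whose footprint spans at
least two full slices for any axial position. This is the regime in
which χ-based detection physically operates; markers below the
resolution limit fail for the same reason edge-of-gland markers are
missed clinically. Marker positions are fixed configuration (apex /
mid-gland / base pattern) with sub-voxel in-plane offsets ≤ 0.3 voxel;
placements near voxel corners dilute the core below the detection
threshold and are a known limitation of the voxel scale, not of the
algorithm.

## Field estimation

1. **Temporal initialization** — phase of Σ_j s_{j+1} s_j\* divided by
   2π ΔTE (magnitude-weighted, offset-immune); pairwise weighted least
   squares for non-uniform spacing.
2. **Complex-domain fit** — per-voxel Levenberg-damped Gauss–Newton on
   (f, R2\*) with the complex amplitude eliminated analytically at each
   step (variable projection). Stops at relative parameter updates
   < 1e−6 or 50 iterations; voxels whose plain step fails are damped
   individually; voxels whose residual exceeds 10% of their amplitude
   are re-seeded from a 16-point grid over one aliasing period of the
   (periodic-in-f) objective and polished, which rescues fits stuck in
   a wrong local basin.
3. **Reliability** — the relevant question is whether a voxel's field
   is *constrained*, which requires signal across at least two echoes:
   reliability is the model amplitude at the second echo,
   A·exp(−R2\* TE₂), normalized by its robust in-mask median, floored
   to 0 below 5% of that median. Empirically this separates voxels with
   field error ≤ 0.1 ppm (reliability ≥ 0.1) from dephased voxels whose
   fitted field is unusable.
4. **De-aliasing** — with uniform ΔTE the model is exactly degenerate
   under f → f + k/ΔTE together with φ0 → φ0 − 2π k TE₁/ΔTE. Because
   TE₁/ΔTE is not an integer here, the fitted φ0 of an aliased voxel is
   displaced from the smooth true initial phase by a known per-branch
   offset; choosing the branch that returns φ0 closest to a smoothed
   φ0 reference de-aliases each reliable voxel independently of spatial
   field continuity. On the phantom this resolves every aliased branch
   exactly. Laplacian unwrapping of the TE-normalized phase (discrete
   7-point Laplacian diagonalized by a cosine transform, i.e. an FFT of
   the reflectively extended volume; congruence step returns values
   congruent to the measured phase) then handles smooth large-scale
   wraps for voxels the φ0 test cannot reach.

## Background removal and void completion

Background fields are removed by projection onto the dipole field
(PDF): a susceptibility distribution supported on the complement of the
(2-voxel-eroded) body mask is fitted to the reliability-weighted total
field by conjugate gradients on the normal equations (relative residual
< 1e−3 or 100 iterations) and its field subtracted.

Marker and air interiors produce no signal, so their local field is
unmeasured — yet for a compact source those interior values carry most
of the deconvolution amplitude (zero-filling them collapses a −34 ppm
core to ≈ −7 ppm). The **field-completion** step treats void voxels
(reliability < 0.1 inside the body) as unknowns and solves the damped
least-squares problem

    min_v ‖ P_ext D⁻¹_δ (f_known + E v) ‖² + damp ‖v‖²,

i.e. the completed field must not imply susceptibility sources outside
the body (P_ext), with D⁻¹_δ the truncated-inverse dipole kernel.
Solved matrix-free with LSMR (damp 0.01, 100 iterations — the damped
iteration count acts as the regularizer; chosen at the noise-consistency
point where the filled gold interiors stabilize near the forward-model
values across noise realizations). Void clusters whose filled values
stay below 3 ppm RMS carry no exterior evidence of strong content
(e.g. the calcification core or the air pocket, whose true interior
field is near zero) and are reset to zero fill, since keeping an
under-determined fill only injects deconvolution noise.

## Dipole inversion

* **TKD** — truncated k-space division with |D| clipped at δ = 0.1;
  zero-referenced afterwards. Fast baseline; underestimates compact
  sources by ~10–15%.
* **MEDI+0-style** — minimizes
  ‖W(Dχ − f)‖² + λ₁‖M_G ∇χ‖₁ + λ₂‖M_ref(χ − mean_ref χ)‖² with W the
  reliability/magnitude weights, M_G the smooth-region mask (magnitude
  gradients above their 70th in-mask percentile are anatomical edges,
  excluded from the penalty), and M_ref a background tissue reference
  region (body minus prostate minus |χ_TKD| > 5 ppm). IRLS with
  warm-started CG inner loops; the ε-smoothed objective (ε = 1e−3) is
  non-increasing across outer iterations; the final map is shifted to
  zero mean over the reference region. λ₁ = 1e−3, λ₂ = 0.1 on
  ppm-scaled inputs, calibrated on the default phantom. The data term
  is linear in the field and the original CSF zero-reference is
  replaced by the pelvic background-tissue region; full published
  fidelity (model-error weighting, merit-based λ) is out of scope and
  validated instead by phantom recovery. The mean field level inside
  the mask is removed at entry (the dipole kernel has no DC response),
  which makes the zero-referenced contrast invariant to constant field
  offsets.

The detection chain defaults to TKD on the completed field: after
completion it recovers gold cores at the material value, and it costs
~40× fewer dipole convolutions per volume than the regularized solver,
which matters when scoring many phantom realizations. The regularized
inversion is selectable everywhere (`--inversion medi0`).

## Marker extraction

Prostate mask dilated by 3 mm (whole voxels per axis — a 1 mm margin
does not cross a 2 mm slice); voxels with χ ≤ −28 ppm (midpoint of the
gold −36±4 and calcification −21±3 bands) selected, with an adaptive
fallback to the 5th percentile of χ in the search region when the fixed
cut selects nothing; 26-connected components below 2 voxels removed;
regions must span ≥ 2 slices (the dephasing-enlarged footprint of a
real marker always does); candidate centroids are |χ|-weighted voxel
centers in world mm (geometric centroids by flag). Classification by
region-mean χ: gold [−48, −24], calcification (−24, −10], air [0, ∞),
else unknown — nominal ±3σ bands meeting at the midpoint. Candidates
sort by |χ_mean − (−36)|; the best `max_markers` (3) gold candidates
are the detections, surplus gold regions are flagged rather than
silently dropped, for physicist review. Cross-sequence verification
against T1 water voids is a manual QA step; the CLI emits coordinates
for it.

## Frame geometry and evaluation

Frame rods are localized as the largest elongated (principal axis ≥ 3×
second) bright components above the 99.5th intensity percentile in the
inferior quarter of a T2-weighted volume; rod reference points are
component centroids (robust to partial visibility). The MRI→frame map
is the Kabsch least-squares rigid transform (SVD of the centered
cross-covariance, reflection-corrected). Frame rod coordinates are
institution-specific hardware and therefore user-supplied YAML.

Detections are scored by Hungarian one-to-one assignment within a 5 mm
gate (about twice the clinically reported mean displacement; the
matching criterion is a package choice). The detection-rate denominator
is the number of reference markers; displacement statistics use matched
pairs only. Image agreement uses signed mean error, mean absolute
error, and the Dice coefficient (defined 1.0 for two empty masks).

## Validation scope and problem sizes

The phantom validates the *chain* — forward physics (discrete dipole
vs. analytic sphere to < 5% at r ≥ 3a), estimator efficiency (within 2×
the Cramér–Rao bound), unwrapping, ≥ 90% background
suppression/retention, inversion recovery bands, and end-to-end
detection (20 noise realizations: 100% detection, ≈ 0.4 mm mean
displacement, no confounder labeled gold). It does not emulate coil
phase singularities, motion between echoes, B1 inhomogeneity, partial
Fourier/parallel-imaging artifacts, or marker shapes below the
resolution limit, so passing tests demonstrate correctness of the
algorithms under the stated acquisition physics, not clinical detection
rates; the clinically reported figures (89.4% auto-detection, 2.6 mm
mean displacement against CT) come from patient data this package
cannot reproduce.

Problem sizes used in the shipped tests: operator-level checks run on
64³–96×96×48 grids; inversion recovery and the 20-realization detection
study run at the full 160×160×48 acquisition size, with the noise
realizations sharing one deterministic forward simulation (only the
complex noise differs, as in repeated acquisitions of one object).
Iterative solvers run in single precision where their own tolerances
(≥ 1e−3) are far above float32 resolution.

## Known limitations

* The φ0-consistency de-aliasing requires uniform echo spacing with
  TE₁ not a multiple of ΔTE, and a spatially smooth true initial phase;
  with strongly structured coil phase the smoothing scale (10 mm) may
  need adjustment.
* Field completion assumes all sources lie inside the body mask; it
  must run after background removal.
* The fixed −28 ppm cut assumes the gold/calcification contrast of the
  measured material values; different marker alloys need recalibration,
  as the clinical workflow itself notes.
* Sub-resolution markers (true 0.3 mm hardware on coarse grids) are
  out of the method's physical operating regime in this voxel geometry.
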