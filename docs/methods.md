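# Methods

## Device model

The fiducial device is modelled as four labeled points in a canonical
frame: base vertices A, B, C in the z = 0 plane (A at the origin, B on
+x, C at positive y) and the apex D on +z above the base centroid.
Labels are fixed by opposite-side ordering — the side opposite A is the
shortest base side (50.7 mm by default), opposite B the middle (69.2 mm),
opposite C the longest (88.9 mm) — which removes any ambiguity in mapping
physical wells to labels. Each marker is a cylinder of 12.7 mm inner
diameter and depth whose axis is normal to the base plane; its signal
volume π·6.35²·12.7 ≈ 1608.8 mm³ anchors every size gate in the
detector, and its space diagonal √(12.7² + 12.7²) ≈ 17.96 mm anchors the
shape gate (1.5 × diagonal ≈ 26.94 mm, i.e. the 26.9 mm figure at
printed precision).

With the default dimensions the six pairwise separations are 88.9, 69.2,
51.92, 50.7, 44.23 and 30.31 mm — all distinct, with a minimum mutual gap
above 1 mm, which is what makes unambiguous labeling of a matched
quadruple possible. Note the apex-to-B separation of the ideal geometry
is 44.23 mm; physically manufactured devices (built to roughly 1 mm
marker-placement tolerance) can differ from the ideal values by a few
tenths of a millimetre, so measured spacing tables for a real unit are
not expected to agree with the ideal constellation beyond that tolerance.

## Coordinate conventions

All world positions are in the LPS patient frame in millimetres; NIfTI
RAS affines are converted on load and save, and DICOM geometry is used
as-is. Voxels are node-centered with 0-based indices. COMs, distances
and extents are always computed in world mm — never in voxel units — so
anisotropic and oblique grids behave identically. Gapped 2D acquisitions
are represented as contiguous grids with dz = slice thickness + gap; the
information loss inside the gap is modelled by the simulator, not by the
container. Intensities are non-negative integers (float inputs are
rounded, never rescaled, because the noise-threshold step depends on a
bin-width-1 histogram).

## Detection pipeline: numerical choices

**Noise threshold.** The background peak is the histogram maximum over
the lower half of the occupied intensity range, excluding the I = 0 bin
(exactly zero can be artificially massive in reconstructed images). The
threshold is the smallest intensity above the peak whose forward
difference h(I+1) − h(I) first becomes ≥ 0; a strict zero of the
derivative rarely exists on integer histograms. By default the pipeline
applies a 3-bin moving average to the histogram first: when bins hold
only a few thousand counts, Poisson jitter alone produces spurious
non-negative forward differences inside the background mode, stalling
the threshold at a few intensity units and merging the entire volume
into one connected component. The average restores the intended
peak/valley structure and has no practical effect on large, smooth
histograms. `compute_noise_threshold` itself defaults to the unsmoothed
rule.

**Size gates.** All voxel-set volumes are compared in mm³ (count ×
dx·dy·dz, dz including any gap): the preset geometries differ by more
than an order of magnitude in voxel volume, so voxel counts are not
comparable across sequences. Both windows — (0.5, 3)·V_marker for the
reference threshold, (0.35, 1.3)·V_marker for candidates — are strict
inequalities; objects exactly on a boundary are excluded. Thresholding
is inclusive (intensity ≥ threshold survives). The reference threshold
averages the original voxel intensities of surviving voxels.

**Iterative stage and the merge rule.** Candidate sets from successive
thresholds ST_n = (n/4)·R_T are merged into a composite mask. When a new
set overlaps or touches (26-adjacency) existing composite objects, the
union is tested against 1.3·V_marker: if it exceeds the cap the *new*
set is discarded and the composite is unchanged — growth is rejected,
never the established object. Candidates are processed in a
deterministic order (volume, then lexicographic first voxel) so results
are identical across platforms. Intensity-weighted COMs always use the
original, pre-threshold intensities of member voxels. Candidates
touching the volume boundary are retained but flagged (a marker at the
FOV edge is still usable, just partially sampled).

**Shape gate.** "Longest dimension" is evaluated per logical axis
(bounding-box extent (max − min + 1) × spacing per axis), each required
to be ≤ 1.5 × the marker diagonal. A 3D-diagonal interpretation was
considered and rejected as slightly looser for oblique candidates; the
per-axis reading matches how the candidate extents are tabulated.

**Matcher.** For τ = 1, 2, … τ_max mm, all 4-subsets of candidate COMs
are enumerated; a subset matches when its six sorted pairwise distances
each differ from the template's sorted six by ≤ τ. Among matches the
subset minimizing the RMS of the sorted-distance errors wins; labels are
then assigned by the best of the 24 permutations against the labeled
separations. τ_max defaults to 5 mm: beyond about half the smallest gap
between distinct template separations, labeling becomes unreliable. A
cheap prefilter (a true marker must have at least three other candidates
within the largest separation plus τ_max) bounds the enumeration without
ever excluding a matchable subset.

**Pose.** The device COM is the *unweighted* mean of the four marker
COMs: the markers are physically identical, and weighting by total
intensity would make the position sequence-dependent. The base normal's
sign is fixed by the apex side rather than by label handedness, making
(θ, φ) invariant to base-label permutations; φ is reported in
(−180°, 180°], θ in [0°, 180°], and a degenerate azimuth at the poles is
reported as 0 with a flag. The rigid template fit is a standard SVD
(Kabsch) solution constrained to a proper rotation.

## Synthetic acquisition model

The simulator emulates the features the detector actually depends on:

- **Partial volume from slice selection.** The continuous scene is
  integrated over each voxel's sensitive volume — full in-plane
  footprint, slice-thickness extent along the slice axis — with 4×
  supersampling per axis (cylinder volume error < 2% at the coarsest
  preset). The gap region between slices contributes nothing.
- **Acquisition geometries.** Eight presets mirror a clinical abdominal
  protocol: a 1.9 mm / 10 mm localizer, a coronal 0.9 mm / 6 mm + 1 mm
  single-shot preset, two 0.7 mm / 6 mm + 1 mm echo variants, a
  0.7 × 0.7 × 1.7 mm thin-slice 3D preset, and 0.7 mm presets with 4, 5
  and 7 mm slices and 1–2 mm gaps. The three-plane localizer is
  represented by its axial plane as a single volume. Oblique planes and
  scanner-axis table shifts rotate/translate grid versus scene exactly
  as a scanner would (grid fixed in scanner space; scene moves with the
  table).
- **Background confusers.** A tissue ellipsoid (semi-axes 130 × 70 ×
  200 mm) with 30 seeded internal ellipsoidal blobs spanning
  0.2–4 × V_marker at 0.5–1.5 × tissue intensity deliberately populates
  the marker-size windows. The device stands ~9 mm off the anterior body
  surface, as its housing dictates physically; the air clearance is what
  keeps marker components separate from the body at the noise threshold.
- **Noise and quantization.** Gaussian channel noise on a magnitude
  floor (|signal + N(0, σ)|, a rectified approximation to Rician noise
  that is adequate at these SNRs), then rounding to integers in
  [0, 4095]. Default levels: air 0, tissue 120, marker 400, σ = 10 — a
  plausible integer DICOM-like range, not a measured one.

Not modelled: pulse-sequence contrast physics (relaxation times of the
marker solution), coil sensitivity profiles, bias fields, motion and
breathing, and tissue deformation. Passing the synthetic suites
therefore demonstrates geometric and algorithmic robustness — partial
volume, gaps, oblique resampling, confuser rejection, intensity
scaling — but not contrast robustness across real sequences, which only
scanner data can show.

## Experiment suites and problem sizes

- **Detection / spacing:** the 8-preset suite at five seeds (40 volumes,
  FOV 160 × 110 × 180 mm) per run; spacing accuracy is pooled over the
  six marker pairs of the thin-slice preset (30 values per run).
- **Repeatability:** axial plus 10° and 20° oblique planes at two table
  positions (30 mm commanded shift), for a 5 mm-slice gradient-echo-like
  and a 7 mm + 1 mm spin-echo-like preset; differences are taken against
  the unshifted axial baseline with the commanded shift removed.
- The oblique angles are not externally prescribed; 10° and 20° are
  package defaults, configurable per run.

All randomness (blob placement, noise) flows from explicit seeds;
volumes are bit-identical across runs for a fixed seed.

## Known limitations

- No three-marker fallback and no manual seeding: fewer than four
  surviving candidates is a hard failure by design.
- Intensity-scale invariance holds only up to histogram discretization:
  scaling intensities by an integer factor interleaves empty histogram
  bins, which can shift the noise threshold within the background
  valley. Detected voxel sets are unchanged in practice; COMs move by
  well under 0.1 mm.
- The matcher is exhaustive over 4-subsets; with pathological candidate
  counts (hundreds of confusers surviving the shape gate) enumeration
  grows as C(n, 4), though the reachability prefilter keeps realistic
  cases small.
- DICOM support covers single-orientation series reading only; there is
  no DICOM writing and no 4D/multi-echo handling.
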