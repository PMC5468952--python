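# Methods

This note documents the measurement model, the synthetic-data model, the
numerical choices and the limitations of `plaquelapse`.  Nothing here
states a number that the test suite or `scripts/acceptance.py` does not
itself compute.

## Plaque measurement model

A plaque in one session is measured entirely in 2D frames:

1. **Center frame.** The z-slice maximizing the mean intensity of a square
   ROI around the plaque (default side: four expected plaque diameters,
   i.e. 80 μm; ties go to the lowest z).  The library default searches the
   whole stack; the automated pipeline restricts the search to ±40 μm
   around the detected seed's depth, because in a crowded field a brighter
   plaque overlapping the same lateral ROI at a different depth would
   otherwise capture the center frame.
2. **Background.** Per frame, the lowest ⌊N/10⌋ pixel intensities define
   the background; `μ_bg` is their mean and `σ_bg` their population
   standard deviation.  Which pixel population defines the SD is genuinely
   open; only the lowest-decile set is unambiguously background, so it is
   the default, with the whole-frame SD available behind
   `sd_population="frame"` (used on maximum-intensity projections, where
   bright structure should widen the threshold).
3. **Border.** Pixels strictly above `μ_bg + 3σ_bg`, 8-connected to the
   seed (or to the nearest above-threshold pixel within 3 px of it),
   interior holes filled.  Strict inequality makes a constant frame yield
   an empty mask (the σ = 0 degenerate case).  Hole filling follows from
   reading "area with the border" as the area enclosed by the border.
4. **Size.** Mean border area over the center frame ± 2 frames (areas in
   μm² via `pixel_size²`, default `(508/512)² μm²`).  Frames beyond the
   stack ends are dropped and the observation flagged `clipped`, as are
   masks touching a lateral frame edge; clipped observations participate
   in tracking but never in size statistics.

**Quality control.** Two additional flags exclude measurements a careful
analyst would reject, without removing the plaque from the track
bookkeeping: `merged` (the border mask contains a second detected plaque,
or two of the other session's plaque centroids fall inside it — a fused
component whose apparent size change reflects the fusion, not growth) and
`irregular` (the center frame does not carry the largest of the five
areas, or one frame's area exceeds 1.4× their median — a mis-centred
window or a transient fusion).  The 1.4 bound is far above the smooth
area variation of a compact plaque across ±2 μm (≤ ~10 % for radii ≥ 4 μm)
and far below the ≥ 2× jump a fusion produces.

**Automated seeding.** The study this design derives from selected plaques
by eye; automation requires a detector.  Candidate seeds are local maxima
of a Gaussian-smoothed (σ = 2 μm) maximum-intensity projection above the
projection's decile-mean + 3·whole-projection-SD threshold, separated by
≥ 10 μm, each refined to the brightest voxel of a strongly smoothed
(σ = 5 μm) local 3D window.  The strong smoothing matters: the raw
intensity argmax lands anywhere on a plaque's flat noisy core plateau,
while the smoothed argmax sits at the center of mass of the bright region.

## Tracking and growth statistics

Sessions are registered by phase correlation of maximum-intensity
projections (translation only; chronic-window fields do not measurably
rotate or scale between sessions a week apart).  Observations are matched
greedily by 3D centroid distance in offset-corrected coordinates, closest
pairs first, one-to-one, unmatched beyond 10 μm — well below the
nearest-neighbor spacing at the densities involved (~500 plaques/mm³),
which is why a global assignment would change nothing while being harder
to audit.  Unmatched observations open (appeared) or close (disappeared)
tracks; every observation belongs to exactly one track, so counts are
conserved.  Percent size change between two days of a track is
`100·(A_b − A_a)/A_a`, pooled as mean ± SEM over usable tracks, with the
paired raw sizes compared through the gated test procedure.

## Peri-plaque profile

One radial line per plaque, direction drawn uniformly from [0, 2π) as a
pure hash of `(plaque_id, master_seed)` — persisted across sessions and
reruns with no stored state.  Intensities are sampled every 0.25 μm
(≈ ¼ pixel; band membership is insensitive to ±1 sample) by bilinear
interpolation on the center frame, out to 15 μm beyond the border.  The
border radius is the distance to the last sample whose nearest pixel lies
in the border mask.  Normalization divides by the maximum over the whole
sampled line (inside + outside), scaling it to 0–100 %; the band statistic
averages normalized samples over the half-open interval
`(border, border + 5 μm]` (no endpoint convention is canonical; half-open
avoids counting the border sample itself, which is inside the plaque).

## Dendrite morphometry

Traces are polylines (μm) with spine annotations as arclengths and an
optional plaque entry/exit interval; all measurements operate in the
soma-first orientation, making classification invariant to how the trace
was digitized.  Proximal = the ≤ 80 μm ending at plaque entry; distal =
the ≤ 80 μm starting at plaque exit; segments shorter than 20 μm are
omitted.  Non-crossing traces more than 30 μm from every plaque border are
controls, split at the midpoint (halves capped at 80 μm so control
segments obey the same 20–80 μm range as plaque-relative ones).  Spine
counts use half-open spans `[start, end)` so bin edges never double-count.

Shaft diameter is the full width at half maximum of the intensity profile
perpendicular to the local tangent (±3 μm, 0.1 μm steps), above a local
background taken as the mean of the profile minima on either side of the
peak, with linearly interpolated crossings.  The profile is sampled with
cubic spline interpolation: diameters sit near the pixel scale, and
bilinear sampling measurably biases the half-maximum crossings at
half-pixel offsets (≈ +0.01 μm at 0.9 μm diameter and 0.2 μm/px), while
cubic sampling of the smooth profile is accurate to a few thousandths of
a micrometre.  FWHM itself is a declared stand-in: the commercial software
used for the original measurements does not document its operator.

## Statistical procedure

Each sample is gated by a one-sample Kolmogorov–Smirnov test against a
normal with the sample's mean and SD; p > 0.05 passes.  Both pass →
two-tailed Student's t (paired variant for longitudinal data); otherwise
Mann-Whitney (independent) or Wilcoxon signed-rank (paired).  Significance
is inclusive at p ≤ 0.05.  Samples under n = 8 or with zero variance fail
the gate (nonparametric fallback, with a warning).  Plain KS with
estimated parameters is anti-conservative as a *normality* test but is
what the procedure names; the Lilliefors correction is available via
`method="lilliefors"`.  Identical paired samples are reported as p = 1
rather than the undefined 0/0 t-statistic.

## Synthetic scenes

The generator emulates the acquisition geometry (508 × 508 μm at
512 × 512 px, 1 μm steps to 300 μm) and plaque statistics (515 plaques/mm³;
log-normal radii, median 10 μm, σ = 0.25, floor 2 μm — a 10 μm radius
gives a ~314 μm² cross-section, matching reported 309–343 μm² mean sizes).

* **Plaque model**: solid sphere of uniform core intensity (default 200
  counts) plus an isotropic exponential halo (amplitude 30, length scale
  2 μm) on a constant background (3 counts).  No plaque intensity
  statistics are published; these are free parameters chosen so cores are
  far brighter than background while halo tails fade into it.
* **Growth is self-similar**: a factor *g* dilates the whole radial
  profile (core radius and halo length scale), so any fixed threshold
  measures a border scaled by *g* and an area scaled by *g²*.  A halo of
  fixed extent attached to a growing core would make the measured change
  systematically smaller than *g² − 1*, which contradicts the observation
  the halo model encodes — peri-plaque fluorescence grows with the plaque.
* **Sensor model**: additive Gaussian noise (σ = 0.2) plus a
  signal-proportional variance term (0.01 × signal), then rounding to
  integer counts and clipping at zero.  Quantization is not cosmetic: the
  decile-based background statistic is only well behaved on detector-like
  integer data.  For any continuous unimodal background the lowest-decile
  mean + 3 × decile SD falls *below* the background mode (for Gaussian
  noise at μ − 0.52σ), so the border mask floods the frame; with integer
  counts and sub-count read noise the statistic lands about one count
  above background, cleanly separating plaques — evidently how the method
  behaved on real detector data.
* **Reproducibility**: all randomness flows from one seed through named
  substreams (placement, radii, noise, jitter); a fixed seed yields
  byte-identical scenes.  Placement keeps one diameter clear of lateral
  edges and a five-frame margin axially, and rejects sphere overlaps
  deeper than 2 μm.
* **Dendrites** are rendered with a Gaussian cross-section whose FWHM
  equals the configured diameter at each arclength (piecewise-constant
  profile), with spines as short alternating perpendicular protrusions.
  Sub-resolution shafts (≈ 1 μm) appear Gaussian under diffraction-limited
  imaging, and the construction makes "rendered FWHM = configured
  diameter" hold by definition, which is exactly what a render-then-measure
  round trip should test.

What the generator does **not** model: optical PSF anisotropy and
depth-dependent attenuation, vasculature shadows, motion artifacts within
a stack, microglia or any second channel, non-spherical plaque
morphologies, and detector gain nonlinearity.  Passing tests therefore
validate the *measurement chain* — thresholding, sizing, tracking,
profiling, statistics — on idealized but statistically realistic data;
they do not certify segmentation accuracy on real morphologies.

## Problem sizes used in validation

The growth-recovery experiment uses five 254 × 254 × 300 μm fields
(256 × 256 px) of 15 plaques each — 75 plaques total, the tracked-cohort
size it emulates.  Spreading 75 plaques over five fields keeps the 2D
nearest-neighbor spacing in projection well above the 10 μm detection
radius; a single field holding all 75 would fuse most of them in the
maximum-intensity projection, which is a property of the synthetic
crowding, not of the measurement chain.  The per-field density
(775 plaques/mm³) remains the same order as the densities the generator
emulates.  Zero-growth runs of the same experiment bound the pipeline's
intrinsic size drift (|mean change| < 2 %).

## Known limitations

* The 5-frame window is fixed in μm, so measured area ratios carry a
  small positive bias relative to *g²* (second-order in 1/r²; ≈ +0.1–0.3
  points at the simulated radii).
* Greedy matching can mis-pair plaques closer than ~10 μm; such
  configurations are rare at realistic densities and usually excluded by
  the merge QC anyway.
* Registration is translation-only by design; rotation would require
  landmark- or feature-based alignment.
* Stable fusions (two plaques merged in *all* frames of *both* sessions)
  pass QC and bias their track's change upward; they are indistinguishable
  from a single plaque without higher-resolution information.
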