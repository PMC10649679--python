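# Methods

`vesiscope` quantifies where inhibitory receptors (CTLA-4, PD-1, LAG3,
TIM3, TIGIT) and TCRζ reside inside T cells, from three kinds of
fluorescence data: confocal midplanes (edge vs interior, clustering),
high-resolution z-stacks (membrane-associated fraction), and TIRF
time-lapse movies (vesicle-insertion events, interface profiles,
dual-colour colocalization).  Every analysis can be exercised on
synthetic scenes with exact ground truth; this note records the models,
the defaults, and the design decisions.

## Edge/interior partition and clustering statistics

A cell midplane mask is split into an outer "edge" ring and an interior
core using the Euclidean distance transform: the edge is all pixels whose
distance to the cell boundary is at most d*, the smallest distance at
which the ring reaches a target share of the cell area (default 0.35, in
the 30–40% range used for midplane analysis).  Reported per cell:

* **Edge:interior ratio** — mean intensity in the ring over mean
  intensity in the core, plus the integrated-intensity fraction at the
  edge.  For a cell whose signal density is uniform the ratio is 1.
* **Gini coefficient** of pixel intensities within the cell, computed
  from the sorted-values identity (equivalent to the mean absolute
  pairwise difference over twice the mean).  With the n/(n−1)
  normalisation a constant image scores exactly 0 and a one-pixel image
  exactly 1; the unnormalised variant is also reported.  Gini is
  invariant under global intensity scaling and increases under any
  transfer of signal from a dimmer to a brighter pixel.
* **Greyscale Ripley's K** at radii 1–9 px.  The estimator is the
  intensity-product pair mass observed within radius r around centre
  pixels at least max(r) from the boundary (erosion border correction),
  divided by the same quantity for a homogeneous field of equal mean
  intensity, scaled by πr².  Normalising by the homogeneous-field value
  rather than by a continuous-area formula removes the lattice
  discretisation bias that otherwise dominates at r ≤ 2 (at r = 1 the
  disc contains 4 lattice neighbours but π·1² ≈ 3.14).  A spatially
  random cell therefore scores πr² at every radius by construction,
  clustered signal scores above πr², and an image with all signal in one
  pixel has no cross pairs and scores 0.  Both K̂(r) and K̂(r)/πr² are
  exported.

Midplane preprocessing selects the z-slice of highest mean intensity,
smooths with a Gaussian (σ = 1 px) and removes diffuse background by
rolling-ball subtraction (radius 100 px).  For large radii the background
is estimated on a downsampled copy and upsampled back; the ball is smooth
at that scale and the residual error is far below the shot noise.

The three-section vesicle position cuts the cell's extent along a
caller-supplied interface axis into three equal-depth bands from the
interface backward; ties go to the nearer-interface band.

## Membrane-associated fraction from z-stacks

The estimation chain: (i) 3D instance segmentation of a pixel-probability
stack — binarise at 0.5, remove foreground and background components
below 200 voxels, split merged cells by a distance-based watershed,
discard instances above 1800 µm³ or touching the image edge; (ii) select
the central slice (maximal cross-sectional area, lower index on ties);
(iii) refine the surface with 360 radial rays (bilinear interpolation,
0.5 px steps): scanning inward from outside, the surface is the first
sample at ≥ 30% (inhibitory receptors) or 50% (TCRζ) of that ray's
maximum; (iv) estimate the apparent membrane width by fitting a 1D
Gaussian (amplitude, centre, σ ∈ [0.5, 10] px, offset) to each ray in a
±6 px window around the surface and averaging the 5 (or 20) smallest σ,
times 2 (inhibitory receptors except TIM3) or 3 (TIM3, TCRζ); (v) split
the angle-averaged radial profile Ī(ρ) (ρ = radius normalised per-ray by
the refined surface radius) into membrane and interior and extrapolate to
3D assuming isotropy, i.e. weighting by ρ² as for spherical shells.

Step (v) needs care.  The threshold-refined contour sits on the *outer*
flank of the PSF-broadened membrane ridge (about 1.55 σ outside the peak
for the 30% threshold), and a uniform interior contributes roughly 3 w/R
of its mass to any band of width w wide enough to contain the ridge — a
floor of 0.15–0.25 for realistic T-cell geometry that would swamp low
membrane fractions.  The band is therefore anchored at the ridge peak
(falling back to the refined surface when no ridge rises at least 10%
above the interior plateau), the far-field background is subtracted
everywhere, and a modelled interior profile — the in-cell plateau level
falling off sigmoidally at the ridge, with the ridge σ as the fall-off
scale — is subtracted inside the band before integration.  Everything
not attributed to the membrane counts as interior.  With this
decomposition the estimator recovers constructed membrane fractions of
0.2/0.5/0.8 to within 0.05 in all three receptor-class parameter sets,
is invariant under global intensity scaling, and sends all-interior
cells to ≈ 0.  Fractions below about 0.15 fall under the ridge-prominence
floor and are reported near 0 — a sensitivity limit, stated rather than
hidden.

When no external pixel-probability stack is supplied (the trained
classifier used for real data is a pluggable input), a fallback
pseudo-probability is built from a robust background threshold (median +
6×1.4826×MAD of the smoothed stack) with a logistic squash and 3D hole
filling.  A histogram split such as Otsu is deliberately avoided: on
membrane-dominated cells it lands between the interior and shell levels
and binarises the cell as a hollow shell.  The fallback assumes
background occupies the majority of the stack volume.

## TIRF insertion-event detection

Four steps, in order:

1. **Blur exclusion.** Six per-frame focus measures (Brenner gradient,
   Tenengrad, variance of Laplacian, normalised grey-level variance,
   histogram entropy, wavelet-detail variance) feed a linear SVM
   (standardised features, C selected from {0.01…100} by 10-fold CV).
   Only the longest contiguous run of frames classified sharp is kept.
2. **Particle detection.** The ROI is the time-averaged movie thresholded
   at 90% of its Otsu value.  Each frame is denoised with a 2-level
   biorthogonal-3/5 wavelet decomposition whose detail bands are zeroed
   (reconstruction from the coarse approximation).  Zeroing only the
   finest band leaves enough residual noise that near-threshold spots
   are found intermittently (per-frame detection probability 0.4–0.8 in
   our conditions vs ≥ 0.9 with both bands zeroed), so the deeper
   smoothing is the default; the depth is a parameter.  Candidates are
   strict 8-neighbourhood local maxima inside the ROI (a plateau
   contributes its centroid once); local minima are collected frame-wide.
   For each candidate, the five brightest pixels of its 3×3 patch (xp)
   are shifted down by 4 σl + 3 σg — σl the standard deviation of xp
   (variants: full patch, or the patch's dimmest four pixels), σg that of
   the dimmest 25% of the *raw* frame, i.e. the imaging-noise floor
   before smoothing — and compared against the fifteen dimmest pixels
   pooled from the three nearest minima (xm) with a one-sided Welch
   two-sample t-test.  Candidates with p < 0.001 survive.
3. **Tracking.** Greedy nearest-neighbour linking, closest pair first,
   linkage threshold 22 px, gap closing over up to 3 missing frames.
4. **Classification.** Every tracked particle is classified at every
   time point from its track's log10 p-value series in a 30-frame window
   aligned at that detection (missing frames padded at p = 1); a linear
   SVM with 10-fold CV and balanced class weights separates *insertion*
   onsets (deep, abruptly appearing, then fading) from everything else
   (persistent microclusters, noise, static footprint texture).  The
   decision threshold is calibrated to the insertion-F1 optimum of the
   out-of-fold training scores.  Consecutive same-class detections form
   one event; same-class events within the linkage radius and a 30-frame
   window are merged so a sparsely detected event is not double-counted.
   Per-time-point prediction matters: an abrupt insertion that the
   tracker chains onto a pre-existing dim particle at the same location
   is still recognised at its own onset and position.

Insertion rates are tabulated per consecutive 100-frame window (30 s at
the 333 ms frame interval), divided by the footprint area in µm².
Microcluster-class events are excluded from the counts by default; a
flag includes them.  The line-scan interface profile averages a 20 px
wide band across the cell into 10 equal segments, normalised to the
brightest segment.

Training data for both SVMs come from the synthetic generator: sharp and
defocused frames for the blur classifier, and detection/tracking output
on insertion-only and microcluster-only movies for the event classifier,
with per-detection labels (positive within 15 px of a true insertion and
±2 frames of its onset; everything else, including late dispersal
frames, negative).

## Colocalization

PCC is always measured on the two raw channels within a segmented
object; it is invariant under per-channel affine rescaling and undefined
(flagged NaN) when a channel has no variance in the region.

*Dual-colour TIRF route*: per channel — median filter (r = 2),
rolling-ball subtraction (r = 50), Sauvola local threshold (r = 50),
removal of holes/fragments below 25 µm² and of regions with circularity
4πA/P² ≤ 0.2 (Crofton perimeter); the two channel masks are merged,
median-filtered, watershed-split and labelled; objects kept in the
50–500 µm² area range (sizes printed as µm³ in the source recipe are
treated as areas — the objects are 2D footprints) and tracked through
time by greedy centroid linking, dropping tracks present in fewer than 5
frames (configurable).

*Confocal route with a nuclear stain*: nuclei — 3D median (r = 2),
per-slice background subtraction (r = 30; rolling-ball standing in for a
sliding paraboloid, which no installed library provides and which differs
negligibly at this radius), Huang threshold (implemented here: the
minimum-fuzziness criterion), hole fill, median (r = 5), connected
components, volume filter at 20 µm³, per-slice convex-hull
solidification (standing in for an alpha-shape fill; nuclei are
near-convex), distance-watershed split.  The cytoplasm is the binarized
cell body minus nuclei, partitioned so each region joins its nearest
nucleus; objects below a mean green-intensity threshold (default the
25th percentile of per-object means) are excluded.  PCC is reported both
over the full 3D voxel set and over the object's central slice.

*Confocal route without a nuclear stain*: a DoG filter (r = 6) and a
ridge operator pick the best-focus slice by maximal summed ridge length;
a membrane probability (pluggable, with the same fallback as the
membrane module) is median-filtered, Otsu-binarized, cleaned of regions
below 300 voxels, and eroded (r = 2).

## Synthetic scenes and what they do and do not show

* **Confocal cell** — a disk with an edge ring at the target area
  fraction carrying a set share of the noise-free signal; the remainder
  uniform or concentrated in Gaussian puncta.  Photon (Poisson) noise
  then Gaussian read noise.
* **Cell stack** — a sphere (radius 40 px ≈ 4.3 µm at 0.108 µm/px,
  0.25 µm z-spacing) with fraction f of the signal in a 1.5 px surface
  shell, the rest uniform inside; isotropic Gaussian PSF (σ = 1 px
  lateral); about 400 photons at the blurred shell peak (SNR ≈ 20).
* **TIRF movie** — a tapered circular footprint (3 px rim, since
  membrane curvature leaves the evanescent field gradually) on a nonzero
  coverslip background (70 vs 100 photons inside), plus a static
  fine-grained footprint texture (σ = 1 px, 4% of background).  The
  texture matters twice: real footprints are not flat, and without it a
  sharp-but-featureless frame is indistinguishable from a defocused one,
  so focus classification has nothing to learn.  Its grain is chosen
  fine so it lives in the wavelet detail bands the particle detector
  discards, and its amplitude at the point where it stays below the
  detector's evidence threshold while remaining visible to the raw-frame
  focus measures.  Insertion events appear at full amplitude (60
  photons, spot σ 1.2 px — SNR ≈ 5 against the shot noise) and disperse
  with σ growing 1.2 → 4 px over ~10 frames and the peak decaying with a
  5-frame constant; microclusters ramp linearly over 10 frames and
  persist; designated frames are defocused (σ = 3 px) before noise.
* **Correlated pair** — two jointly Gaussian channels from a shared
  latent field, offset ten standard deviations above zero so the
  nonnegativity clip never biases the correlation.

Passing tests on these scenes show that the implementations recover what
they are designed to recover under the stated noise and geometry.  They
do not show robustness to cell motion, photobleaching, non-spherical
cells, nonuniform interiors (the membrane decomposition assumes an
approximately flat interior profile), realistic confocal PSFs, or the
domain shift between synthetic and annotated real training data for the
two classifiers.

## Numerical choices

Coordinates are 0-based (row, col); all stated radii/thresholds apply in
pixel units, with physical conversion only at reporting.  Welch's
unequal-variance one-sided t-test is used throughout detection (particles
are bright excursions); its p-values match an independent textbook
computation to 1e-10.  Gaussian surface fits use bounded least squares
and simply drop non-converged rays.  Ties: central-slice selection takes
the lower index; the three-section position assigns boundary centroids
to the nearer-interface band; greedy linking resolves conflicts closest
pair first.  All stochastic paths take explicit seeds (default 0) and
are bit-reproducible for a given seed.
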