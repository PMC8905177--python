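# Methods

This note documents the models, defaults and numerical choices behind
`rgcpipe`, and what the synthetic experiments do and do not establish about
real recordings.

## The two-factor identification model

A unit is accepted as a DREADD-expressing RGC only when two independent
lines of evidence coincide:

* **Pharmacological evidence.** Its spontaneous activity increases by more
  than `change_thresh_pct` (default 50 %) after CNO, measured as the larger
  of the percent changes in mean firing rate and in burst index over the two
  spontaneous epochs (≥5 min each is recommended; below 60 s is an error).
* **Anatomical evidence.** Its spike-cluster centroid lies within
  `radius_um` (default 60 µm) of a GFP-labelled soma registered into the MEA
  frame.

Neither factor suffices alone: amacrine cells expressing the same construct
drive activity increases in unrelated RGCs (the *confound* population, which
can outnumber genuine matches ten to one), while proximity alone picks up
silent neighbours.  The 60 µm radius accounts for the offset between the
soma and the spike-initiation site at the axon initial segment (usually
<30 µm, occasionally more) plus localization error.  The
`distance_change_profile` diagnostic reproduces the threshold-justification
analysis: pooled (distance, change) points for all units within 200 µm of
any soma, with kernel-density FWHM summaries of the change marginal and of
the supra-threshold distance distribution.

Conventions worth noting:

* `percent_change(0, x>0) = +∞`, so a unit recruited from silence passes any
  increase threshold (excitatory DREADDs can recruit silent cells).
* Only *increases* qualify; `change_pct = max(ΔMFR, ΔBI)` is signed and the
  threshold is one-sided.
* The burst index is the fraction of spikes inside maximal runs of ≥3 spikes
  whose ISIs are all <100 ms (the cited formula is not restated in the
  source literature; these parameters are exposed).  A percent change of the
  burst index counts only when at least one epoch contains ≥300 burst spikes
  (~80 bursts in 5 min): below that the index rests on a handful of chance
  ISI runs and its relative sampling error exceeds the 50 % decision
  threshold, so the burst change is reported as 0.
* Matching is many-to-one by default (somatic and axonal units may both sit
  within radius of one soma); `nearest_only` restricts each soma to its
  closest qualifying unit.

## Registration and segmentation

The local weighted mean transform follows Goshtasby's construction: around
every control point a full second-order bivariate polynomial (6 terms per
coordinate) is least-squares fitted to its `n_neighbors` (default 50)
nearest control points; an arbitrary point is mapped by the weighted average
of all local polynomials whose support covers it, with weight
`w(R) = 1 − 3R² + 2R³` for `R = distance/radius_i < 1`, where `radius_i` is
the distance to the n-th neighbour.  Points outside every support are
extrapolated with the nearest control point's polynomial and flagged.
Degree-2 polynomials contain all affine maps, so affine ground truth is
recovered exactly (≈1e-12 px in practice).  Image resampling traverses the
fixed grid, maps it back through an LWM fitted in the opposite direction,
and interpolates the smooth inverse displacement from a 4-px lattice;
sampling is bilinear and out-of-domain pixels are zeroed and flagged.

GFP segmentation is the classical chain: Kapur maximum-entropy threshold on
a 256-bin histogram spanning the image range (ties broken toward the lower
level), flood-fill of holes (4-connected background), removal of components
below `blob_min_size_px` (default 50 px, 8-connectivity), then per-component
centroids and equivalent diameters `2√(area/π)` converted to µm.  The
size-filter boundary keeps components of exactly the minimum size.  All
public coordinates are µm in the MEA frame: 0-based pixel indices, x =
column, electrode (i, j) at (42·i, 42·j) µm.

## Response features and typing

PSTHs convolve each trial with a unit-mass Gaussian (sd 25 ms) evaluated
exactly on a 1-ms grid, then average trials.  From the chirp PSTH: the bias
index `(R_on − R_off)/(R_on + R_off)` over 1-s windows after the contrast
step edges; the response duration from the post-onset peak to the first
crossing of baseline + 25 % of the peak-minus-baseline; and the baseline
rate from the pre-stimulus segment.  Bar responses are summarized as mean
spike counts per direction, from which DSI = `|Σ r e^{iθ}|/Σ r` and OSI =
`|Σ r e^{2iθ}|/Σ r`.  Units with `max(DSI, OSI) ≥ 0.33` form the
non-stationary pool.  Within each pool, units below the 25th percentile
(linear interpolation) of either SNR or reliability are discarded.  Both
quality metrics are defined so that higher is better — SNR as the variance
over time of the trial-mean curve divided by the time-averaged across-trial
variance, reliability as the mean pairwise Pearson correlation of
single-trial curves (0 substituted for constant trials) — which makes the
"below the percentile" rule coherent for the pair.

## SPIKE dissimilarity, clustering, gap statistic

The time-resolved SPIKE dissimilarity is computed from its piecewise
definition with auxiliary spikes at both interval edges; between consecutive
spikes the profile is linear in time, so the time average is an exact
segment-by-segment integral (the test suite checks agreement with a dense
numerical integration oracle to 1e-6).  Spikes closer than 1e-12 of the
interval are merged as physically coincident to avoid squared-ISI
underflow.  The unit-level distance is the mean over all n×n cross-unit
pairs of chirp trials; the diagonal is 0 by convention (the within-unit
trial-to-trial floor is *not* subtracted, so identical units sit at the
floor, not at 0).

Clustering is average-linkage agglomeration on the precomputed distances
(Ward requires Euclidean geometry; linkage is configurable).  The cluster
number is selected by the gap statistic: within-cluster dispersion
`W_k = Σ_c (pairwise sums)/(2 n_c)`; the reference null draws `B = 50`
datasets uniformly over the bounding box of the classical MDS embedding of
the distance matrix (positive eigenvalues, capped at 10 dimensions), scores
them with the same linkage on Euclidean distances, and
`gap(k) = mean_b log W*_k − log W_k`, `s_k = sd_b(log W*)·√(1+1/B)`; the
chosen k is the smallest with `gap(k) ≥ gap(k+1) − s_{k+1}` (else `k_max`,
flagged).  Stationary and non-stationary pools are clustered independently;
distances span the full chirp presentation including the initial step.

## The synthetic experiment

The generator emulates the statistical structure the pipeline assumes, at
desk scale.  A default scene holds 150 somata on the 2.688 mm array; 2 %
(3 somata) are DREADD-expressing with CNO gains drawn uniform in
[1.8, 2.2], and ten confounds per DREADD cell receive gains from the same
distribution but no GFP label — a ~1:10-scale model of the per-retina
proportions the method faces (tens of matches versus hundreds of confounds
among over a thousand units).  By default confounds stay ≥120 µm from
DREADD somata (the planted-truth regime); `confound_clearance_um=None`
places them uniformly, in which case chance co-localization alone bounds
matching precision (≈0.95 observed; it scales with GFP-cell sparsity).
Spike centroids are displaced from somata by a truncated-exponential AIS
offset (mean 15 µm, capped at 30 µm by default) plus 2 µm isotropic jitter.
An optional burst mode inserts doublets (4 ms) during CNO with configurable
probability, raising the burst index with only a bounded rate change.

Spikes come from inhomogeneous Poisson processes over archetypal rate
templates (three stationary, five motion-selective classes, plus a silent
control).  Because the SPIKE metric is sensitive to spike *timing* and
nearly blind to proportional rate scaling, the archetypes are separated by
temporal structure, as real types are: ON/OFF polarity and transient decay
at the contrast steps, distinct frequency bands and carrier phases during
the sweep, and distinct contrast-sensitivity onsets and phases during the
contrast modulation.  Firing during stimulation is organized in
phase-locked packets (rectified carriers raised to the 4th power, amplitude
proportional to the instantaneous frequency so the expected spikes per
cycle stay constant, ceiling 250 Hz), with near-silent interludes — the
regime in which spike-timing metrics resolve cell types, and a reasonable
cartoon of light-driven RGC firing.  Dark spontaneous rates (1–8 Hz,
class-specific) are set independently of the light-adapted chirp baseline.
Template amplitudes are balanced so all archetypes have comparable
single-trial SNR and reliability: the quality filter is meant to remove
noisy units (the silent class is always discarded), not whole response
classes.  DS/OS classes modulate bar responses by `1 + cos(θ−θ₀)` or
`1 + cos 2(θ−θ₀)`.

Micrographs are rendered at 1.4 µm/px (1920²): vessels as random smooth
curves rasterized in the fixed frame and re-rasterized after applying the
ground-truth warp (similarity plus a sinusoidal displacement, default 5 px
amplitude at a 3000 px period — a gentle, sub-cycle field-scale distortion
that degree-2 LWM neighbourhoods can represent); the GFP image renders
soft-edged 18 µm disks at warped DREADD soma positions over a background
gradient and Gaussian noise.  120 landmark pairs are sampled on the vessel
curves and satisfy `moving = warp(fixed) + jitter` (0.5 px) by
construction.

**What passing tests do and do not show.**  The generator demonstrates that
every stage does what it claims under its own assumptions: Poisson spiking,
stationary gains, disk-shaped somata, smooth invertible warps, and
archetypes that differ in timing.  Real recordings add non-Poisson firing,
nonstationary drift, photoreceptor adaptation, overlapping somata,
stitching artefacts and manual-landmark error, none of which are modelled;
real cluster structure is also far less crisp than planted archetypes, so
recovery rates here are upper bounds, not forecasts.

## Problem sizes and determinism

Default analyses run on one CPU in minutes: recovery cohorts use 12 units
per archetype with 5 chirp trials (the pool sizes after quality filtering,
~26 and ~44 units, keep the gap statistic's simulation-error term small);
matching studies use 20 seeded 150-unit scenes; the full pipeline processes
one default scene in ~40 s.  All randomness flows from integer seeds
through `numpy` `SeedSequence` spawning, so every artefact — including the
end-to-end summary — is bit-reproducible for a fixed configuration, and the
configuration hash stamped into each output directory prevents mixing
artefacts across configurations.

## Known limitations

* The burst-index definition stands in for an uncited formula; its count
  floor (300 burst spikes) deliberately silences the burst channel for
  low-rate units, whose identification then rests on the rate channel.
* Quality metrics (SNR, reliability) are documented interpretations of a
  companion methodology that is not restated in the source literature.
* The gap-statistic null (uniform box in MDS space) is the simple reference;
  principal-component-aligned boxes would be tighter for elongated clouds.
* LWM accuracy degrades when the true warp varies on scales smaller than
  the control-point neighbourhoods; with ~120 landmarks and n = 50 the
  transform resolves field-scale distortion only.
* Matching precision under uniformly placed confounds is bounded by
  geometry (GFP-cell density × the 60 µm capture disc), not by the
  algorithm; scenes with dense labelling will show proportionally more
  chance matches.
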