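# Methods

`isletca` quantifies cytosolic Ca²⁺ dynamics of pancreatic beta cells in
tissue-slice imaging and the ultrastructure of their mitochondria–ER
contacts in electron microscopy.  This note documents the models,
estimators, parameter choices, and known limitations.

## Signal model and synthetic data

The trace generator is the reference model the analysis is tested against.
A cell's fluorescence is

    F(t) = B · b(t) · (1 + Σᵢ aᵢ · exp(−(t − tᵢ)² / 2σᵢ²)) + ε(t)

with baseline `B` (default 100 intensity units), multiplicative
photobleaching `b(t) = exp(−t/τ)` (τ = `bleach_tau_s`, ∞ disables), and
additive white Gaussian noise ε of standard deviation `noise_sd`.
Transients are symmetric Gaussian pulses parameterized by their full width
at half maximum, `FWHM = 2√(2 ln 2) σ ≈ 2.355 σ`; a symmetric kernel keeps
the detector's width accuracy directly assertable against ground truth.
Peak amplitudes are `amplitude_snr` times `noise_sd` (times a unit
reference when `noise_sd = 0`, so noiseless ground-truth runs still carry
events).

Event times follow a renewal process with log-normal inter-event intervals
(IEI); `iei_dist = (median_s, dispersion)` with dispersion the standard
deviation of the log, so the stated median is exact.  Halfwidths are
log-normal the same way.  Strictly positive, right-skewed intervals match
the long-tailed kinetics distributions seen in islet recordings; the
default dispersion of 0.3 gives visible spread without frequent event
pile-ups.

Cell–cell coupling is phenomenological: each connected component of the
coupling adjacency graph shares an "islet clock" event train, and each
member adopts each clock event with probability `shared_prob`, otherwise
firing an independent private event.  This tunes pairwise trace
correlation continuously from ≈0 (`shared_prob = 0`) to 1
(`shared_prob = 1`, noiseless) without simulating gap-junction biophysics.

Movies place cells as non-overlapping disks; every pixel of a cell carries
the cell's noiseless trace plus independent pixel noise, and background
pixels carry noise only.  What the generator deliberately does not
emulate: microscope PSF blur, motion, inhomogeneous illumination,
intracellular amplitude gradients, photon-counting (Poisson) statistics,
and asymmetric rise/decay transient shapes (an asymmetric kernel exists as
an option but is not the default).  Passing tests therefore demonstrate
correctness of the algorithms under the stated signal model, not
robustness to every artifact of real recordings.

Organelle-mask layouts are axis-aligned rectangles with known gaps.  Their
contact truth is computed in closed form (point-to-rectangle distances
walked along the rectangle boundary) — an independent route from the
image-based module, which uses distance transforms and Moore boundary
tracing — so agreement between the two is a meaningful check.

## Segmentation

The *statistical image* is the per-pixel temporal mean plus a high
temporal percentile (default 99th, linear interpolation between order
statistics).  Active pixels score above inactive pixels of equal mean, so
oscillating cells separate from background.  The image is thresholded with
the intermeans/ISODATA criterion by default.  Otsu (offered as an option)
maximizes between-class variance, but when cells and background are
cleanly separated the criterion is constant across the empty gap of the
histogram and histogram-based implementations return the lowest maximizer,
which grazes the background's upper tail and sprays noise components;
ISODATA centres the threshold midway between the class means.  Touching
cells are split by a watershed on the distance transform (markers from
`peak_local_max`), and 8-connected components pass area gates (defaults
30–2000 px at 64–256 px frames).  Labels are ordered by centroid,
row-major, for determinism.  Manual ROI curation is replaced by optional
user-supplied label images.

## Photobleaching correction (F/F₀)

F₀ is a robustly fitted `a·exp(−t/τ) + c` baseline: the fit is iterated
three times, each time excluding samples more than 2 robust standard
deviations (1.4826 × MAD) *above* the current fit, since Ca²⁺ transients
are positive-going.  τ is bounded to [1 s, 10⁷ s].  If the exponential
does not beat a constant baseline on trimmed residuals (lower 90% of
squared residuals, insensitive to transients), the constant — the trace
median — is used, so a flat trace maps to exactly 1.0.  A rolling
10th-percentile baseline (`method="percentile"`) handles non-exponential
drift.

## Event detection

Detection scans dyadic timescales 1, 2, 4, …, 256 s.  At scale `s` the
F/F₀ trace is band-pass filtered by a difference of Gaussian smooths with
σ = s/2.355 and 2s/2.355.  The band is standardized by a noise floor
obtained by propagating the trace's white-noise level — estimated robustly
as 1.4826 × median|ΔF/F₀| / √2, which events barely touch because they are
smooth at the sample scale — through the filter's ℓ₂ norm.  A MAD taken on
the filtered trace itself was rejected: in densely oscillating traces the
events inflate it and suppress recall of wide events.  The band is *not*
re-centered before thresholding: the filter has zero DC gain, and a robust
center would be dragged negative by the events' own side-lobes, turning
quiet stretches into false positives.  Excursions above `z_thresh`
(default 4) become candidate events; candidates must lie at least two
scales from either trace edge, where filter edge effects dominate the
small large-scale floors, and scales without interior room are skipped
with a warning.

Each candidate's halfwidth is measured on the de-bleached trace, lightly
smoothed (σ = scale/8); the smoothing broadening is afterwards removed in
quadrature, which is exact for Gaussian pulses.  The local baseline is the
10th percentile of a ±3-scale window excluding the event — a low quantile
rather than a median because, at inter-event intervals of ~3×FWHM,
neighbouring events occupy most of the window and bias a median upward
(measured width bias −0.14 s with the median, −0.02 s with the decile).
Half-maximum crossings are located by linear interpolation; the event
midtime is the midpoint of the crossing pair and the halfwidth their
separation.

Cross-scale merging proceeds fine-to-coarse by midtime containment: two
detections are one event when either midtime lies in the other's FWHM
interval; the higher peak-z wins.  A coarse candidate containing two or
more already-accepted midtimes is a bridge across distinct oscillations
and is discarded — necessary because per-scale floors shrink with scale,
making coarse detections systematically more "significant".

Measured on the generator's conditions (amplitude 8σ, FWHM uniform in
[2, 6] s, IEI = 3.5×FWHM, 20 Hz, 600 s): recall 1.00, FWHM mean absolute
error ≈ 0.14 s, false positives ≈ 0.2 per 600-s pure-noise trace.

Population filters: ROIs with fewer than 5 events over the whole recording
are discarded (counted before the band filter — total activity decides
membership), then events are kept only for halfwidths in [1 s, 10 s],
inclusive at both ends.

## Summaries and statistics

Events are assigned to protocol conditions by half-open intervals
[start, end); events in gaps are "unassigned".  Inter-event intervals are
differences of consecutive midtimes within an ROI; an interval takes the
condition of its earlier event and is discarded when its endpoints
straddle a condition switch, avoiding artifactual long intervals at
solution changes.  Per-condition medians pool events across ROIs (IEIs
computed within ROI, pooled across ROIs; a per-ROI-median mode is
provided).  Even-sized medians use the central-pair mean.

KDEs use a Gaussian kernel with bandwidth = factor × sample standard
deviation (factor 0.2 by default; the scalar `bw_method` convention),
renormalized to unit trapezoidal integral on the evaluation grid.

The Mann–Whitney U test enumerates all group labelings of the pooled
average ranks when C(n_a+n_b, n_a) ≤ 20 000 — exact with ties — with
two-sided p = P(|U − n_a·n_b/2| ≥ |U_obs − n_a·n_b/2|); larger samples use
the normal approximation.  Student's t (equal variances) and the
two-sample Kolmogorov–Smirnov test come from scipy.  No multiple-testing
correction is applied; raw p-values are reported.

## Dose–response

The four-parameter logistic `bottom + (top − bottom)/(1 + (EC50/c)^h)` is
fitted by unweighted least squares in log-concentration space (standard
for ramps spanning decades, e.g. 0.1–100 nM epinephrine).  Initialization
is data-driven (extreme responses; geometric-mean concentration; slope
sign from the response direction).  Fits are canonicalized to
`top > bottom` with the Hill sign carrying direction, removing the
(bottom, top, h) ↔ (top, bottom, −h) degeneracy.  Constant responses and
fewer than 4 distinct concentrations are rejected.  Normalizing responses
by a pre-agonist baseline median is available as an explicit helper.

## Functional networks

"Cross-correlation" is the zero-lag Pearson correlation of de-bleached
traces within a condition's time window (≥30 s); a ±max-lag option exists
but is off by default, since a correlation threshold of 0.7 corresponds to
explaining ~half the variance (R² > 0.49) only in the zero-lag reading.
Edges connect ROI pairs with correlation ≥ 0.7 (inclusive).  Metrics:
mean node degree 2|E|/K; average local clustering (degree < 2 contributes
0); global efficiency — mean inverse shortest-path length over ordered
pairs, 0 for disconnected pairs, which keeps the metric defined for
fragmented networks.  Zero-variance traces get zeroed correlations with a
logged warning.

## Mitochondria–ER contacts

A perimeter pixel is a mask pixel with ≥1 of its 4-neighbours outside the
mask.  A perimeter pixel is in contact when any ER pixel centre lies
within 10 nm (Euclidean, centre-to-centre, inclusive — 2 px at the 5 nm/px
default) of its centre, computed via a distance transform of the ER mask.
Contact sites are runs of contiguous in-contact perimeter pixels along the
Moore-traced boundary (cyclic; wrap-around runs joined) of length
≥ 10 nm, i.e. ≥2 px at 5 nm/px; a single in-contact pixel (5 nm) is not a
site.  A mitochondrion is ER-coupled when strictly more than 5% of its
perimeter pixels belong to qualifying sites; exactly 5% is uncoupled.
Rotating or mirroring the mask pair leaves all counts and classifications
unchanged, and the contact fraction is non-decreasing in the gap
tolerance.

ER surface-to-volume from 3D masks: surface by exposed-face counting
(exact for voxel objects, overestimates smooth surfaces) or marching cubes
(option, better for smooth structures; on a digitized ball of radius 20
voxels it reproduces 3/r within ~9%); volume is always the voxel count
times the voxel volume; anisotropic voxel spacings are supported.

## Problem sizes and numerical choices

Tests and the acceptance script run the movie pipeline at 6 cells on
64×64 px frames, 600 s at 20 Hz — enough events (≈50–300 per movie) to
estimate medians while keeping a full 10-seed × 2-group study desk-sized.
Network properties use 8-cell, 300-s trace populations.  Detector
benchmarks use 600-s single traces.  All generators accept a seed and are
bit-reproducible; the pipeline writes a manifest (parameters, input
SHA-256 hashes, package version) and contains no timestamps, so re-running
an identical configuration is byte-identical.

## Known limitations

* The detector assumes approximately white trace noise when setting band
  floors; strongly correlated noise (e.g., slow focus drift beyond what
  F/F₀ removes) would need the MAD-based floor variant or pre-whitening.
* Events closer than roughly one FWHM merge at detection; no deconvolution
  or spike inference is attempted.
* FWHM accuracy degrades near trace edges (events within two scales of an
  edge are not reported at that scale).
* The 4PL fit reports a convergence flag but no parameter uncertainties.
* Contact-site length is counted in pixels along the boundary, not along a
  smoothed sub-pixel membrane contour.
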