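# Methods

This note documents the models, defaults, and numerical choices behind
arborquant, and what its synthetic-data validation does and does not
show about real data.

## Conventions

Images are lateral views, anterior left, dorsal up; the flag is carried
on every `PixelImage` because angle signs are meaningless without it.
Axial angles (line orientations) live on (−90°, +90°] with 0° along the
anterior–posterior axis and negative angles descending toward posterior.
Distances are micrometres, behavioral lengths centimetres, times in
seconds (imaging) or minutes (branch dynamics), matching the units each
assay is reported in.

## Orientation profiling

Per-pixel orientation uses the structure tensor: Gaussian-derivative
gradients at σ_g (default 1 px), tensor components smoothed at σ_T
(default 2 px), both settable in µm.  Line orientation is the minor
eigenvector, θ = −(½·atan2(2J_xy, J_xx−J_yy) + 90°) after the y-axis
flip from array to visual coordinates.  Pixel weight is tensor energy ×
coherency, with a coherency floor (default 0.1) that excludes isotropic
pixels; on noise-free single-orientation images the tensor orientation
agrees with a raw finite-difference gradient-orientation oracle within
2° on >99% of strong-gradient pixels.  Histograms use right-closed 1°
bins; total histogram mass equals the summed admitted weights exactly.

The tubeness filter is the multiscale Hessian vesselness of Sato
(scikit-image), single scale, bright ridges; scales below one pixel are
rejected as unresolvable.

Group comparison is per-image trapezoidal AUC over a chosen angular
range followed by a Welch t-test.  The alternative — a z-test assembled
from group means and standard errors — is available as
`mode="summary"`; per-image is the default because it propagates
between-image variance honestly.  Normalized (percent-of-total)
profiles are recommended for orientation-bias questions so that overall
signal differences between groups cannot masquerade as directional
ones.

## Branch metrics

Branch density: eight 3-µm horizontal bands placed dorsal→ventral.  The
band spacing and anchor are configuration (recorded in output); the
`standard_for_image` grid spreads the bands evenly over the central 88%
of the image height.  Each band is Otsu-thresholded independently and
connected components of ≥ 2 px are counted.  A band whose dynamic range
is under 2% of the image's is treated as signal-free: Otsu has no
meaningful split there and would binarize the faint tails of structures
outside the band.  "Crossing count" therefore means objects present in
the strip, not skeleton intersections — matching a particle-counting
procedure rather than a tracing one.

Dynamics statistics are closed-form functions of scored event tables
(events are inputs; no automatic event detection).  Loss ratios for a
type with zero events are NaN, an explicit undefined marker.  Both
pooled and per-neuron loss ratios are emitted because the replicate
unit for inference is genuinely ambiguous; tests use per-neuron values.
Growth velocity is accumulated path length over elapsed time
(time-reversal invariant).  Rose histograms bin per-step directions in
15° sectors by default; zero-length steps carry no direction and are
excluded from the step count.  Sister-branch angles are measured
node-to-tip at 15 and 75 min after bifurcation with linear
interpolation between samples; a branch that retracted before the
offset yields NaN (no data), and the measure is symmetric in branch
order.  Nascent-branch scoring admits terminal branches ≤ 10 µm and
reports the excluded count.

## Kymographs and transport

Kymographs resample the traced polyline at 1-px arc steps and average
across an odd perpendicular line width per step; z-stacks are
max-projected per frame.  Distance increases away from the cell body
(the path's first vertex), so positive ridge slope is anterograde.

Track extraction (the published workflow measured kymographs by hand;
`tracks_from_frame` imports such hand annotations): the kymograph is
smoothed along distance (σ = 2 px, matched to the spot size), per-frame
peaks found with prominence max(30% of dynamic range, 4× the MAD noise
estimate), linked greedily by motion-predicted nearest neighbor (linear
fit of the last ≤ 5 anchors, tolerance 20% of the maximum per-frame
displacement, one-frame gaps allowed), and fragments merged when one
chain starts ≤ 5 frames after another ends on its linear extrapolation
with consistent slope.  Tracks need ≥ 3 frames and ≥ 1 µm net
displacement; net displacement < 0.5 µm flags a track non-motile (the
denominator for "% anterograde of motile" statistics).  Velocity is the
slope of a constant-velocity fit.  Crossing ridges are resolved
greedily; behavior on crossings is documented, not guaranteed.

Transport frequency is normalized to tracks·min⁻¹·(10 µm)⁻¹ so segments
of different lengths are comparable; the normalization is logged with
the summary.

Branch-point accumulation divides post-activation frames into four
equal windows (≈ 7–8 min each for a ~30 min movie), max-projects each
window over time (and z), takes the mean ROI intensity, subtracts the
pre-activation ROI signal measured the same way, and normalizes to the
corrected first window.  The series is invariant to affine intensity
rescaling of the stack; a corrected t1 ≤ 0 flags the series invalid
rather than producing unstable ratios.

## Behavior

Touch assay (50 fps, 1050 frames): response time runs from the first
moving frame after the stimulus to the last moving frame before a gap
of more than 15 still frames; bouts are movement runs separated by more
than 5 still frames.  The two gaps are distinct parameters: inter-bout
pauses last ~7–8 frames, so the bout separator must sit below that and
the termination criterion above it.  Non-responders are flagged and
excluded from summaries.

Freezing: per-step speeds (frame-to-frame displacement × fps) are
median-filtered over 3 steps with edge padding, and a freeze bout is a
maximal run of sub-threshold steps spanning ≥ 3 s of wall time
(boundary inclusive; m sub-threshold steps span m+1 frames).  Step
speeds rather than central differences are used because central
differences blur the bout boundary by one frame, which matters at the
3.0 s criterion; the median filter still suppresses single-frame
tracker glitches.  The speed threshold defaults to 0.2 cm/s — tracked
fish are never at exactly 0 cm/s — and is configurable and logged.  The
visual "except for gills" part of the published criterion has no
trajectory counterpart; the speed threshold is this package's
operationalization, not the authors'.

Tank sessions: the upper/lower boundary is the geometric half height of
the water column.  Zone times are per-frame counts × frame period, so
upper + lower equals session length exactly.  Total velocity is path
length over elapsed time; mobile velocity averages only steps at or
above the speed threshold and is therefore ≥ total velocity, with
equality exactly when no sub-threshold steps exist.  Group statistics
report binary outcomes (entered upper, froze) per experiment day when a
day column exists — the replicate unit of those panels — and test them
with Fisher's exact test; continuous metrics go through the
normality-screened test chooser.  Habituation curves aggregate per
exposure; untrackable sessions are omitted and counted, and an exposure
with no fish yields no row rather than a zero.

Statistical glue: Shapiro–Wilk screen at α = 0.01 per group (a screen
should catch clear non-normality; at α = 0.05 roughly 10% of genuinely
Gaussian two-group datasets would be kicked to the rank branch), then
Welch t / one-way ANOVA or Mann–Whitney / Kruskal–Wallis.  Identical
samples short-circuit to p = 1.  No multiple-comparison correction by
default (tests are reported per panel); Holm adjustment is available.

## Synthetic data

The generators define the package's study conditions; all are
deterministic given spec + seed.

**Arbors.** Segments are straight Gaussian-profile lines (anti-aliased
rasterization then Gaussian blur, σ = 1.2 px) — a reasonable stand-in
for diffraction-limited neurites.  Orientations come from a von Mises
mixture on the doubled angle, the natural axial distribution;
concentration ≥ 1e5 collapses to the mean exactly, and
`stratified_mixture` allocates component counts by largest remainder so
every image carries the exact mixture proportions.  Defaults: 192×192 px
at 0.5 µm/px, 25 segments of 15–35 µm, two broad lobes at ±60°
(concentration 3) mimicking the ventral-posterior/ventral-anterior
arbor structure; SNR is peak signal over noise SD.  Placement enforces
(i) ≥ 8 px between centrelines, so each segment stays a distinct
connected component after thresholding, and (ii) endpoint clearance
from ROI-band edges, so band membership is unambiguous at the tube
width; together these make the 8-band crossing counts exactly
recoverable on noise-free renders.  Bias-detection benchmarks use 30
segments on 256×256 px with a concentrated (κ=20) +10% component at
−35.5° — the injected mass sits inside the tested angular window.

**Movies.** Constant-velocity puncta (Gaussian spots, σ = 1.5 px,
0.2 µm/px) on a 1D path, rendered directly in kymograph geometry (or as
a t,y,x stack with the path on a row — the profile mode separates
track-detection error from path-tracing error).  Frame intervals default
to 2.5 s within the 2–5 s acquisition convention.  Runs truncate at the
path domain and movie end; truncation is recorded in ground truth, not
an error.  Benchmark movies use runs of max(6, 14·|v|) µm so that every
particle lives ≥ ~5 frames across the 0.1–2.0 µm/s sweep.

**Events.** Poisson initiations per neuron per type, uniform initiation
times, Bernoulli retraction, anterior/posterior labels on retracted
events.  Defaults use the published wild-type values (GCB 2.22/h, IB
0.99/h, losses 0.13/0.10) so "default" simulations resemble the real
assay scale.

**Trajectories.** A swim/pause/freeze jump process discretized at the
frame rate.  Freeze dwells are freeze_min + exponential (every labeled
bout satisfies the criterion); pauses are capped two frames below it;
swim bouts last ≥ 4 frames so the detector's 3-step median filter
cannot merge adjacent immobile bouts; a freeze that could not reach its
minimum before session end is not started.  Swimming moves at constant
speed with persistent heading and mirror reflection at walls (a
reflection that would cancel the step is retaken along the reflected
heading — a swimming frame always displaces the fish).  Zone preference
is implemented as a per-bout target zone with confinement after entry;
preference 0 keeps a lower-zone fish in the lower zone exactly.
`expected_state_fractions` gives the semi-Markov occupancy (jump-chain
stationary distribution weighted by mean dwells) under a
continuous-dwell approximation.  Pause↔freeze transitions default to
zero; with nonzero rates, adjacent immobile bouts would merge in any
speed-threshold detector and ground-truth bout matching no longer holds.

## What passing tests show — and what they do not

Recovery on this synthetic data demonstrates internal consistency: the
estimators invert the generators at the stated tolerances and the group
tests have the claimed power at the study sample sizes.  The generators
omit uneven illumination, structured background (skin autofluorescence),
curved/branching neurites, photobleaching, z-drift, crossing-ridge
ambiguity beyond what greedy linking handles, and tracker artifacts
other than sub-threshold jitter.  Exact branch-density recovery in
particular depends on the separation/clearance constraints; real arbors
touch and cross, where object counts undercount crossings by design of
the thresholded-component procedure itself.

## Problem sizes

Benchmarks use 18 orientation angles (20 noisy replicates each), 100
bias replicates of 2×20 images, 20 density seeds, 200-neuron event
tables (≈ 900 events), 5-velocity sweeps plus 20 clean and 20 noisy
20-particle movies, 50 trajectories of 300 s, and 200 power replicates
per design — sizes at which the Monte-Carlo error of each reported
quantity is comfortably below its acceptance tolerance.
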