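# Methods

## Scope and data model

`netarch` quantifies the architecture of 2-D projections of cross-linked
actin networks and the binding kinetics of single fluorescent molecules
on them. The in-memory objects mirror the measurement chain: a
`FieldSpec` (bounded field of view, µm, with the camera pixel size and a
root RNG seed), `Snake`s (ordered `(x, y, intensity)` samples tracing a
cable), `Junction`s (crossover centroids), `PointPattern`s (junction or
focus centroids), track tables, and dwell-time sets. Filament tracing
itself (SOAX's energy-minimizing contour evolution) is out of scope; its
text output is parsed.

Coordinate convention throughout: origin at the centre of the top-left
pixel, x rightward, y downward, 0-based pixel indices, converted to µm
on load. Defaults follow the instrument values the analyses were
designed around: pixel size 0.078 µm (78 nm/pixel camera magnification),
video rate 20 frames/s (0.05 s frame interval), snake sampling distance
c = 0.625 µm (8 pixels).

## Spatial randomness of junctions

For a pattern of N points, each point's nearest-neighbour distance
r_NN is the minimum over its pairwise separations; `R_NN = Σ r_NN / N`.
The Poisson reference at density σ (points/µm²) is `r_rand = 1/(2√σ)`,
and the randomness index is `R = R_NN / r_rand`: ~0 when points
coalesce (aggregation), 1 for complete spatial randomness, and maximal
for triangular-lattice packing. The nearest-neighbour search is
k-d-tree accelerated but contractually identical to exhaustive search
(property-tested bit-for-bit against an O(N²) oracle).

**Density.** σ defaults to count / field area; a convex-hull mode is
provided for cropped fields. This matters for the lattice calibration:
on a finite field the measured density of a lattice differs from the
asymptotic one by a perimeter-order term, so the calibrated maximum of
R measured on a desk-scale lattice (60×60 µm at 1 µm⁻², interior points
at a two-spacing margin) is 2.161, slightly above the infinite-lattice
limit 2·√(√3/2) ≈ 2.149. The package reports what the measurement
procedure yields on finite data, because that is the procedure applied
to real fields.

**Edge handling.** By default no edge correction is applied. Border
points have truncated neighbourhoods, which inflates R_NN and biases R
upward by about +0.4% at 10⁴ points on a 100×100 µm field (documented
in a test). The optional guard-zone mode excludes points within a
configurable margin of the border as nearest-neighbour *sources* while
keeping them as *targets*; with a 2 µm guard the Poisson calibration is
unbiased within sampling error. Calibration tests use the guard mode;
analyses of real fields may prefer the uncorrected default for
comparability across conditions.

## Cable intensity and bundling

Q is the mean intensity along a snake, either from the per-point
intensities carried in the tracer output or sampled from an image by
nearest-pixel lookup, with optional background subtraction (both modes
provided; whether measured Q values should be background-subtracted is
an acquisition-dependent choice). Because bundle fluorescence is
additive below the diffraction limit, Q scales with the number of
bundled filaments — the synthetic renderer reproduces this exactly
(multiplicity-2 cables are twice as bright). S is the adjusted
(small-sample-corrected) Fisher–Pearson skewness of the per-snake Q
distribution, the definition spreadsheet `SKEW` functions use; S = 0
for a symmetric distribution and grows as a minority of cables bundle.

## Curvature and persistence length

A snake is resampled at uniform arc length Δs; ΔT is the unsigned angle
(in [0, π]) between consecutive tangents and `K = mean(ΔT)/Δs`. Under a
worm-like chain, per-step curvature magnitudes are half-normal,
`P(K) = √(2 l_p c/π)·exp(−l_p c K²/2)` (unit-normalized; verified by
quadrature), giving the closed-form MLE `l_p = 1/(c·⟨K²⟩)` with a
Kolmogorov–Smirnov goodness-of-fit against the same density.

**Sampling-distance bias.** The estimate is unbiased when Δs equals the
snake's own sampling distance (the default Δs = c). Resampling an
m-times finer chain at Δs uses chords, which average tangent noise and
shrink the ΔT variance by (2m²+1)/(3m²) — a 4/3 inflation of l_p at
m = 2, approaching 3/2 as m → ∞ (verified analytically and by
simulation). The raw MLE is reported with no bias correction, flagged
in the fit provenance; Δs should match the tracer's sampling distance.

## Junction editing

Neighbouring junctions closer than 1.2·c are fused. Fusion is
single-link (transitive): chains of sub-threshold gaps collapse to one
junction at the unweighted centroid of the original members, with
incident-snake lists unioned. The merge iterates to a fixed point so
the operation is idempotent and independent of junction input order.
Pruning removes snakes below configurable length / mean-intensity
thresholds (the programmatic counterpart of manual spurious-snake
editing), never touching junctions; removals are logged.

## Foci segmentation and compaction time courses

Images are binarized (Otsu by default, manual override recorded in the
output), connected components labelled (8-connectivity, configurable),
and components kept only if their area strictly exceeds 50 µm². Q_foci
is the mean of original-image pixels under the binary mask; centroids
are intensity-weighted. `ΣQ_foci = Σ A_foci(px²)·Q_foci` integrates the
compacted fluorescence; the spacing of focus centroids reuses the
junction R statistic. Over a compaction run, R(t) is fitted by ordinary
least squares and ΣQ_foci(t) by `Q_∞(1 − e^(−t/τ))` with a zero
intercept — compaction starts at perfusion (t = 0).

## Single-molecule kinetics

A dwell is a maximal run of consecutive frames in one track; gaps split
dwells. Dwells touching the first or last frame of the record are
right-censored: ignoring censoring biases k_off upward (tested — a
naive 1/mean on a window-censored set overestimates a 0.2 s⁻¹ rate by
>30%). The bound fraction is the fraction of dwells strictly longer
than the detection threshold (default 6 frames = 0.3 s at 20 fps,
configurable).

Survival models are exponential mixtures fitted by maximum likelihood.
Because recorded durations are whole frames (ceiling quantization: a
molecule visible during any part of a frame counts that frame), the
likelihood for quantized data is interval-censored — an m-frame dwell
contributes S((m−1)Δ) − S(mΔ) — which removes the ~Δ/2 discretization
bias a continuous-density fit would incur at rates comparable to the
frame rate. Censored dwells contribute survival terms; fitting only
above-threshold dwells left-truncates the likelihood at the threshold
so fitted rates refer to the full distribution. The mono fit on
continuous uncensored data reduces to k = 1/mean (agreement with the
optimizer property-tested to 1e-8 relative); the bi fit runs 10
deterministic-seeded Nelder–Mead restarts, reports rates descending
with amplitudes summing to 1, and raises (recommending mono) when the
mixture collapses to a boundary. AIC enables mono/bi selection.

MSD curves are time-averaged per track over all start points and
ensemble-pooled with per-lag pair weighting; `fit_dlat` fits a weighted
line over the first 4 lags (bias/variance compromise for short tracks)
with an offset absorbing the localization-noise floor (≈ 4σ_loc²), and
`D_lat = slope/4`; negative slopes clip to 0 with a flag. Kymographs
sample a polyline at one-pixel arc spacing, taking the maximum over an
odd transverse width per sample, stacked time × arclength.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (parameters, field seed); the same
seed is bit-reproducible, and different generator families draw from
separated seed streams. Defaults are the study's operating conditions:
20 fps, 0.078 µm pixels, 20 s observation windows (a 400-frame video
record), and recovery settings at the reported fit values (k = 2.55 s⁻¹
mono; 0.43/1.2 s⁻¹ + 0.57/0.06 s⁻¹ bi, amplitudes normalized to sum to
1; D = 0.37 µm²/s; l_p = 4.5–10 µm).

- Point patterns: homogeneous Poisson; Thomas process for aggregation
  (chosen for its closed-form intensity = parent density × mean
  offspring); triangular lattice with optional Gaussian jitter for
  optimal spacing. Offspring/jittered points falling outside the field
  are discarded.
- Filaments: discrete worm-like chains with i.i.d. Gaussian tangent
  increments of variance step/l_p. Rendering integrates the path onto
  the pixel grid, scales by filament multiplicity (additive bundles, no
  quenching), convolves with a Gaussian PSF (default σ = 0.12 µm — the
  instrument's PSF is not calibrated, so this is configurable), adds a
  flat background and Poisson shot noise. No photobleaching, blinking,
  or EMCCD excess noise; no 3-D generation.
- Dwells: exact exponential mixtures, ceiling-quantized to frames,
  right-censored at the window. Tracks: Brownian increments of per-axis
  variance 2DΔt plus i.i.d. localization noise. Foci: Gaussian blobs
  with the analytic above-half-max area (2πr²ln2) recorded in ground
  truth and overlap flagged.

Passing recovery tests therefore demonstrate estimator correctness
under the stated noise models, not robustness to the full pathology of
real recordings (uneven illumination, tracing errors, track-linking
failures, bleaching).

## Problem sizes and numerical choices

Test and calibration problem sizes are chosen as the smallest that make
the statistical assertions sharp: 60×60 µm lattice (≥ 2500 interior
points) for the hexagonal calibration; 20 seeds × 10⁴ points for the
Poisson calibration; 10⁴ chain segments for l_p; 1200 / 5000 dwells for
mono / bi recovery; 200 tracks × 100 frames for D. Convergence
tolerances: 1e-10 (simplex) on the mixture likelihood, 1e-12 on the
mono log-rate; curve fits via Levenberg–Marquardt defaults. Degenerate
inputs raise informative errors rather than returning silent values:
empty patterns (density undefined), < 2 points (no R_NN), constant
samples (skewness, auto-threshold), all-zero curvature (infinite l_p),
identical dwells (degenerate likelihood).

## Known limitations

- R carries the uncorrected edge bias by default (documented above).
- l_p is a raw MLE; finite sampling distance and tracing noise bias it
  (no correction applied; flagged in provenance).
- Location classes for dwells (junction vs cable) use track-centroid
  distance to the nearest junction (< c), a geometric proxy.
- Kymographs are for visualization; dwell statistics come from track
  tables, not streak-length reading.
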