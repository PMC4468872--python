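# Methods

This note documents the models, estimators and numerical choices behind
`fibrilmap`, and what the synthetic validation does and does not show.

## The staggered-overlap protofibril model

A protofibril is modeled as a single axis of extended Fn dimers. Dimer
`k` occupies the axial interval `[kL, kL + E]`, where `E` is the dimer
end-to-end length and `L` the repeat length of the assembly; adjacent
molecules therefore overlap antiparallel over `O = E − L` at their
N-termini. Epitope sites per dimer: N-terminal → both ends `{kL, kL+E}`
(per period the N labels form pairs split by `O`, the "split peaks" seen
in real patterns); C-terminal → two coincident labels at the dimer centre
(the C-termini meet at the inter-monomer disulfide bridge); an internal
site at distance `d` from the centre → `centre ± d`. Defaults `E = 133 nm`
and `L = 95 nm` are the measured means of the system the package was
built for; both are plain constructor arguments.

Molecules sit on a single axis (a protofibril is treated as one molecule
thick); bundles add parallel axes 10 nm apart. The exact C-terminal
epitope position relative to the bridge is not known to better than a few
nm; it is modeled at the dimer centre with a configurable internal offset.

## Labeling and localization model

Each epitope independently carries a label with probability `efficiency`
(default 0.7 — realistic immunostaining). A labeled epitope's fluorophore
is displaced isotropically in 2D by the antibody linkage error
(`Normal(0, 8 nm)` by default, approximating a primary+secondary IgG
stack; 0 for direct dye conjugates). Each fluorophore produces a
geometric number of localizations (support ≥ 1, mean 2 — a simple,
testable stand-in for blinking statistics), each displaced by its own
localization precision drawn from a truncated normal (mean 6 nm, s.d.
1 nm, matching a good red-dye dSTORM channel). Photon counts are
exponential; frames uniform. All randomness flows from one
`numpy.random.Generator`, so a seed fully determines the output.

Two deliberate deviations from the plain defaults:

- **Dimer spot pairs** (`simulate_dimer_pair_spots`) model *selected*
  measurements: a real analyst fits only spot pairs that are visible as
  two distinct spots, so each end's blink count is conditioned on a
  minimum (default 5) and the blink mean is higher (10) — a directly
  conjugated dye imaged over tens of thousands of frames accumulates many
  localizations. Without the selection step, ~2 % of simulated pairs have
  ≤ 3 localizations and produce meaningless fits that no one would accept
  from an image.
- **Junction stains** (`simulate_junction`) use a dense site set (termini
  plus six internal sites) with efficiency 0.9 and blink mean 3: bundling
  analyses use lysine-conjugated protein or polyclonal antibodies, which
  label quasi-uniformly along the molecule rather than at one epitope.

What the generator does *not* emulate: drift residuals, channel
cross-talk, astigmatic 3D PSFs, camera gain statistics, fibril curvature,
and out-of-focus background. Passing recoveries therefore demonstrate the
correctness and calibration of the estimators under the stated stochastic
model, not robustness to every instrumental artefact of real data.

## Line profiles

Localizations within a perpendicular band (half-width 100 nm) of a
user-drawn polyline are projected to nearest-segment arc length (ties at
shared vertices go to the earlier segment) and rendered in 1D as
bin-integrated Gaussians of each localization's own precision on a 2.5 nm
grid. Each in-band localization carries unit integrated weight, so the
profile integral counts localizations. Rendering kernels are floored at
σ = 1 nm to avoid delta spikes.

## Periodicity by autocorrelation

The profile is mean-subtracted and autocorrelated with unbiased per-lag
normalization (divide by the overlap count `n − k`, then by the
variance), giving exactly 1 at lag 0; a biased mode (divide by `n`) is
available. Equivalence with direct O(n²) lag sums is asserted to 1e−10 in
the tests. Local maxima beyond a 30 nm minimum lag (below the smallest
expected repeat, excluding the self-peak) with prominence ≥ 0.05 form the
peak ladder.

The periodic/non-periodic call — made by eye in classical practice — is
made quantitative here: *periodic* iff the first four peaks have a
spacing coefficient of variation ≤ 0.15 **and** the k-th peak lies within
0.15·L of `k·L`, with `L` the mean peak spacing. Anchoring the harmonic
test on the mean spacing rather than the first-peak lag matters: the
first peak is quantized to the 2.5 nm lag grid and the error would be
amplified k-fold. The repeat estimate refines the first peak by the
vertex of the parabola through it and its two neighbours,
`L̂ = lag + (h/2)(y₋ − y₊)/(y₋ − 2y₀ + y₊)`; a non-concave triple falls
back to the unrefined lag with a warning. Under the default synthetic
conditions, ~60 % of fibrils classify periodic and the mean `L̂` recovers
the true repeat within ~1 nm (s.d. ~4 nm over seeds); random Poisson
controls classify periodic in < 10 % of runs.

## Two-channel phase

Cross-correlation uses the same mean-subtraction with joint
normalization `sqrt(var_a · var_b)`. The default is the *biased*
(triangular-tapered) estimator: phase is read off near lag 0, and the
taper guarantees that a periodic in-phase pair attains its global maximum
at lag 0 rather than at a distant repeat. Phase is interpreted on the
*averaged* correlogram over fibrils; a single fibril's cross-correlogram
is dominated by stochastic voids.

## End-to-end distances

Paired-spot profiles are fitted by `A₁G(μ₁,σ₁) + A₂G(μ₂,σ₂) + b` with
independent widths (nothing forces the two spots to share a width), via
bounded least squares. Initialization: the two most prominent local
maxima at least 3 bins apart, ties toward the leftmost. A fit is flagged
unresolved when only one maximum exists or `|μ₂ − μ₁| < max(σ₁, σ₂)`.
The distance estimate is invariant to profile translation and intensity
scaling, and its bias is < 2 nm for separations ≥ 5σ (simulated).
Distance populations are summarized with a strict `>` threshold
(80 nm for photobleaching data, separating doubly-labelled single termini
from true dimer pairs; 0 keeps everything).

## Stepwise photobleaching

Spots are detected in the fifth movie frame (index 4) as local maxima
above threshold; 9×9-pixel ROIs must be isolated (both members of an
overlapping pair are dropped) and free of saturated pixels (default
65535) in every frame. The summed-ROI trace is segmented into plateaus of
≥ 5 frames by greedy change-point placement (each step adds the split
that most reduces the residual sum of squares, followed by a
re-optimization pass of every change point between its neighbours), with
the number of steps selected by BIC (`n ln(RSS/n) + (2k+1) ln n`). An
exhaustive enumeration over all admissible change-point sets is provided
for short traces; greedy and exhaustive agree on 100 % of noiseless and
≥ 95 % of Poisson-noise 60-frame traces when run over the same model
order.

Quality rules: reject traces with upward steps, step heights varying by
more than a factor 2, incomplete bleaching (final plateau above the
supplied background level by more than half the smallest step), or a
reduced χ² > 3 of the plateau fit under Poisson variance. For each step,
the summed ROI after the step is rescaled by the plateau-length ratio and
subtracted from the summed ROI before it; the difference image isolates
the bleached fluorophore and is fitted by a pixel-integrated 2D Gaussian
(x, y, width, total photons, constant offset). Residual structure (mean
residual of any ROI quadrant beyond 2 standard errors) discards the whole
spot; this check is skipped when residuals are numerically negligible.
The per-step precision estimate uses the Thompson-style Gaussian-PSF
error formula (shot-noise + pixelation + background terms) on the
difference image. On noiseless movies the pipeline recovers positions to
< 0.5 nm; at realistic photon counts (≈ 500 photons/frame/fluorophore
over ≥ 60-frame plateaus) per-step precisions are ≈ 1.4 nm and propagated
pair distances good to ≈ 2 nm.

## Cross-sections and the junction metric

A section box (200 nm long, 50 nm wide by default) projects its
localizations perpendicular to the fibril axis into 2 nm bins, fitted by
a Gaussian plus constant offset. FWHM = 2√(2 ln 2)·σ ≈ 2.355 σ is an
upper bound on fibril diameter (precision and linkage error broaden it;
a zero-width fibril shows the precision floor ≈ 2.355·σ_loc). Density is
`(N_box − offset · n_bins)/length`, clipped at 0 with a flag.

Two numerical safeguards, found necessary in validation: the fit is
seeded from moment estimates with the background seeded from the edge
bins, and the fitted offset is capped at the edge-bin level plus its
standard error. Without the cap, the non-negative offset rectifies bin
noise into a *count-dependent* density bias that systematically
penalizes brighter (bundled) segments. Boxes generated for synthetic
junctions are widened so that their edge bins see only background
(bundle width + 10 transverse sigmas).

At a junction, each branch density is the mean of three adjacent
non-overlapping sections, and `Δ = (B − A1 − A2)/B`. Δ is exactly 0 for
pure bundling and invariant to global density rescaling. As a per-
junction ratio it carries a small Jensen bias (≈ −cv(B)² ≈ −0.01 at the
synthetic counting depth), inherent to the formula; the pure-bundling
null is therefore a statistical check (mean within 2 s.e. over ≥ 30
junctions, one-sample t-test at α = 0.01) with the usual ~5 % intrinsic
false-alarm rate of a 2-s.e. criterion.

## Architecture arithmetic

`O = E − L` with `se_O = sqrt(se_E² + se_L²)` (the two measurements are
independent); `E ≤ L` is a domain error. Module geometry sums
per-module linear lengths (FnI 2.8 nm, FnII 2.5 nm); FnIII has no
assigned length and must be supplied explicitly, since no comparable
single value exists for type III modules in a fibrillar context.

## Problem sizes and determinism

The validation suite and the acceptance script run at desk scale: 50
simulated protofibrils / spot pairs per recovery, 30 junctions for the
bundling null, 100 Poisson traces for the step-finder equivalence,
200-frame movies on 21×21-pixel fields. These sizes put the recovery
standard errors well below the assertion tolerances. Every simulation is
reproducible from a single integer seed; the pipeline writes a
provenance record (config hash, seed, package version) next to its
results.

## Known limitations

- Polylines and junction boxes are inputs; there is no automatic fibril
  tracing or junction detection.
- The periodic/non-periodic fraction depends on the quantitative
  classification thresholds (CV ≤ 0.15, prominence 0.05) and on the real
  data's noise; only its direction (periodic model ≫ random control) is
  meaningful.
- Merging of re-localizations is single-sweep sequential chaining:
  idempotent for emitters separated by more than the merge radius, but a
  second pass over overlapping emitter clouds may merge further since
  centroids move.
- Cross-correlation amplitudes depend on the normalization convention;
  only peak/trough lag positions are interpreted.
- The photobleaching camera model omits EM-gain excess noise; photon
  counts are treated as Poisson.
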