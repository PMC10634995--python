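# Methods

This note records the model behind `lrrwind`, the numerical choices that
make it behave, what the synthetic fixtures do and do not establish, and the
known limitations. Reading order follows the pipeline.

## Geometric model

An LRR solenoid is modeled as a space curve γ(t) (ordered Cα positions, t in
residues) that coils with period p ≈ 20–30 residues around a smooth core
curve. The quantity of interest is the cumulative winding number w(s): the
number of revolutions of γ around the core up to residue s, measured in the
normal plane of the core. For an ideal solenoid w is linear with slope 1/p
inside the domain and flat outside; everything the package annotates
(boundaries, repeat units, anomalies, motif audits) is read off this
profile or its spectral refinement.

## Core smoothing and why σ_core = 12

The core is the Gaussian-smoothed trace (reflect boundaries, kernel radius
⌈4σ⌉). The bandwidth matters more than it looks: a Gaussian of bandwidth σ
attenuates the coil harmonic by exp(−½(2πσ/p)²). If the core keeps a
residual coil (e.g. ~29% at σ = p/4), its tangent precesses on a cone once
per turn, and the parallel-transported frame then picks up holonomy — the
swept solid angle — which *removes* winding: a 10-turn solenoid can read
under 5 turns. At σ = p/2 = 12 the residual is 0.7% and the deficit is a
few hundredths of a turn. The default is therefore 12 residues;
substantially smaller values silently destroy the turn count and larger
ones only blur boundary localization.

## Tangents, frames, and the derivative kernel

Tangents are Gaussian-derivative convolutions (σ = 1) of the curve,
normalized per residue. The discrete derivative-of-Gaussian kernel is
exposed as `gaussian_derivative_kernel`; wherever it is used as a
differentiator the kernel is rescaled to unit response on a linear ramp
(the same correction scipy applies to order-1 Gaussian filters), so its
printed normalization constant is immaterial to results.

Frame transport starts from a seeded random orthonormal pair perpendicular
to the first tangent and propagates it with the nearest-orthonormal-matrix
(orthogonal Procrustes) update. Transport is equivariant under in-plane
rotation/reflection of the initial pair, so the planar projection — and
hence |w| — does not depend on the seed; the test suite checks invariance
to 1e−6 and observes ~1e−15. Orientation is normalized so w ends
non-negative; the raw handedness is reported as metadata.

## Winding discretization

The integrand (x ẏ − y ẋ)/(2π(x² + y²)) is accumulated by cumulative sum.
Two numerical choices:

* **Consistent mollification.** ẋ, ẏ from a Gaussian-derivative filter are
  the derivatives of the σ-*smoothed* coordinates. Pairing them with raw
  x, y under-counts every turn by the kernel's frequency attenuation
  (≈3.4% at p = 24, σ = 1 — half a turn on a 14-turn domain). The
  implementation therefore also smooths the positions in the integrand, so
  the summand is exactly dθ/dt of the σ-mollified planar curve; the
  mollified and raw curves have the same winding whenever the mollified
  curve stays away from the origin.
* **Origin guard.** The integrand is singular at the origin. Points within
  1e−6 Å of it are an error (the projection is meaningless there), and the
  mollified squared radius is floored at the same scale.

Agreement with an independent oracle (cumulative unwrapped atan2 of the
same mollified curve) is ~0.002 turns at the endpoint and <0.05 over the
interior; the first/last ~8 residues differ more because the two estimators
treat the reflect boundary differently.

## Breakpoint regression

The two-breakpoint model (flat–sloped–flat, discontinuities allowed) is
minimized exhaustively over breakpoint pairs using prefix-sum statistics;
within a configuration flats take segment means and the sloped piece its
OLS line. The four-breakpoint model (flat–sloped–flat–sloped–flat, slopes
independent) is minimized by stage-wise dynamic programming over the same
per-segment costs; the three interior segments must each span at least
`min_seg_len` (default 5) positions and the outer flats may be empty, so
terminus-abutting domains are representable. Both optimizers are exact:
tests compare them to brute-force enumeration at 1e−9. Ties are broken
toward smaller breakpoints, which matters only for degenerate zero-residual
profiles. Breakpoints are integer positions; segments are half-open index
ranges.

Model selection follows the sloped-residual standard deviation of the
two-breakpoint fit: above `sd_threshold` (default 0.15 winding units,
calibrated on the synthetic suites where clean fixtures stay below ~0.13
and ≥10-residue plateaus exceed ~0.12) the four-breakpoint model is used
and its middle flat piece becomes the anomaly interval. A fit whose
(length-weighted) sloped slope is below `slope_floor` = 1/60 turns/residue
is reported as "no LRR": genuine LRR periods are 20–30 residues, and the
floor guards the all-flat degenerate case.

## Boundary refinement

Least-squares breakpoints alone are systematically over-extended — by five
to thirty residues on the synthetic suites — because w is only meaningful
where the structure actually coils: in flanking regions the projected
displacement is small and erratic, the integrand is noise-dominated, the
core tangent wanders (holonomy), and the resulting slow drift of w is
cheaper for the optimizer to absorb into the sloped segment than into a
flat mean. The refinement step therefore re-localizes the two outer
boundaries with a frame-independent signal: the windowed Fourier power of
the unit tangent field at the fitted period (window = one period). This
power sits on a plateau inside the coil, falls to background over half a
window at the domain edge, and crosses 50% of the plateau median at the
edge itself; each breakpoint is walked to that crossing. Interior anomalies
do not disturb it because the walk is anchored at the breakpoints, not
scanned from the middle. Refinement can be disabled
(`boundary_refinement=false`), which reproduces the raw regression
breakpoints.

## Spectral phase and SWL2D

On the annotated domain the tangent field is delay-embedded (window 24,
delay 1; dimension 3·25 = 75), turning per-period oscillation into a loop
in ℝ⁷⁵. A mutual k-nearest-neighbor graph (k = 50, ties to the smaller
index, k clamped below the point count for short domains) approximates that
loop; its unweighted Laplacian's leading non-constant eigenvector pair are
quadrature sinusoids at the coil frequency, verified in tests by DFT bin
(±1) and cross-correlation lag (p/4 ± p/8). Because the first two
non-constant eigenvectors are not guaranteed to be the coil pair on messy
graphs, the selector checks that their dominant frequencies agree within
25% and otherwise scans pairs among the six leading non-constant vectors
for the best match. Disconnected graphs keep the largest component (with a
warning; error in strict mode below 80% coverage), and the pipeline falls
back to union-kNN when mutuality disconnects badly. Phase uses the
two-argument arctangent — the printed single-argument form cannot reach
(−π, π]. Embedding point t maps to residue t + window/2 (center
convention).

SWL2D scores each one-period window of the eigenvector winding profile by
its L2 distance to a secant of the median slope anchored at the window
start; the score is assigned to the window center and is invariant to
adding constants to w. The spike threshold is **absolute** (default 0.4;
w is dimensionless so this transfers across structures) rather than a
multiple of the median score: on the synthetic suites a plateau inflates
the median enough to hide its own spike under a 5×-median rule, while
near-perfect profiles have medians so small that noise exceeds any
multiple. Calibration on those suites: clean maxima ≤ 0.17, ≥10-residue
plateau maxima ≥ 0.72.

## Discrepancy statistic

D sums (w(Rⱼ) − w(Rⱼ₋₁) − 1)² over j = 2…k (k−1 terms; the printed sum
from j = 1 would reference an undefined R₀). It is a per-protein sum, not a
mean; corpus-level comparisons should average per-protein values. Running
differences below 0.5 are flagged as duplicate predictions and above 1.5 as
missing ones; both thresholds are configurable and are reporting aids, not
part of D.

## Synthetic fixtures

`make_solenoid` builds a helix with period 24, radius 8 Å and rise
5 Å/turn (canonical plant-NLR LRR scale) about a straight or circular-arc
axis, samples one residue per step, optionally inserts a straight
out-and-back hairpin excursion perpendicular to the local tangent (return
leg offset ~1 Å so the curve stays non-degenerate), attaches flanks, and
adds isotropic Gaussian coordinate noise last. Flanks are persistent
self-avoiding random walks (3.8 Å steps, 2–15° turning per step) that exit
along the solenoid axis, emulating the semi-extended linkers and termini
that flank real solenoid domains at the 20–60-residue lengths used here.
Ground truth (coil span, repeat boundaries, hairpin interval) is recorded
exactly.

What passing on these fixtures shows: turn counting, boundary and anomaly
recovery are correct when the flanking regions do not themselves coil
around the extended core. What it does not show: behavior when a *compact
globular domain* abuts the solenoid. There the smoothed core curls through
the flank, the transported frame accrues holonomy, and w can drift at a
substantial fraction of the coil rate — boundary estimates degrade (the
periodicity refinement softens but does not remove this). Real multi-domain
receptors sit between these regimes.

## Parameter summary

| parameter | default | units | role |
|---|---|---|---|
| sigma_core | 12 | residues | core smoothing (half period) |
| sigma_deriv | 1 | residues | tangent / velocity bandwidth |
| min_sloped_len | 48 | residues | smallest credible LRR (two periods) |
| min_seg_len | 5 | residues | interior segments of the 4-breakpoint fit |
| sd_threshold | 0.15 | winding units | 2- vs 4-breakpoint selection |
| slope_floor | 1/60 | turns/residue | "no LRR" guard |
| window, delay | 24, 1 | residues | delay embedding (one period) |
| k_neighbors | 50 | – | mutual-kNN degree bound |
| swl2d_window | 24 | residues | SWL2D window (one period) |
| spike_threshold | 0.4 | winding units | SWL2D spike cutoff |
| seed | 0 | – | initial-frame RNG (results invariant) |

## Limitations

* Compact globular flanks (see above) blur boundary estimates.
* Multi-domain chains with more than one solenoid get a single sloped
  region per model; only one domain (plus one interior anomaly) is
  annotated per chain.
* The repeat period is assumed near 24 residues by the embedding and
  SWL2D window defaults; strongly different periods need those windows
  adjusted (boundary refinement already uses the fitted period).
* Chain breaks are kept contiguous in index space; long missing segments
  will distort the local winding around the gap.
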