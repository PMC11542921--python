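# Methods

## The encoding problem

The package treats prosthetic stimulation as an optimization problem with
three parts: an *objective* (squared error between the target image and a
linear reconstruction of the image from evoked RGC spikes), a *constraint*
(responses can only be produced through a calibrated dictionary of
single-electrode stimuli, each with a per-cell Bernoulli activation
probability vector), and an *algorithm* (greedy selection of a temporally
dithered stimulation sequence).  Spikes evoked at different time steps are
assumed independent and to sum within the brain's visual integration window;
refractory masking (below) is what keeps the independence assumption viable.

For a sequence of elements with probability vectors `p_i`, the expected
error splits exactly into a bias term on the cumulative expected response
and a per-step variance term `v_c = Σ_n ||a_n||² p_{n,c}(1 − p_{n,c})`
(cross terms vanish because responses are independent across steps and
`E[A r_i] = A p_i`).  The greedy step minimizes
`||s − A(P + p_c)||² + v_c` over the valid set, with ties broken toward the
lowest element id.  The implementation maintains per-element inner products
and Gram-matrix columns so a pick costs O(elements); an exhaustive-argmin
oracle in the tests pins the incremental update to the definitional form.

## Refractory masking and spatial multiplexing

A cell counts as *targeted* when the chosen element activates it with
probability > θ; any element activating a targeted cell with probability > θ
is invalid for the next `window` steps.  Defaults θ = 0.1, window = 100
steps.  Bookkeeping uses the chosen element's probabilities, not sampled
spikes, keeping selection open-loop.  With multiplexing enabled, several
elements are picked greedily within one time step, re-evaluating the shared
objective after each pick; electrodes within the exclusion radius of an
already-picked electrode are disabled for the remainder of the step.  The
exclusion radius is an empirical quantity (~200 µm in the measurements the
model emulates); the calibration module estimates it from bi-electrode
activation scans via sigmoid threshold fits, inverse-variance-weighted
distance-bin means, and a pair-level bootstrap.

Runs stop early when an entire step selects only the null element.  Because
masked elements can become valid again as cells leave refractoriness, this
is a heuristic stop, not a proof of global convergence; in practice the
objective plateau at stop is indistinguishable from the T_max run.

## Bounds and baseline

* Joint usage relaxation: `min_{w≥0} ||s − ADw||² + vᵀw`, solved exactly by
  an active-set (Lawson–Hanson style) method extended with the linear
  penalty; the KKT residual is verified at return (tolerance 1e−5 relative
  to `‖s‖²`).  This lower-bounds every integer usage vector and hence every
  stimulation sequence from the dictionary.
* Perfect control: non-negative least squares `min_{r≥0} ||s − Ar||²`
  (scipy's NNLS), the floor for an interface with independent control of
  every cell.
* Static pixel-wise baseline: per electrode, mean target intensity over a
  130 µm × 130 µm window maps through a scaled sigmoid
  `i = a + b/(1 + exp(c·s̄ + d))` to a current, snapped to the nearest
  calibrated amplitude in log scale, delivered `n` times (repeats
  interleaved round-robin across electrodes).  Parameters `(a, b, c, d, n)`
  are fit per electrode by cyclic coordinate descent over a structured
  derivative-free candidate grid, minimizing the expected (bias + variance)
  training error with other electrodes held fixed.

Gap metric: `gap = (err_hi − err_lo)/err_hi`, the fraction of error the
better method removes; used consistently for the greedy-vs-relaxed and
relaxed-vs-perfect comparisons.

## Synthetic retina fixtures

The fixture layer replaces ex vivo calibration products:

* Electrode array: offset-row triangular lattice (default 16 × 32 at 60 µm
  pitch; interior nearest-neighbor distance equals the pitch).
* Mosaics: ON and OFF populations placed by dart throwing with a minimum
  same-type spacing of half an RF diameter; somas are RF centers with 10 µm
  jitter.
* Filters: signed 2-D Gaussians (σ = `rf_radius_um`, truncated at 3σ),
  positive for ON and negative for OFF, with peak `gain` in expected-spike
  units.  A single Gaussian (not difference-of-Gaussians) suffices because
  the encoder only consumes the filters linearly.
* Dictionary: for every electrode × amplitude on a 40-level logarithmic
  0.1–4 µA grid, activation probability is logistic in log amplitude with
  slope 6 and midpoint threshold `t(d) = t0 · exp(d/λ)` in soma–electrode
  distance d (t0 = 2 µA, λ = 40 µm).  Elements are dropped if flagged as
  axon-bundle activation (a seeded 10% of high-amplitude elements — the
  detection algorithm itself is out of scope) or if they activate no cell
  with probability ≥ 0.01; one null element is appended.  On the full
  512-electrode array with ~700 cells these defaults retain ~4000 elements,
  and a substantial fraction (~⅓ on the quarter-size fixture) activate two
  or more cells, reproducing the partial non-selectivity that makes the
  dictionary the binding constraint.

Frozen study fixtures (`dither.protocols`): the quarter-array checkerboard
fixture (8 × 16 electrodes, 50 ON + 50 OFF, σ = 45 µm, gain 0.2, pixel grid
8 × 16 at 60 µm) and the sparse wide-field dynamic fixture (full array,
60 ON + 60 OFF, σ = 130 µm, gain 1, 40 × 80 grid at 44 µm).  The
checkerboard pixel pitch matches the electrode span so target dimensionality
(128) is comparable to the cell count (100) — the regime in which coarse
checkerboards are resolvable by the mosaics, as in the recorded analyses.
The dynamic fixture is deliberately sparse with unit gain: the scaled-down
stimulation rate (12 choices per frame instead of 83) supports
proportionally fewer cells per integration window, and unit gain keeps a
cell's full contribution reachable from the spikes evocable within one
window.

What the fixtures do **not** emulate: long-range axonal co-activation
(cells with somas far from the stimulating electrode), non-stationary
response properties, inter-electrode current interactions below the
exclusion radius, and realistic RF irregularity.  Passing tests therefore
show the optimization machinery behaves as specified under calibrated-like
response structure — not that the quantitative gaps equal those of any
particular recorded preparation.  The clearest consequence: the
dictionary-vs-perfect gap measures ~30–38% on the synthetic fixtures versus
>40% in tissue, because purely distance-based activation is more selective
than real dictionaries.

## Dynamic scenes

Gaze: fixation centers are sampled with probability proportional to a
Gaussian-smoothed gradient-magnitude (high-spatial-frequency) map of the
scene; inter-saccade intervals are Gaussian (default 300 ± 100 ms) truncated
at one frame; fixational jitter is a per-frame Brownian walk (3 px SD per
axis), clamped so the 40 × 80 patch stays inside the scene.  Frames are
120 Hz crops at the rounded eye position.

The spatiotemporal reconstruction filter is rank-1: the spatial filters
above, shared causal exponential kernel (support 8 frames ≈ 65 ms, time
constant 3 frames), polarity carried once by the signed spatial columns.
The kernel peak is 1 rather than mass-normalized so a spike contributes its
full calibrated spatial filter to the frame it occurs in.

Dynamic greedy evaluates, at each choice step, the spike's total effect over
its kernel support against the current frame's residual (a frozen-target
lookahead): `Δ(c) = −2 (Σ_j κ_j) ⟨resid_f, g_c⟩ + (Σ_j κ_j²)(||g_c||² + v_c)`
with `g_c = A p_c`.  A causal encoder cannot credit a spike against frames
already rendered, and future frames are unknown at choice time; evaluating
the full kernel mass against the current residual is the real-time
approximation of minimizing total error over the affected steps, and it
reduces exactly to the static greedy objective for an impulse kernel (an
equivalence the tests assert).  Refractory masking runs per choice step with
the static defaults.

Scene assembly averages each reconstructed patch pixel over all gaze
positions whose *filter-covered* region included it; a coverage map counts
contributions.  The error-vs-saccades curve reports whole-scene relative
MSE with uncovered pixels reconstructed as zero (the covered-pixel variant
is also emitted): the covered-only error is non-monotone early on — each
fixation changes which pixels enter the metric — which would make
"first saccade to reach a level" ill-posed.  The jitter benefit is the ratio
of saccade counts at which the two conditions first reach the matched error
level both actually attain within the budget (the final error of the worse,
no-jitter run).

## Perceptual budget optimization

`min_{w_i ≥ 0} d(s, G({A D w_i})) + λ Σ_i ‖w_i‖₁` over per-patch usage
vectors, where G averages patch reconstructions over a half-patch-stride
grid of fixation locations (the desk-scale discretization of "all possible
saccade locations") and d is relative MSE or 1 − SSIM.  Expected responses
only; no variance term, matching the formulation.  SSIM uses the standard
reference parameterization (11-pixel window, Gaussian weights σ = 1.5,
k₁ = 0.01, k₂ = 0.03, dynamic range 2 for signed intensities), averaged
over fully contained windows; its analytic gradient (verified against
finite differences) drives projected quasi-Newton descent (L-BFGS-B with
non-negativity bounds).  SSIM is non-convex, so solutions carry a
convergence flag and the projected-gradient norm.

## Numerical choices and defaults

| parameter | default | meaning |
|---|---|---|
| θ, window | 0.1, 100 steps | refractory masking rule |
| retention threshold | 0.01 | minimum max-cell activation probability |
| amplitude grid | 40 levels, 0.1–4 µA, log | calibration grid |
| t0, λ, slope | 2 µA, 40 µm, 6 | activation threshold model |
| axon fraction | 0.1 | high-amplitude elements excluded |
| exclusion radius | 200 µm (when multiplexing) | simultaneous-stimulation spacing |
| kernel | exp, 8 frames, τ = 3 | temporal integration at 120 Hz |
| KKT tolerance | 1e−5 · ‖s‖² | relaxed-solver stationarity check |
| SSIM | win 11, σ 1.5, k₁ .01, k₂ .03 | reference parameterization |

Degenerate inputs: zero targets make relative MSE undefined (raised);
dictionaries must carry the null element; non-identifiable sigmoid fits
(all-silent or all-saturated scans) are flagged and excluded from pair
summaries; empty distance bins are omitted.

Problem sizes in the shipped protocols — 20 targets × up to 10,000 steps on
the quarter-array fixture, and 100 fixations × 2 conditions × 5 replicates
for the dynamic study — were chosen so a full reproduction completes in
about a minute on one CPU while keeping per-target behavior (sequence
lengths ~10³, sub-percent greedy gaps) in the regime the method is designed
for.

## Known limitations

Single-electrode dictionaries only (no calibrated multi-electrode
elements); linear decoding only; the greedy planner has no lookahead beyond
the frozen-target kernel window; fixture realism limits listed above.  The
pixel-wise baseline optimizer is a structured grid search — adequate to the
baseline's role as a generous reference, not a state-of-the-art fit.
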