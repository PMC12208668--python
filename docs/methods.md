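# Methods

This note documents the models, conventions and numerical choices the
package commits to, and what its synthetic benchmarks do and do not
demonstrate about real recordings.

## Stimulus protocol and normalization

A recording is interpreted against a `StimulusProtocol`: stimulus onset
at `t_on` (default 10 s), removal at `t_on + stim_duration` (default
30 s), total length 60 s, at 2 frames/s. Frame *i* is stamped at
*t = i / fps*, so the first frame is at *t* = 0.

Background is subtracted per frame; negative results are floored at
zero and counted in a logged warning (real background estimates can
exceed a dim ROI in single frames; silently negative fluorescence would
poison F₀). F₀ is the arithmetic mean of background-subtracted frames
with *t* strictly less than the 9-s baseline window — frames 0–17 at
the defaults. The strict inequality is a declared convention; whether
the frame at exactly *t* = 9 s should count is not decidable from the
protocol description, and including it changes F₀ by well under the
frame noise. Traces with F₀ ≤ 0 are rejected (`TraceRejected`) rather
than normalized to garbage. ΔF/F is reported in percent. Consequences
asserted in tests: the baseline-window mean of ΔF/F is 0 to float
tolerance, and ΔF/F is invariant under any common rescaling of
fluorescence and background (illumination/gain changes drop out).

## Laterality

The imaged neuron's body side is a pure lookup over (nose direction,
ventral side from the vulva, focal plane near/far). The table is
generated from a parity rule anchored at (left nose, ventral bottom,
near focal plane) → left, which makes the one property that is
geometrically forced hold exactly: flipping any single field flips the
answer. The anchor itself is a package convention — the original
bench bookkeeping is not recoverable — so only internal consistency is
guaranteed, not agreement with any particular rig.

## Transient model (synthetic data)

Calcium transients are rise-times-decay kernels

k(t; t₀, A, τ_r, τ_d) = A · (1 − e^{−(t−t₀)/τ_r}) · e^{−(t−t₀)/τ_d}, t ≥ t₀

with an onset kernel at stimulus ON and dip and/or bump kernels at
OFF. Defaults τ_r = 1.5 s, τ_d = 8 s give the multi-second transients
of a slow red indicator (jRCaMP1a-class); the closed-form peak time is
t₀ + τ_r ln(1 + τ_d/τ_r) ≈ t₀ + 2.77 s, peak height ≈ 0.595 A. The
five template classes (ON, OFF, OFF-2, ON–OFF, NONE) constrain which
amplitudes may be nonzero and are validated at construction.

Fluorescence is F(t) = background + f₀ · (1 + g(t)/100) · e^{−t/τ_bleach}
with additive i.i.d. Gaussian frame noise. Defaults: f₀ = 100 a.u.,
background 10 a.u., no bleaching, no noise (each configurable). Noise
is Gaussian rather than Poisson for simplicity — at the ~100 a.u.
baselines simulated the distinction is immaterial for pipeline
testing. Bleaching multiplies the signal only, not the additive
background: an explicit, testable convention. Cohort amplitudes are
drawn uniformly from 40–80 %ΔF/F by default, the magnitude range the
averaged population traces display; per-trace seeds derive from the
master seed through `SeedSequence`, so cohorts are reproducible
trace-by-trace and safely parallelizable.

What the generator does **not** model: realistic optics (PSF,
z-sectioning), body movement, indicator binding kinetics, correlated
noise, or baseline drift other than exponential bleaching. Passing the
recovery benchmarks therefore shows the *analysis chain* is correct and
well-calibrated under its stated noise model — not that classification
of real recordings reaches the same accuracy.

## Image stacks and tracking

Simulated stacks render each neuron as an isotropic Gaussian spot
(σ = 1.5 px) whose integrated intensity follows the supplied
fluorescence trace, over a uniform background, drifting linearly;
generation fails if a spot approaches within 3σ of the frame edge.

The tracker follows each spot by the intensity-weighted centroid of
pixels within `search_radius_px` of the previous centroid, with the
local median subtracted before weighting (otherwise a uniform
background biases the centroid toward the window center). ROI
fluorescence is the pixel sum within `roi_radius_px` (default 5 px ≥
3.3 spot σ, so capture loss is < 1 %); local background is the median
of the (r, 2r] annulus scaled to the ROI pixel count. A frame whose
search-window peak does not exceed the local floor by `lost_threshold`
(default 10 a.u.) is flagged and the previous centroid carried; a trace
with > 20 % flagged frames is rejected. Because ΔF/F is a ratio, any
constant capture fraction cancels, which is why the zero-noise round
trip (render → track → normalize) reproduces ground-truth ΔF/F to
≈ 0.05 % RMS, far inside the 2 % budget the tests assert.

## Response metrics and classification

Bar statistics follow the figure conventions: for a transition at
t_ref, pre-window = [t_ref − 10 s, t_ref] (closed), post-window =
(t_ref, t_ref + 10 s] (half-open); the transition frame belongs to
"pre". Amplitudes are max-post minus min-pre; for the OFF statistic
the pre-window is the 10 s preceding removal (t ∈ [20, 30] s), not the
pre-ON baseline — each bar is tied to its own transition. `off_dip` is
the post-removal minimum; `afd_on_max`/`afd_off_max` are the plain
post-window maxima used for biphasic (AFD-style) comparisons.

Classification is threshold-based (the original judgement was by
inspection, so the package declares an explicit, configurable rule):

* **onset** fires when the post-ON maximum exceeds the threshold;
* **dip** fires when the post-OFF minimum falls below its negative
  *and* the trace recovers ≥ `return_frac` of the dip depth by the end
  of the window (mean over the final 2 s — a single end frame is too
  noisy to anchor the judgement);
* **bump** fires when the post-OFF maximum *minus the pre-removal
  level* (mean over the 2 s before OFF) exceeds the threshold — an
  onset transient still decaying through the removal window must not
  masquerade as a removal response.

Labels: dip without onset → OFF (a bump may accompany it); onset and
bump → ON–OFF; onset only → ON; bump only → OFF-2; otherwise NONE.
Exactly one label is always produced, and the evidence list records
every comparison.

Three numerical choices matter and were set by analysis of the
operating characteristics, then frozen:

1. **Detection runs on a 2.5-s boxcar-smoothed copy** of the trace.
   The kernels are ~5 s wide, so smoothing costs a few percent of peak
   height while cutting frame noise by √5. Raw extrema remain the
   reported bar statistics; only the significance decisions use the
   smoothed copy.
2. **The noise scale is estimated from first differences** of the raw
   ΔF/F with 10 %-per-side trimming (Gaussian consistency factor
   0.6615), then scaled to the smoothed series. Estimating σ from the
   18 baseline frames alone makes the threshold itself so noisy that
   false-positive rates triple.
3. **k_sig = 3.5, with a 1 %ΔF/F absolute floor.** The floor keeps
   noise-free traces classifiable (their estimated σ is 0). The 3.5
   accounts for the search over a ~20-frame window: a per-frame 3-σ cut
   fires on several percent of response-free windows purely through
   the maximum over the window. With these settings the classifier
   recovers 100 % of noiseless template labels and ≥ 95 % (typically
   97–99 %) of a 200-trace cohort whose weakest amplitude is 5 baseline
   σ.
4. **return_frac = 0.25.** With τ_d = 8 s a genuine transient dip has
   recovered only ~42 % of its depth 10 s after removal (closed form),
   so demanding 50 % would reject the canonical OFF shape itself; 25 %
   still rejects a sustained depression, whose recovery is ~0.

## Group statistics

Ribbons are pointwise mean ± t_{0.975, n−1} · s/√n per frame (a seeded
percentile bootstrap is available as `method="bootstrap"`); n = 1
groups carry a `ribbon_defined = False` flag instead of a fabricated
interval. Coverage is verified by simulation at 95 % ± 1 %. No
multiplicity correction is applied across frames — the ribbon is
descriptive; inference happens on the scalar bar statistics.

`compare_groups` screens both samples with Shapiro–Wilk at α = 0.05;
both normal → Welch's unequal-variance t-test (safer than pooled when
group variances differ), otherwise two-sided Mann–Whitney. The chosen
path and the screen p-values are recorded. A zero-variance sample is
treated as failing the screen (Shapiro is undefined there); two
identical samples yield p = 1. The adaptive procedure's null rejection
rate is verified at 5 % ± 0.7 %.

`crop_ribbon` exists because plots sometimes clamp ribbons to share
y-axes: it returns a display-only copy whose `statistics()` accessor
raises, so clipped bounds can never re-enter an analysis.

## Chemotaxis statistics

The plate index (A − C)/(A + C) is computed in exact rational
arithmetic and is undefined (an error, not 0) when no worms reach the
arenas. Plates with fewer than 10 scored worms are excluded with
reason "participation"; any further exclusion must arrive as an
explicit user-supplied plate-id list and is logged with reason
"manual" — outliers are never auto-detected, so no silent data editing
can occur.

Condition inference is a fixed-effects two-way ANOVA (genotype × salt,
interaction included by default and toggleable) on included plate
indices via statsmodels OLS. Within each salt, every genotype is
compared to the reference with many-to-one t statistics pooled on the
full-model residual mean square; the family-wise adjustment samples
the comparisons' joint multivariate-t null (correlation
(1/n₀)/√((1/nᵢ+1/n₀)(1/nⱼ+1/n₀)), residual df) with a seeded
Monte-Carlo (default 20 000 draws, MC error on p ≈ 0.05 about 0.0015).
The adjusted p-values agree with an independent Dunnett implementation
to 0.01, and the simulated family-wise error under a global null is
5 % within Monte-Carlo tolerance. Whether the original analysis pooled
within or across salts is unknowable from the figure legends; within-
salt families with full-design variance pooling is this package's
declared choice. All-identical indices (a degenerate but constructible
input) short-circuit to F = 0, p = 1 instead of 0/0 float noise.

The plate simulator draws participation and attraction as independent
binomials, giving E[index] = 2p − 1 exactly; the estimator's
convergence to this value ties the generator and the index module
together in the acceptance run.

## Problem sizes

The shipped benchmarks use 120-frame traces, 200-trace cohorts,
64 × 64 × 120 stacks with two ROIs, 10 000-replicate coverage and
type-I simulations, 5 000-replicate Dunnett FWER simulation, and
10 000 plates per attraction probability — sizes at which every
Monte-Carlo tolerance quoted above is resolvable and the whole
acceptance run completes in well under a minute on one core.

## Known limitations

* The classifier's thresholds are calibrated under the generator's
  i.i.d. Gaussian noise; correlated noise or slow drift in real
  recordings would raise the false-positive rate and should be handled
  upstream (the pipeline deliberately applies no detrending).
* The laterality table guarantees consistency, not correspondence with
  any specific microscope geometry; re-anchor it per rig.
* The OFF-vs-sustained-depression distinction rests on the recovery
  gate; stimuli producing genuinely sustained hyperpolarization would
  need a longer post-window than 10 s to separate.
* Dunnett adjustment is Monte-Carlo: p-values carry ~0.002 sampling
  error at defaults; raise `n_sim` where decisions are marginal.
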