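# Methods

`freezescore` scores freezing behavior — sustained defensive immobility —
from fixed-camera video of a single subject, and reproduces the
session- and cohort-level statistics and the rater-validation protocol
built around that score. This note documents the model, its
assumptions, the parameters that matter, the synthetic data the test
suite relies on, and the numerical choices made where the design was
genuinely open.

## The similarity trace

A session of `n` frames at nominally 30 fps is reduced to `n − 1`
*similarity scores*: the squared Pearson correlation (r²) between each
pair of consecutive grayscale frames, with score `i` spanning frames
`(i, i + 1)`. With a fixed camera and fixed lighting, nearly all pixels
belong to the static background, so r² sits near 1 when the animal is
still and drops when it moves. All downstream durations are
`run_length / fps`.

Conventions the figure of merit does not itself fix:

* Grayscale conversion uses ITU-R BT.601 luma weights (0.299, 0.587,
  0.114).
* Degenerate variance: two pixelwise-identical constant frames score
  1.0; a constant frame paired with anything else scores 0.0, so the
  denoiser's outlier rule treats it as an artifact.
* Pearson r² is symmetric and insensitive to global gain or offset
  changes (lighting flicker does not register as motion); perfectly
  anticorrelated frames would also score 1.0, a case that does not
  arise in cage video.
* Frames are scored whole; an optional rectangular crop is available
  when the recording includes regions outside the cage.

## Denoising

Dropped frames and lighting aliasing produce isolated, anomalously low
scores. Denoising (1) replaces every score at or below an outlier
threshold (default r² = 0.93) with the *modal* score — the center of
the most populated 0.001-wide histogram bin over the non-outlier
scores, ties to the higher bin — and then (2) applies a single-pass
median filter (3-frame kernel, reflect padding). The order is fixed:
substitute, then filter. The mode is computed after excluding outliers
(substituting with a value that is itself an outlier would be
self-defeating). A trace in which *every* score falls at or below the
threshold has no usable stillness signal and raises a degenerate-trace
error routing the session to manual handling.

One property worth stating precisely: outlier substitution is exactly
idempotent (after one pass nothing is at or below the threshold), but a
single-pass 3-point median filter is *not* its own fixed point on noisy
data — that is a structural property of median filters, whose fixed
points are "root signals" reached only after repeated passes. The
package keeps the published single-pass filter; the test suite asserts
the attainable invariant (substitution idempotent; repeated filtering
converges monotonically to a fixed point).

## The per-subject mixture model

The denoised scores of each subject are modeled as a three-component
one-dimensional Gaussian mixture. Lower scores mean more frame-to-frame
change, so components are labeled by ascending mean:

| component | mean rank | interpretation |
|---|---|---|
| motion | lowest | locomotion and large movements |
| ambiguous | middle | scores too ambiguous to classify confidently |
| freezing | highest | stillness |

(The ambiguous component exists to absorb borderline scores, making
freezing/motion assignments conservative.)

Fitting runs `n_restarts` (default 300) independent EM fits from random
initializations and keeps the one with the highest final
log-likelihood. Numerical choices:

* **Initialization**: component means at the trace's 10th/50th/90th
  quantiles plus seeded Gaussian jitter (sd = 0.25 × trace sd); sds at
  the trace sd; uniform weights.
* **E/M steps in log space** throughout (manual log-sum-exp over the
  three components), so scores far in a tail never underflow to NaN.
* **Variance floor** of 1e-8 per component, preventing singular
  collapse onto a single value.
* **Convergence**: relative change of the total log-likelihood,
  `|ΔLL| ≤ em_tol · (1 + |LL|)` with `em_tol = 1e-8`, within
  `max_em_iters = 500`. The EM is vectorized across restarts in chunks;
  each restart's trajectory is independent of the chunking, so a fixed
  seed gives bit-identical winners.
* **Edge-case gate**: a winning fit with any component weight below
  `min_component_weight = 0.01` or adjacent means closer than
  `min_mean_separation = 0.005` carries a warning. The pipeline refuses
  to auto-score such a session (exit status *review-required* plus
  suggested clip frame ranges) — the semi-automated contract. A human
  then supplies approximate component point estimates
  (`override_components`, or `manual_model` when no fit exists, e.g.
  an animal that never moved); the override need not be precise, only
  good enough that every frame classifies to the correct extreme.

Posterior membership probabilities follow Bayes' rule over the three
weighted component densities, computed in log space; each score's
triple sums to 1.

## From posteriors to freezing bouts

A score *qualifies* as freezing when

1. its posterior probability of membership in the freezing component is
   at least `posterior_threshold = 0.95`, **and**
2. its value is not anomalously low under Tukey's boxplot rule applied
   to the denoised scores: `score ≥ Q1 − k·IQR` with quartiles from the
   trace and `k = tukey_k = 1.5`.

Any maximal run of **90 or more consecutive qualifying frames** (3 s at
30 fps) is one freezing bout; shorter stillness is not freezing, and
any non-qualifying frame separates bouts (a 4-s freeze, movement, then
a 10-s freeze is two bouts of 4 s and 10 s).

The quantile condition deserves a design note, because an alternative
reading cuts at the freezing component's own 75th percentile
(`mean + 0.6745·sd`). That variant is implemented and selectable
(`BoutConfig(quantile_rule="upper_quartile")`), but it cannot serve as
a default: by construction only ~25 % of genuine freezing frames exceed
their own component's upper quartile, so the probability that 90
consecutive frames all do is ~0.25⁹⁰ ≈ 10⁻⁵⁴ — the rule would never
detect a bout in any noisy recording. The default applies the quartile
cut the way Tukey's anomaly detection is normally applied — to the data
— where it rejects residual artifact dips without breaking genuine
stillness runs. The configuration records which variant ran.

Other classifier outputs:

* **Motor activity** = Σᵢ P(motion | scoreᵢ), an objective, unitless
  per-session measure of movement, bounded by the trace length.
* **Session summary**: total freezing seconds, bout count, mean bout
  duration (0 when there are no bouts), motor activity, and the
  fraction of scores inside bouts. Bout timing is reported in score
  indices; the one-frame offset between scores and frames (≤ 33 ms) is
  ignored. Tense body posture is deliberately not modeled: human raters
  agree on it only at chance level (κ ≈ 0.2), and the validation below
  shows the similarity-based score suffices.

Raising `posterior_threshold` can only shrink the qualifying set, so
total freezing is monotonically non-increasing in it — a property the
tests assert end-to-end.

## Session and cohort statistics

* **Split-half comparison** (habituation check): per-subject freezing
  totals in the first vs second half of the session, a bout straddling
  the midpoint apportioned by overlap; compared with an
  *independent-samples*, equal-variance t test, so n subjects give
  df = 2n − 2 (18 subjects → df = 34). A paired test would be the more
  orthodox design for within-subject halves; the independent-samples
  form is retained deliberately to match the published analysis.
* **Minute bins**: per-subject freezing probability in consecutive
  60-s bins (fraction of the bin's scores inside a bout; bins partition
  the session, the final bin may be short). The cohort trend is the
  Pearson r of the grand-mean probability against bin index; a constant
  grand-mean series (e.g. a cohort frozen throughout) is flagged rather
  than silently returning NaN. Weighted bin probabilities conserve the
  total freezing count exactly.
* **Correlations** against covariates: Pearson r with two-sided p and a
  Fisher-z 95 % CI. Freezing durations are right-skewed, so y may be
  log-transformed; the transform is ln(y + 1), the +1 keeping subjects
  with zero freezing defined.

## Rater validation

From a scored session, equal numbers of classifier-freezing and
classifier-non-freezing 3-s segments are sampled (non-overlapping,
uniformly, seeded; an unsatisfiable request raises an error naming the
deficient class). Raters label each segment freezing/non-freezing in
isolation; the per-segment consensus (modal label; exact ties resolve
to non-freezing, the conservative direction) stands in for ground
truth. Agreement is measured with Cohen's kappa
(κ = (p₀ − pₑ)/(1 − pₑ); the degenerate pₑ = 1 case is defined as 1
under perfect agreement and an error otherwise), sensitivity and
specificity against the consensus, and human-vs-human reliability as
the unweighted mean pairwise kappa (round robin). Because no analytic
null is standard for kappa here, significance is available as a seeded
permutation test on one rater's labels.

## Synthetic data: what it emulates and what it does not

Two seeded generators share a common behavioral schedule — a
semi-Markov alternation over {freezing, ambiguous, motion} with
exponential dwell times (defaults 6 / 3.5 / 5 s), freezing dwells
floored at 3 s so every ground-truth freezing interval is detectable in
principle. A score's ground-truth state is the state of the *later*
frame of its pair (displacement is applied on entering a frame).

**Direct traces** (`simulate_trace`) draw each score from a per-state
Gaussian truncated to [0, 1] — truncated, not clipped, so no mass piles
up at the boundary and the mixture stays identifiable. Defaults:
motion N(0.955, 0.004), ambiguous N(0.975, 0.004), freezing
N(0.995, 0.002) — a well-separated trimodal regime representative of a
small subject in a wide fixed-camera view, cheap enough for 10⁴–10⁵
score statistical tests.

**Rendered sessions** (`render_session`) draw actual 8-bit frames: a
Gaussian-profile blob over a static i.i.d.-noise texture plus per-frame
sensor noise. The kinematics encode the three states as *speed
regimes*, because that is what distinguishes them physically:

* motion: sustained ~3.5 px/frame travel with an angular-random-walk
  heading (reflected off the walls with a margin that keeps the whole
  blob on screen — a half-visible subject changes fewer pixels and
  would skew its state's score band);
* ambiguous: the same dynamics at ~2.5 px/frame (slow, continuous head
  movement — not zero-centered sputter, which would place many frames
  at zero displacement and make them indistinguishable from freezing);
* freezing: micro-oscillation at a ~0.4 px radius tethered to the spot
  where the animal froze (the behavioral definition permits slow head
  movements; a perfectly static subject would produce a degenerate
  zero-width score pile that no real recording shows, and whose
  baseline would depend on where the subject parked).

Per-frame speeds vary by ~10 % around the state's typical value. The
background texture is i.i.d. per pixel so the displacement →
decorrelation response is spatially homogeneous and the stillness
baseline does not depend on the parking spot. Under the defaults the
rendered state bands come out near motion 0.957 ± 0.020, ambiguous
0.979 ± 0.006, freezing 0.9918 ± 0.0001.

What the generators deliberately do **not** emulate: posture, occlusion
and perspective, multi-animal scenes, camera auto-exposure or lighting
drift, compression artifacts, and the long-tailed behavioral repertoire
of a real macaque. Passing tests therefore demonstrate that the
pipeline recovers ground truth when the modeling assumptions hold and
that it detects (and refuses to auto-score) sessions where the mixture
is degenerate; they do not certify performance on arbitrary real
footage.

## Problem sizes and evaluation protocol

The test suite and the acceptance script use scaled study sizes chosen
to keep full runs routine on a laptop: mixture recovery on ten
9,000-score sessions (5 simulated minutes each) at the full 300
restarts; frame-level detection on five rendered 60-s sessions; the
cohort analyses on 18 subjects × 5-minute simulated sessions; rater
validation on 80 3-s segments (20 from each of 4 sessions, half
classified freezing) with three synthetic raters who err on ~7 % of
segments. Rendered sessions whose fit trips the edge-case gate are
re-scored through the manual-override path, with the reviewer's point
estimates stood in for by the per-state mean similarity from the
ground-truth schedule (the synthetic analog of a human watching labeled
clips); this mirrors the semi-automated protocol, under which a small
minority of real sessions also required manual adjustment.

## Known limitations

* The similarity score is a whole-frame statistic: a large moving
  object elsewhere in view (a second animal, an experimenter's arm)
  registers as subject motion.
* The three-Gaussian model is a deliberate simplification; heavily
  skewed motion-score distributions can push the middle component into
  covering a mixture of behaviors. The edge-case gate catches the
  severe cases; mild misfit degrades sensitivity gracefully.
* Bouts are not merged across short gaps; a single sub-threshold frame
  splits a bout, which biases bout counts up and mean durations down
  relative to a gap-tolerant scorer.
* The fence variant of the qualifying rule and the permutation test for
  kappa are this implementation's choices where the published
  description is ambiguous or silent; both are recorded in the
  configuration and report.
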