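# Methods

`synvar` quantifies how variable upper-limb muscle synergies are within a
subject (across repetitions of the same multi-directional reaching trial)
and between subjects, and how far one subject's synergies generalize to
another's muscle activations. This note documents the models, the
numerical choices, and what the synthetic cohorts do and do not emulate.

## The synergy model

Phasic muscle activity is modeled as a non-negative linear combination of
a small set of time-invariant synergy vectors:

    M = W C + e,     W >= 0 (muscles x N),  C >= 0 (N x T)

where `M` is the muscles x pooled-samples phasic matrix (16 x 900 under
the default design: 100 resampled points per forward phase x 9 reaching
tasks). Factors are fit by multiplicative updates for the squared
Frobenius loss; goodness of fit is the variance accounted for,
`VAF = 1 - SSE/SST`, with the *uncentered* SST (the plain sum of squares
of `M`). Each fit restarts from several uniform-(1e-6, 1) random
initializations (production default 50 restarts) and keeps the lowest-SSE
restart; a restart stops when the relative SSE decrease falls below 1e-6
or after 1000 iterations. Synergy columns are reported unit-norm, with
the compensating scale pushed into the coefficient rows, so cosine
comparisons and cross-subject fixing are scale-free.

The number of synergies is selected from the VAF-vs-order curve: the
smallest `N` with `VAF(N) >= 0.8` whose next synergy adds less than 5% of
variance. The alternative reading — every retained synergy must itself
add at least 5% — is available via `select_model_order(...,
strict_increment=True)`; the default is the stopping rule. If no order
satisfies both conditions, the smallest order reaching the VAF floor is
used; if none reaches it, the largest computed order is returned with a
warning. During cohort extraction the curve stops as soon as the rule is
decidable, which avoids fitting the remaining orders up to 16.

## Preprocessing

Raw EMG (1000 Hz) and wrist speed (100 Hz) are turned into phasic
matrices as follows: the speed trace is smoothed with a centered 0.2 s
moving average (edge-truncated); the forward phases are the n largest
speed peaks, with onset/offset at the last/first crossing of 5% of each
peak's height (the threshold is a conventional reaching-onset choice and
is configurable). EMG is high-pass filtered at 50 Hz (7th-order
Butterworth), full-wave rectified, and low-pass filtered at 10 Hz
(7th-order Butterworth); both stages run forward-backward (zero phase) so
the envelope is not delayed against the kinematics — the effective
response is the squared magnitude of each stage. Each phase is taken with
0.2 s of padding on both sides, absorbing the electromechanical delay;
the tonic (antigravity) component is estimated per channel as a linear
ramp between the mean envelope in the pre-onset pad and the mean in the
post-offset pad, subtracted, and negative residuals are clipped to zero.
The padded phasic segment is linearly resampled to 100 points (linear
interpolation keeps the endpoints exact), normalized per channel by the
maximum over *all repetitions of the subject* (making subjects
comparable), and pooled across tasks. All-zero channels are carried
through as zeros with a warning rather than dropped, preserving the
shape contract. Only forward phases are analyzed; the return movements
are gravity-assisted and carry little phasic activity.

## Similarity and the random-matching null

Synergy order out of NMF is arbitrary, so all comparisons first match
synergies by maximizing total cosine similarity (SSV) over pairings —
optimal assignment on the N x N SSV matrix (Hungarian algorithm); greedy
matching was rejected as order-dependent. Intra-subject similarity
aligns every repetition to an iteratively refined mean (match all
repetitions to repetition 1, average, re-match once to the mean), then
reports per-synergy statistics over all repetition pairs. Inter-subject
similarity averages each subject's aligned synergies (re-normalized),
aligns the subject means to a reference subject — the one with the
highest within-subject similarity, a stable template — and reports
statistics over all subject pairs.

The matrix-level similarity SSM is reported in two modes: `matched`
(mean over the optimally matched pairs; the default, consistent with the
magnitudes this literature reports) and `allpairs` (the literal mean over
all N^2 ordered pairs, which is bounded near 1/N for distinct synergies).
Both are always computed. The null is the random-pairing level: the mean
SSV over all unordered pairs of the pooled synergy population (every
synergy of every repetition of every subject), enumerated exactly.

For the three-level hypothesis test (one-way ANOVA with Tukey HSD), the
sampling unit is the subject: each subject contributes its mean matched
SSV across repetitions (intra), the mean matched SSV of its synergy means
against the other subjects (inter), and the mean unmatched SSV of its
synergies against the pooled synergies of all other subjects (random).
The choice of per-subject units keeps the three groups the same size and
avoids pseudo-replication from the ~10^5 raw pairs.

## Cross-subject reconstruction (rVAF)

To measure generalization, a source subject's repetition-averaged
synergy matrix is held fixed and the coefficients are refit to a target
matrix by non-negative least squares — each time-sample column solved
exactly by active-set NNLS (columns are independent; a
multiplicative-update refit with frozen W was rejected as inexact).
`rVAF = 1 - ||M - W C||^2_F / ||M||^2_F` is reported unclipped: negative
values are informative about transfer failure. The full grid is every
source subject against every (subject, repetition) target, with each
target's own extraction VAF carried along for comparison. The rVAF table
uses N = 4 synergies throughout, matching the fixed-order convention of
the cross-subject analyses.

## Variability statistics

The coefficient of variation (sample SD with the n-1 denominator, over
the mean) is computed per subject across repetitions — for the selected
synergy count and for the VAF at fixed orders 3 and 4 — and pooled over
all repetitions of all subjects ("All"), which folds inter-subject
variability on top of intra. Synergy counts are compared across subjects
with a Kruskal-Wallis test; pairwise post-hocs are Dunn tests with
Bonferroni correction (a parametric Tukey variant is available — the
procedure pairing a rank test with "ANOVA post-hoc" is not standard, so
both are offered and the choice is documented, not asserted).

## The synthetic cohort generator

No public recordings accompany this analysis pipeline, so cohorts are
generated with known ground truth. Defaults mirror the target design:
12 subjects x 10 repetitions x 9 reaching directions, 16 muscles, 4
planted synergies, 1 s forward phases separated by 1 s pauses.

* **Template synergies** are sparse non-negative unit vectors: muscles are
  dealt round-robin so every channel participates somewhere, each synergy
  keeps one private anchor muscle, and supports are topped up to half the
  muscles so most muscles serve more than one synergy (as real upper-limb
  muscles do). Templates are redrawn until all pairwise cosines are below
  0.6 so matching is identifiable.
* **Subject synergies** add Normal(0, sigma_inter = 0.3) noise on the
  template's active entries (rectified, re-normalized). The perturbation
  is support-preserving and recruited weights are floored at 40% of the
  muscle's template weight: subjects modulate a muscle's participation
  but do not silence a recorded channel — a channel with a near-zero
  maximum would otherwise turn into pure amplified noise under
  per-channel max normalization, which no real cohort of healthy
  reaching data shows. The relative floor keeps the zero-perturbation
  limit an exact identity.
* **Repetition synergies** multiply the subject's weights by
  (1 + Normal(0, sigma_intra = 0.05)), so within-subject variation is an
  order of magnitude gentler than between-subject variation — the
  structure whose recovery the acceptance checks assert.
* **Activations** are rectified-cosine direction tuning (preferred
  directions spread evenly on the circle) times Gaussian bursts in
  normalized phase time, truncated to zero beyond 2.4 widths. Burst
  centers are staggered (0.15-0.85 of the phase) with widths ~0.05 of the
  phase (FWHM ~120 ms), so bursts of different synergies have disjoint
  time supports. Disjoint bursts plus anchor muscles make the planted
  factorization provably unique up to permutation and scale, which is
  what lets parameter-recovery tests demand matched cosines >= 0.99 on
  noiseless data.
* **Envelope noise** is additive half-Normal with SD sigma_noise = 0.05
  of the clean-signal RMS, clipped at zero (preserving non-negativity
  without the mean distortion of symmetric clipping).
* **Raw signals** place the repetition envelope on the trial timeline,
  add a tonic baseline (0.2 of the mean phasic amplitude per channel,
  constant over the trial), and modulate band-limited 20-450 Hz Gaussian
  noise (the surface-EMG bandwidth), so the 50 Hz HP / 10 Hz LP chain is
  exercised meaningfully. The wrist-speed trace is one minimum-jerk bell
  per forward phase, zero during pauses.
* **Seeding**: one root seed expands through a fixed counter scheme
  (`SeedSequence([seed, stream, subject, repetition])`) so any single
  trial can be regenerated bit-identically without generating the rest.

Because per-channel max normalization rescales muscle rows, the synergies
that generate the *normalized* matrix are the planted ones divided by the
channel scales; `EnvelopeSet.planted_W` exposes them in those
coordinates, and recovery is always measured there.

**What the generator does not emulate**: motor-unit physiology, electrode
crosstalk and shift, fatigue, powerline interference, trajectory-level
kinematic variation, merging/fractionation of synergies across orders,
and task-to-task changes in activation shape (the planted burst shapes
are shared across repetitions; variation enters through the synergy
weights and envelope noise). Passing tests therefore show the *pipeline*
is correct and that the intra < inter < random structure is recovered
when planted — they do not certify effect sizes on real recordings,
whose similarity levels are substantially lower than the synthetic
cohort's.

## Problem sizes and numerical notes

Cohort-scale tests and the acceptance script run NMF with 2-10 restarts
rather than the production default of 50; on the synthetic matrices the
multiplicative updates converge to the (unique) planted optimum reliably,
and the restart count is a robustness margin for messier real data. The
VAF curve is computed with early stopping. Multiplicative-update
denominators carry a 1e-12 guard; NNLS uses scipy's active-set solver
per column; ties in assignment resolve to the lowest index. Degenerate
inputs fail loudly: zero vectors in cosine similarity, all-zero matrices
in VAF/rVAF, fewer velocity peaks than tasks, EMD padding outside the
recording, unequal orders in matching.
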