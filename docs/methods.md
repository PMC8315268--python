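# Methods

## The question and the measurement

Speakers in conversation sometimes position their articulators toward the
requirements of their *next* utterance well before any sound is produced.
This package measures one observable face of that behaviour: the area
enclosed by the outer lips during the three seconds preceding each
utterance's acoustic onset. If the utterance's first syllable demands a
small lip aperture — a bilabial/labiodental or rounded onset consonant
(/b, f, m, p, ɹ, v, w/) or a rounded nuclear vowel (/ɔ, o, ʊ, u/), the
*labially constrained* condition — an anticipatory posture shows up as a
systematically smaller lip area than for unconstrained utterances, at lags
before the acoustic onset.

## Utterance typing

For every utterance the *reference* is the most recently initiated prior
utterance, whether or not it has ended. A same-speaker reference marks a
restart; so does an other-speaker reference that itself began within
500 ms after the current speaker's own initiation (the partner barged in
and the current utterance resumes the interrupted attempt). Everything
else is a response, timed by the floor transfer offset
`fto = onset_current − offset_reference` and subtyped gap (fto ≥ 0;
a zero offset is a zero-length gap, still non-overlapping),
between-overlap (starts inside the reference, ends after it), or
within-overlap (entirely inside the reference). Restarts and the
conversation-initial utterance never enter the analysis set, and FTO
summaries cover gaps and between-overlaps only: a within-overlap's timing
target is a syntactic closure mid-utterance, so its nominal offset (which
can reach −99 s inside a long turn) does not describe its coordination.

Ties in onset time have no natural order; the classifier refuses them by
default (`tie_break="error"`) rather than silently biasing the typing,
with a deterministic by-speaker policy available.

## Lip area

Area is computed from the four outer-lip landmarks of the 68-point
scheme — left corner 48, top centre 51, right corner 54, bottom centre
57 — taken clockwise as p1..p4. The primary metric treats each perimeter
segment as the hypotenuse of an axis-aligned right triangle and adds a
residual central rectangle:

    A_i = |X_i − X_{i+1}| · |Y_i − Y_{i+1}| / 2   (i = 1..4, X_5 ≡ X_1)
    A_j = |X_1 − X_3| · |Y_2 − Y_4|
    area = ΣA_i + A_j

For quads whose corners are the x-extrema and whose top/bottom points are
the y-extrema this equals `2·bounding_box − shoelace`: it *over*-states
the true polygon area by exactly the box-minus-polygon margin. The
inflation is monotone and within-speaker comparisons are unaffected, which
is all the inference uses; the surveyor's (shoelace) formula is exposed as
an explicitly non-default alternative and serves as the oracle in the
property tests. Absolute values make the metric indifferent to whether the
y-axis points up (3-D millimetre coordinates) or down (pixel coordinates),
so no axis flip is performed. The 3-D millimetre columns are the default
coordinate set — areas are reported in mm² — with the 2-D pixel set
available for camera-frame work.

## Epochs and slices

An epoch is the 90 frames (3,000 ms at 30 fps) ending at the last frame
strictly *before* acoustic onset (half-open convention; a frame falling
numerically on the onset is excluded with a microsecond guard). Slice
offsets map to epoch indices by `round((offset + 3000) · fps / 1000)`;
because only pre-acoustic frames exist, the nominal 0-ms slice is the last
pre-acoustic frame, index 89, ≈ 33 ms before onset. This matters when
interpreting the onset slice: any planted or real contrast is measured a
frame early, and moderation that collapses exactly at onset can retain a
small residue there.

Tracking dropouts (`success = 0`) are linearly interpolated across runs of
at most 3 consecutive frames and remain flagged in the missing mask;
longer runs stay missing and exclude the utterance from affected slices
only. Windows reaching before the start of a recording are padded as
missing rather than discarded, so late slices keep their data.

## Maximum lip movement speed

Over the final 15 first-differences of the epoch (500 ms), each change in
area is scaled by the frame rate to mm²/s and the largest absolute value
is kept. The statistic is translation-invariant and scales linearly with
area, and it is undefined (an error, not a silent zero) when the window
contains missing frames.

## The slice models

At each of the seven offsets (−3000 … 0 ms in 500-ms steps) a linear
mixed model is fitted to the single-frame lip area:

    area ~ constraint * log10(word_count) + random effects

with constraint dummy-coded 0 = constrained, 1 = unconstrained — a
positive coefficient means larger areas for unconstrained utterances,
the posture signature — and word count log10-transformed against its
heavy right skew. Speaker and first word are crossed clustering factors.

**Estimation.** The REML criterion is maximized on the profiled-deviance
scale over the relative Cholesky factors of each random term (L-BFGS-B
with non-negativity bounds on diagonal entries; two deterministic starts).
All per-iteration algebra runs on cached cross-products `[Z X y]ᵀ[Z X y]`
through a Woodbury/Cholesky identity, so a fit costs O(q³) in the number
of random-effect columns, independent of n. Convergence is the
optimizer's success; singularity means a fitted variance below
`1e-8 · var(y)` or a pair correlation within 1e-6 of ±1. Both flags are
carried on the result and drive selection; they are never silently
accepted. The engine reproduces lme4/lmerTest coefficients, standard
errors and Satterthwaite df to ~4 decimals on shared datasets, and
statsmodels' MixedLM is the in-suite cross-check oracle.

**Random-structure selection.** Backward, maximal-first:
`(1 + log10_word_count | speaker) + (1 | first_word)` with the speaker
intercept and slope correlated. Simplification is deterministic: first
drop intercept/slope correlations; then repeatedly drop the single
component (slope or intercept) with the smallest estimated variance
(ties: slopes first, then fewer levels), stopping at the first fit that
converges without singularity. Dropping by estimated variance rather than
by a fixed kind-order matters: with a zero-variance first-word intercept
in the data, a kind-ordered rule discards the genuinely supported speaker
slope first and cascades toward an unclustered fit, which measurably
inflates the moderation test's type-I error (≈ 0.09–0.12 at some slices
in our null simulations) — the smallest-variance rule restores nominal
calibration. If even intercept-only structures fail, the model falls back
to fixed effects only with a loud diagnostic.

**Satterthwaite df.** For a contrast c,
`df = 2·(cᵀC(φ)c)² / Var(cᵀC(φ)c)`, where C(φ) is the fixed-effects
covariance as a function of the variance parameters φ (component
variances/covariances plus the residual variance); the gradient is taken
by central differences and `Var(φ̂) = 2·H⁻¹` from the numerically
differentiated Hessian of the −2 REML log-likelihood (pseudo-inverse at
boundary estimates; a degenerate variance-of-variance falls back to the
residual df with a warning). The construction reduces exactly to n − p
with no random effects, to the Welch–Satterthwaite formula on two-group
heteroscedastic means, and to clusters − 1 on balanced one-way designs.

**Johnson-Neyman regions.** The simple slope of constraint at moderator w
is `s(w) = β_c + β_int·w` with variance quadratic in w; the reported
region is where s(w) is significantly *positive* (the direction that
signals a posture), intersected with the observed log10 word-count span
and mapped back to word counts. The critical value uses Satterthwaite df
recomputed at every candidate w (a fixed mid-span df is available as an
option). Because `cᵀCc` is quadratic in w for any fixed covariance, the
whole df path comes from one set of perturbed covariance evaluations,
and boundaries are refined by bisection; they agree with a 10,000-point
brute-force scan of pointwise t-tests to < 1e-3 log10 units.

**Prediction bands.** Parametric bootstrap: simulate the response from the
fitted model (fixed effects + drawn random effects + residual), refit the
same structure, predict at the population level on the grid
{2, 8 words} × {constrained, unconstrained}; percentile intervals. A
refit failure rate above 10% aborts with a diagnostic rather than
reporting intervals from a censored ensemble. A case-resampling bootstrap
is deliberately not offered for the default path: with crossed random
effects there is no exchangeable unit to resample cleanly.

**Multiplicity.** No correction is applied across the seven slices; they
are reported as seven related looks at one evolving contrast, and any
formal error-rate claim should treat them jointly. The calibration suite
does exactly that (below).

## The synthetic corpus

The source recordings are access-restricted, so the pipeline is validated
on synthetic dyads with known truth. The generator emits the same file
dialects the pipeline reads (annotation TSVs, OpenFace-layout CSVs) plus a
ground-truth sidecar.

**Conversation structure.** Two speakers alternate; 10% of slots are
same-speaker restarts. Floor-exchange offsets are drawn from
N(250, 900²) ms (matching conversational floor-transfer summaries reported for
unscripted dyads); whether an exchange is a gap or a between-overlap *emerges
from the draw's sign*, so the planted gap/between split is Φ(μ/σ) of the
non-within mass and `SimConfig.from_proportions` inverts the relation.
Within-overlaps are short backchannels placed late inside partner turns
that are pre-extended to host them; the backchanneler then takes the
floor, which the reference rule classifies as a restart, so each
backchannel costs one excluded utterance — the hosting probability is
solved from that accounting so within-overlaps are the requested fraction
of *retained* utterances. Word counts are `1 + ⌊lognormal(0.7, 1.2)⌋`
(≈ 28% one-word, matching the observed share), first words are drawn from
a vocabulary modelled on the observed one-word responses with labels
derived from the bundled lexicon, and durations are
`350 + 450·wc ± jitter` ms.

**Posture model.** Baseline area A0 = 320 mm² plus a speaker intercept
(sd 30). Ahead of a constrained utterance the deterministic signal ramps
linearly to `A1 = A0 − 100` mm² over the lead time
`lead(wc) = clip(3000·exp(−κ(wc−1)), 250, 3000)` with κ = ln(3)/2 (so
lead(3) = 1000 ms). The 250-ms floor encodes the irreducible
articulatory-to-acoustic lag reported for syllable onsets (≈ 220–300 ms);
without it the onset-slice contrast would vanish for long utterances one
frame before onset, which no articulatory account predicts. The depth of
100 mm² is of the same order as the onset-slice contrasts reported for
real dyads. First-word intercepts (sd 12) and a speaker-level
log10-word-count slope (sd 15) are added across each utterance's 3-s
pre-onset window so the crossed random structure the models estimate has
real variance; frame noise is AR(1) (ρ = 0.8, stationary sd 18 mm²) with
a per-speaker log-normal noise scale (sd 0.25) that gives the speed model
genuine speaker-level variance. Landmarks are synthesized as a diamond
(fixed 25-mm half-width) whose vertical half-extent solves the *primary*
area formula — area = 6·w·h — so the pipeline's metric inverts the
planted signal exactly; the remaining outer/inner lip points are filled
on an ellipse for format completeness.

**Feasibility.** A ramp needs `lead` ms of lip availability. When a drawn
onset would start the ramp inside the speaker's own previous utterance,
the scheduler defers the onset until the lips have had time (the default),
which right-shifts the realized FTO distribution of posture corpora — a
modelling statement, not a bug: speakers who posture early must wait for
the opportunity. With enforcement disabled the generator instead raises a
constraint violation listing the offending utterances. Backchannels
cannot defer inside their host turn; an infeasible constrained backchannel
is demoted to an unconstrained word instead.

**The calibration null.** Labial constraint is a deterministic function
of the first word, so *any* word-identity variation in lip area induces a
corpus-level constraint contrast. That is a real confound, not a false
positive — lme4/lmerTest shows the same rejections on such corpora — so
the null used for type-I calibration zeroes both the posture depth and
the first-word intercept sd (and, having no ramps, schedules without
deferral). Speaker intercepts, speaker slopes and heteroscedastic noise
remain.

**What the generator does not emulate.** Real articulation during speech
(the signal rests at baseline inside utterances), head-pose error,
camera calibration drift, partial or hold-then-release postures, accent
differences, and any lead longer than the 3-s epoch. Passing the recovery
tests therefore shows the *pipeline* recovers what it is pointed at under
realistic noise, clustering and scheduling — not that real speakers
behave like the generator.

## What the calibration suite demands, and why those slices

Under the default conditions the planted one-word contrast at the slice
frames is ≈ 0.6, 17, 34, 50 and 67 mm² at −3000 … −1000 ms. The epoch
cannot contain a ramp longer than itself, so at −3000 the truth is the
null by construction (the ramp for a one-word utterance starts exactly
there), and at −2500 the planted effect (≈ 17 mm²) sits at the frame
noise sd — no calibrated test should be expected to flag it 90% of the
time. The replicate-level acceptance check therefore demands the full
signature (positive constraint effect and negative moderation) at the
slices where the planted one-word contrast exceeds 30% of the posture
depth — −2000, −1500, −1000 — plus the main effect at the onset slice,
in ≥ 90% of replicates, and separately verifies that −3000 behaves as the
planted null. Type-I calibration runs 200 no-posture corpora and requires
each slice × term rejection rate to sit inside its exact binomial band,
Bonferroni-adjusted across the 14 simultaneous cells.

## Numerical and degenerate-input choices

- Millisecond integers are the single time base; OpenFace second-valued
  timestamps are converted on read (detected from the median frame step).
- REML optimization: two starts (relative sd 1.0 and 0.3), `ftol 1e-12`,
  `gtol 1e-7`, 500 iterations; finite-difference steps for the variance
  Hessian scale with `|φ| + 0.01·σ̂²`.
- Zero residual variance (exactly collinear responses) is guarded by a
  floor inside the criterion; the OLS path handles the no-random-terms
  limit exactly rather than through the optimizer.
- Factors observed with a single level are dropped from the random
  structure before fitting (their variance is inestimable), and the
  reported structure string reflects what was actually fitted.
- Words absent from the lexicon raise immediately (single lookup) or are
  aggregated into one report (corpus coding); a manual override table
  takes precedence over the lexicon. Lexicon entries without a vowel
  phoneme (vocalized nasals such as "mmhmm") are legal and judged on the
  onset consonant alone.

## Known limitations

- The primary area metric inflates true polygon area; only within-speaker
  contrasts are interpretable, never absolute apertures.
- Satterthwaite df from numerically differenced Hessians can be unstable
  when variance components sit at the boundary; the implementation then
  falls back to residual df with a warning, which is anti-conservative in
  principle but only arises where the random structure has already
  collapsed.
- The slice at 0 ms is measured one frame (~33 ms) early; contrasts that
  genuinely collapse at onset retain a small residue there.
- The generator's lead function (exponential decay in word count with a
  fixed floor) is a modelling convenience; recovery results are
  conditional on it.
- No multiplicity correction inside the per-slice reports (see above).
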