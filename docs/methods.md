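# Methods

This note documents the models implemented in `qvcv`, the choices made
where the design was genuinely open, what the synthetic-listener generator
does and does not emulate, and the numerical details a maintainer needs.

## The task and its data

The test is closed-set consonant identification: a vowel–consonant–vowel
token mixed with speech-shaped noise at a fixed per-token SNR, answered on
a 14-button panel (13 consonants + an "other/???" button, which is always
scored incorrect).  A session yields a consonant confusion matrix (CCM):
presented consonant × response counts.  Percent correct is the diagonal
sum over trials.  Listeners are banded by the 3-frequency pure-tone
average (PTA; 1, 2, 4 kHz): normal hearing (NH) ≤ 15 dB HL, slight 16–25,
mild 26–40, moderate 41–55; PTA > 55 dB HL is outside the test's supported
range (at a fixed 65 dB SPL presentation level, audibility floor effects
would dominate).  Non-integer PTAs are rounded half-up before banding.
The two recordings of each token are pooled everywhere.

## Psychometric fitting and SNR90

Per-token performance-vs-SNR data (a few fixed SNRs, binomial counts) are
fitted with a logistic psychometric function

    P(s) = γ + (1 − γ − λℓ) · σ(β (s − m)),

γ = 1/14 (the closed set's guess floor), lapse λℓ = 0.02 fixed.  Fitting
is penalized maximum likelihood — a weak Gaussian prior on log β (sd 3,
centred on 1 /dB) stabilizes 2–3-point fits without materially moving
well-determined ones — by a deterministic coarse grid search plus
Nelder–Mead refinement.  SNR90 solves P(s) = 0.90 analytically.  Because
two or three points cannot support long extrapolations, SNR90 is reported
only within 6 dB of the tested SNR range: curves above target at the
lowest tested SNR are flagged SATURATED, curves still below target more
than 6 dB past the highest tested SNR are flagged UNREACHED, and
zero-information data (all correct / all wrong) are DEGENERATE.  The
narrowed follow-up grid is {SNR90−3, SNR90, SNR90+3}, integer dB.

## Token selection

Discriminability of a token for hearing loss is the Mann–Whitney AUC
between per-listener proportion-correct scores of NH (PTA ≤ 15) and
hearing-loss listeners, ties counted ½ — the probability that a random
impaired listener scores below a random normal-hearing one.  Consonants
whose median token AUC falls below 0.9 are dropped; the vowel context with
the highest median AUC (ties: lower interquartile range, then alphabetical)
is kept, with AUC distributions obtained by bootstrap resampling of
listeners; each retained token then gets its argmax-AUC SNR (ties toward
the lower SNR, matching the panel's predominance of 0 dB).  The per-token
score feeding the AUC is the per-listener proportion correct — the only
listener-level quantity available at token granularity.  The packaged
default panel is the final ten-consonant /ɑ/ set with its published SNRs
and AUCs.

## PTA prediction

Features are the row-normalized CCM response proportions, flattened in
panel order: 10 presented consonants × 11 response choices (the 10 panel
consonants + OTHER; off-panel button presses fold into OTHER so the
feature length is fixed) = 110 numbers per listener.  The pipeline
standardizes features, fits PCA on the training split only, keeps the
smallest component count explaining ≥ 95 % of training variance,
standardizes the component scores, and solves ridge regression of measured
PTA on them.  The penalty convention matters for λ's meaning: we minimize
½‖y − Xβ‖² + λ‖β‖² with λ = 3 on standardized scores, intercept
unpenalized.  Cross-validation repeats random 70/30 listener splits (100
by default, seeded); a listener's predicted PTA (PPTA) is the mean of
predictions from splits that held them out, clipped to [−10, 80] dB HL.  A
single 70/30 split would leave listeners without held-out predictions,
which is why repeated splitting is the default.  The returned model object
is refitted on all listeners for deterministic prediction on new data and
serializes to JSON with bit-identical predictions after a round trip.

The continuous predictor is ridge *linear* regression — predicted PTA has
dB units, which a logistic output cannot deliver; regularized *logistic*
regression is used for the binary heads (NH/HL, excess loss) on the same
component scores with the matching penalty (C = 1/2λ).  For rare-event
heads the cross-validated classifier caps its covariate count by the
events-per-variable ≥ 10 rule (at least one component, leading components
kept): with ~5 events and ~36 covariates an uncapped logistic head learns
spurious directions and its cross-validated AUC collapses; unsupervised
(variance-ordered) selection is used because supervised screening on a
handful of events is itself unstable.

## Audibility baseline and residual loss

Below some threshold the confusion matrix carries no information about
PTA — normal-hearing listeners all perform near the 90 % target — so
predictions flatten at a floor.  The audibility function a(p) =
max(floor, p) captures this: floor is the single free parameter (the
breakpoint equals the floor) fitted by least squares on (measured,
predicted) pairs.  The fit is exact and deterministic: candidate floors
are the stationary points (means of predicted PTA over every
sorted-by-measured-PTA prefix) plus the kinks (the measured values), and
the candidate minimizing the true sum of squares wins.  A cohort with no
listener below the fitted floor cannot identify it; the result is flagged.

Residual hearing loss is RHL = PPTA − a(measured PTA), and "excess loss"
means RHL strictly greater than 5 dB — a threshold chosen (in the source
methodology) to exceed the test's ~5 dB test–retest repeatability limit.
Negative RHL (performing better than the audiogram predicts) is expected
and mostly falls within the repeatability band.

## Repeatability and hearing-aid benefit

Session-pair repeatability is the Pearson correlation and the mean
absolute difference (MAD) of per-listener scores; zero-variance inputs
flag the correlation as undefined.  MAD as a function of trial count t
subsamples t trials per session per listener without replacement,
stratified over the 20 (consonant × recording) tokens so per-token counts
differ by at most one — subsampling rather than truncation removes order
effects; truncation remains available.  Confidence bands are 2.5/97.5
percentiles over resamples (200 by default, seeded).  Reference constants
(5 dB repeatability for this test, 2.5 dB for the comparison sentence
test, 25 trials/minute) are packaged for reporting.

Hearing-aid benefit per listener is Δ% = aided − unaided percent correct
and ΔdB = unaided PPTA − aided PPTA (positive = benefit); ΔdB is
significant only when strictly above the 5 dB repeatability limit.  No
percent-scale significance limit is defined, so percent deltas carry no
flag.  The cohort report also notes whether aided scores reach the >90 %
normal-hearing ceiling.

## The synthetic-listener generator

The generator exists to give every analysis input data with the
statistical structure the method assumes, under seeded, bit-reproducible
control.  Each token has a logistic psychometric function in SNR; a
listener's *effective loss* L = true PTA + excess offset − aided relief
(floored at −10 dB HL) shifts the midpoint once L exceeds a 15 dB HL knee:

    P(correct) = γ + (1 − γ − λℓ) · σ(β (s − m − D(L)))

- **Calibration to the panel.**  Midpoints m are set so P = 0.90 exactly
  at each token's panel SNR for listeners at or below the knee (the SNR90
  normalization target); this pins the NH operating point.  Slopes β are
  drawn per consonant from U[0.25, 0.45] /dB (≈6–10 percentage points per
  dB near the midpoint, typical of consonant-in-noise identification).
- **Compressive deficit map.**  D(L) is piecewise linear in x = max(0,
  L−15): a steep near-knee rate for the first 10 dB HL and a shallower
  deep rate U[0.20, 0.30] dB SNR per dB HL beyond (clinical SNR-loss
  growth rates).  The compressive shape reflects that suprathreshold
  speech-in-noise deficits grow fastest at the onset of loss and saturate;
  it is also what keeps deep losses off the guess floor, and hence still
  informative, as observed cohorts are.  Where a token carries a published
  discriminability AUC, the near rate is solved numerically so the token's
  expected NH-vs-HL AUC on the reference composition (equal thirds
  slight/mild/moderate, 60 trials per token) reproduces that AUC; a purely
  guessed deficit map either under-separates slight losses or floors the
  moderate ones.
- **Structured, loss-dependent confusions.**  Wrong responses are drawn
  from a softmax kernel over phonetic feature distance (voicing, manner,
  place; temperature 1), so /s/ is misheard as /ʃ/ far more than as /m/.
  As effective loss rises, the kernel interpolates (over 30 dB HL above
  the knee) toward a place-blind kernel with a closer OTHER button —
  place-of-articulation cues ride on high-frequency detail and fade
  first.  This matters beyond realism: the method's premise is that the
  confusion *pattern*, not just the score, carries hearing-status
  information, and a static kernel would contradict it.
- **Excess loss** is an offset added to effective loss but invisible to
  the "audiogram" (true PTA) — perception worse than thresholds predict.
  Excess listeners are drawn from the slight/mild/moderate categories by
  default: below the knee an audiogram-invisible offset does not manifest
  in the response model, so it would not constitute a recoverable ground
  truth.
- **Screening mode** provides all 13 consonants in /ɑ/ and /i/ contexts
  with intrinsic consonant parameters shared across vowels, designated
  uninformative consonants (loss rates zeroed, kernel static), and
  documented per-vowel noise: listener-by-token midpoint jitter
  (sd 1.0/2.5/4.0 dB for ɑ/i/u) plus a listener-by-vowel offset
  (sd 0.5/2.0/4.0 dB) — the offset, shared by all of a vowel's tokens, is
  what dilutes a vowel's group-separation AUC and makes /ɑ/ the cleaner
  context.  The single-vowel test cohorts use the bare response model:
  individual differences enter only through PTA, excess offset and lapse.

What the generator does **not** emulate: audiogram shape (loss is a single
scalar; real configurations differ at 1 vs 4 kHz and leave signatures in
specific consonants), age/cognitive covariates, learning or fatigue across
sessions, per-listener slope differences, and acoustic specifics of the
65 dB SPL presentation (absorbed into the deficit map).  Passing tests
therefore show that the analysis chain is correct and well-calibrated
under these structural assumptions — not that the accuracy figures will
transfer to any particular clinical population.

## Validation studies and their sizes

The reference studies (`qvcv.validation`, run by `scripts/acceptance.py`
and the acceptance tests) use 60-listener cohorts (15 per category), 200
trials per listener (two 100-trial sessions, pooled for model fitting),
λ = 3, 100 repeated 70/30 splits, and ten cohort replicates per quantity —
sizes chosen to match the standard cohort design while keeping a full run
in tens of seconds.  Typical results: cross-validated PPTA MAE ≈ 4.5 dB;
normal-hearing normalization ≈ 90.0 %; excess-loss detection AUC ≈ 0.78
(theoretical ranking ceiling ≈ 0.80 for a 10 dB offset at this prevalence
and noise level).

Residual-loss recovery against the injected offsets averages ≈ 3.6–3.8 dB,
the hardest of the four quantities, and its error is mostly structural
rather than noise: ridge shrinkage at λ = 3 biases the top edge of the PTA
range by ≈ −3 dB even on noiseless features; the knee/floor geometry makes
slight-loss residuals negative and over-credits excess listeners just
above the knee; and excess moderates (effective loss above 55 dB HL) lie
beyond the training manifold and under-recover.  These components do not
average away over replicates, and no variant of the pinned estimator we
examined (penalty scale, PCA retention, score scaling) moves the total by
more than ~0.1 dB.  The noise-only analogue — mean |RHL| among ordinary
listeners — is ≈ 3.4 dB.

## Numerical details and edge cases

- All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds give bit-identical cohorts, fits and resampling curves.
- Ridge/PCA/logistic use scikit-learn; the test suite checks the composed
  pipeline against an independent normal-equations oracle at 1e−8.
- Zero-variance feature columns get unit scale instead of dividing by
  zero; single-category cohorts still fit the regression but skip the
  classifier head with a recorded note.
- Session files are comma-separated UTF-8 with ASCII aliases ("sh" for ʃ,
  "a" for ɑ) for portability; parsing reports malformed lines by number.
  Output files carry a provenance header (version, config hash, seed) so
  re-runs are byte-identical.
- Tie-breaks are fixed everywhere (lower SNR for equal AUC, lower IQR then
  alphabetical for vowels, stable sorts in splits) so the selection
  pipeline is deterministic given its inputs.
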