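# Methods

## The evaluation model

A recording session is a timeline of explosive sounds. Three annotators
independently place labels (point or interval) on that timeline, each
carrying a tier in {0, 1, 2, 3}; a detector on each device logs events
with a prediction score in [0, 1] on its own clock. The pipeline converts
these streams into per-second analysis units and computes diagnostic
accuracy and rate agreement.

**Analysis universe.** Only seconds containing at least one annotation
enter the analysis. Detector events in unlabeled silence are counted and
reported separately ("out-of-universe detections") but are excluded from
the contingency table: with no annotation there is no ground truth for
that second, and including long silent stretches as presumed negatives
would inflate specificity denominators arbitrarily.

**Label-to-second assignment.** Seconds are half-open bins [t, t+1),
0-based on the annotation timeline. Point labels of tier ≥ 1 from one
annotator that lie within 1 s of each other (the *merge gap*) are
greedily chained into a single sound, assigned to the second containing
the first label of the chain; tier-0 point labels mark their own second;
interval labels contribute to every second they overlap. Where several
contributions hit the same second, the maximum tier wins.

**Detection pooling.** Detections are pooled within one-second bins: the
bin's score is the maximum member score and the second counts as detected
when that score reaches the operating threshold (inclusive: score ≥ 0.85).
Bin pooling rather than gap-chaining matters here: chaining would let a
low-score stray event just before a true cough pull the cough's detection
into the preceding second and manufacture a false negative.

**Consensus rule.** Per second, each annotator's effective tier is the
maximum tier they placed there (no label in a cough-like second counts as
tier 0, i.e. as disagreement). Then:

- all three tier 3 → `TRUE_COUGH` (unanimous gold cough-second);
- every label present is tier 0 → `NON_COUGH`;
- all three effective tiers equal but not 3 (e.g. 2,2,2) →
  `COUGH_LIKE_NONCONSENSUS`;
- anything else → `DISPUTED`.

Only `TRUE_COUGH` and `NON_COUGH` seconds enter the contingency table;
the two disagreement classes are excluded from accuracy counting but
reported per session.

**Session quality.** A session is evaluated only if (a) every device's
clock could be synchronized and (b) it holds at least 10 unanimous
cough-seconds (boundary inclusive). Exclusions are reported as a
flowchart with one count per reason.

## Clock synchronization

Convention: detector time + offset = annotation time. For a candidate
offset, cough-like reference times (all three annotators' tier ≥ 1 labels,
chained with the merge gap so one sound contributes one time) are matched
one-to-one to shifted detection times by a greedy two-pointer pass in time
order, with tolerance 2 s; for sorted streams with interval-type
compatibility this greedy matching attains the maximum matching size (the
test suite checks it against an exhaustive oracle). The match-error is

    error = (n_unmatched + mean|residual| / tolerance) / max(#labels, #detections)

The residual term is strictly smaller than one unmatched event, so it
only orders candidates *within* the plateau of equal match counts that
the 2-s tolerance creates around the optimum; without it a grid search
cannot localize the offset better than the tolerance. The grid (default
±60 s, step 0.1 s) argmin — ties broken toward smaller |offset|, then the
negative side — is then refined below the grid step by shifting it by the
mean signed residual of its matched pairs (clamped to the grid range).
With exact timestamps this recovers the offset essentially exactly; the
acceptance suite requires recovery within one grid step over 20 seeded
cohorts with offsets injected across ±30 s.

Only detections scoring at or above the operating threshold take part in
synchronization when a threshold is given (the pipeline passes its 0.85):
sub-threshold events are not classified coughs and would otherwise
dominate the denominator. A device whose best error exceeds 0.5 — fewer
than half of events matchable — is flagged unsynchronizable and its
session excluded. Manual overrides are supported and recorded with
`method=manual_override`.

## Accuracy and agreement statistics

- Sensitivity = TP/(TP+FN) over `TRUE_COUGH` seconds; specificity =
  1 − FP/(FP+TN) over `NON_COUGH` seconds; undefined ratios raise rather
  than return a silent value, and per-session tables log-and-skip them.
- Confidence intervals are exact Clopper–Pearson (inversion of binomial
  tail probabilities), computed via `statsmodels`' beta-quantile form and
  cross-checked exhaustively (all n ≤ 50) against an independent
  bisection of the binomial CDF. The exact method was chosen because the
  common approximate intervals disagree with it visibly at these counts
  and the exact interval is the conservative default for diagnostic
  accuracy reporting.
- Per-session five-number summaries use linear interpolation between
  order statistics (the numpy default quantile rule).
- Rate agreement cuts each session into 60-s segments (a final partial
  segment is kept iff at least half a segment long). Gold counts are
  unanimous cough-seconds; device counts are detected seconds, including
  out-of-universe ones — a deployed monitor cannot know which seconds an
  annotator would have labeled. Pearson r and the OLS fit use all
  segments; Bland–Altman percentage error, 100·(device − gold)/gold with
  mean ± 1.96 SD limits, necessarily drops zero-gold segments (the count
  used is reported). The percentage-error denominator is the gold count,
  matching the framing of detector error relative to the human reference.

## Study-design utilities

Session scripts hold 18 isolated coughs, 10 sneezes, 5 throat clears and
13 short words (46 isolated sounds, 39% coughs) plus one read text
passage with 2 embedded coughs — 20 solicited coughs per session — each
isolated sound separated by ≥ 5 s of silence. Five canonical shuffles are
generated deterministically (the version number seeds the permutation),
so the "shipped" versions are byte-stable without committed files. The
word-sound count is 13 so that the isolated-sound total (46) and the
cough fraction (39%) are mutually consistent; the composition is fully
configurable.

Sample size follows the Buderer approach: per branch
n = z²·p(1−p)/d², divided by the branch prevalence (cough prevalence for
sensitivity, its complement for specificity) and by (1 − dropout), taking
the ceiling of the larger branch. With prevalence 1 the specificity
branch has no denominator and is skipped; prevalence 0 or dropout 1
raise. The defaults (Se 0.90, Sp 0.85, d 0.05, prevalence 0.40, dropout
0.10, z 1.96) give 385 sounds.

## The simulator

`synthetic_data` emulates the acquisition setting end-to-end: scripted
events scheduled evenly across the session with Uniform(0, 1) s jitter
(humans do not cough on the exact prompt second) and ≥ 5 s gaps; three
annotators who draw a tier for every event from a per-kind confusion row;
and per device an unknown clock offset drawn uniformly from ±30 s, plus a
detector that:

- detects each cough with probability `p_detect_cough` (default 0.92),
  drawing its score from Beta(8, 1) conditioned at or above the 0.85
  threshold — `p_detect_cough` is the *operating* sensitivity at the
  threshold, which is what an end-to-end evaluation measures;
- logs missed coughs with probability 0.5 at a sub-threshold conditional
  score (the device heard something but did not call it a cough);
- triggers on non-cough sounds with probability 0.3, score Beta(1, 6);
- emits a Poisson spurious stream in silence (0.5 events/min, score
  Beta(1, 6)).

The Beta defaults put substantial cough-score mass on both sides of the
threshold (27% of the unconditional cough distribution lies below 0.85)
so threshold handling is genuinely exercised, while non-cough scores
essentially never cross it. Annotator confusion defaults give each
annotator P(tier 3 | cough) = 0.97, hence tier-3 unanimity on ≈ 91% of
coughs across three independent annotators, with small tier-1/2 mass on
sneezes and throat clears; `degrade_annotators` rescales the cough row so
a stated fraction of coughs fails unanimity, for studying the quality
rule. All randomness flows from a single seeded generator: one seed, one
byte-identical cohort on disk.

**What the simulator does not emulate.** Label and detection timestamps
are exact — real annotators mark onsets with ~0.1 s error and detector
timestamps drift within a second of the acoustic onset. Because analysis
units are floor-binned seconds, such sub-second marking noise makes real
evaluations lose detections across bin boundaries; passing tests here
therefore demonstrate the correctness of the pipeline arithmetic, not
that a per-second framework is lossless on real recordings (it is not —
observed sensitivity on real data bundles boundary losses with true
misses). There is also no acoustic content: no background noise,
waveforms, or sound levels, and no modeling of participants who cough off
script.

## Numerical and degenerate-input choices

- Threshold comparison is inclusive (≥ 0.85), "minimal score threshold"
  semantics; boundary-tested.
- The QC bound (10 coughs) is inclusive; 9 excludes, 10 includes.
- Offset grid ties break toward the smallest |offset|, then negative;
  a single matchable pair therefore yields offset 0, not an arbitrary
  plateau edge.
- Empty label files are valid (empty tracks); malformed lines, tiers
  outside 0–3 and scores outside [0, 1] raise with the file line number —
  bad annotations are never silently dropped.
- `offset_error` with nothing on either side, correlation on fewer than
  3 segments or zero-variance gold counts, Bland–Altman with no positive
  gold segments, and sensitivity/specificity with empty denominators all
  raise informative errors.
- Percentages in reports are rounded to one decimal; all internal values
  are full precision.

## Problem sizes used in tests and drivers

The analysis drivers simulate the full 49-session cohort; the
acceptance-style property tests use 37-session cohorts (20 seeds) for
parameter recovery and single sessions (20 seeds) for offset recovery,
sizes at which Monte-Carlo error is small relative to the asserted
tolerances while the whole suite stays fast.

## Known limitations

- The unanimity rule makes the gold standard conservative: coughs that
  fail unanimity vanish from the sensitivity denominator rather than
  counting against the detector, and the same sounds can still be counted
  by the detector in the rate analysis (which is one reason fitted slopes
  need not equal sensitivities).
- The consensus treatment of a second where one annotator placed no label
  while others marked tier 3 is a modeling choice (treated as
  disagreement, hence excluded); other conventions are defensible.
- Pooled rate agreement concatenates device-session segments, so devices
  with more segments weigh more; per-device results are always reported
  alongside.
- The match-error functional form for synchronization is a design choice
  validated by parameter-recovery tests, not a published standard.
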