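# Methods

This note documents the models, rules and numerical choices behind
`vigistate`, in the order of the analysis chain, and states what the
synthetic data do and do not establish.

## Stage model and scoring rules

Seven vigilance stages span activated wakefulness (0) to sleep onset (C),
with the fixed numeric mapping C=1, B2/3=2, B1=3, A3=4, A2=5, A1=6, 0=7.
All metrics use only non-artifact seconds.

**Amounts.** Percent of non-artifact seconds per reporting category
(A2 and A3 are classified separately — the MVV needs their distinct scores —
but merged into "A2/3" for amount tables). Windows without evaluable
seconds are reported as missing, never as zero.

**MVV.** Arithmetic mean of the numeric scores, per minute and for the
total recording; bounded in [1, 7] by construction.

**Minute criteria and the ASS.** Each complete minute is tested with
inclusive ("at least") boundaries on non-artifact denominators:
I — ≥ 2/3 of seconds in 0/A (variant: 0/A1); II — ≥ 1/3 in B1+B2/3;
III — ≥ 1/3 in B2/3; IV — ≥ 1 C second. The recording is divided into four
equal consecutive quartiles of minutes (5 minutes each at the standard
20-minute duration; any duration divisible by 4 minutes is accepted). With
qII/qIII/qIV the earliest quartile containing a minute that fulfils the
respective criterion, the score is `qIV`, else `4 + qIII`, else `8 + qII`,
else 14 when every evaluable minute fulfils the 0/A1 form of criterion I
and 13 otherwise. This 14-level table is a reconstruction anchored at the
four published values (14, 13, 4, 1) plus the depth ordering II < III < IV;
the interior bands follow from "earlier and deeper declines score lower".
It is deliberately criterion-based: a lone B2/3 second that never tips any
minute over a 1/3 boundary does not lower the score. If several criteria
first appear in the same quartile, the deepest wins. Minutes with fewer
than 20 evaluable seconds (configurable) are skipped; scoring requires at
least one evaluable minute per quartile and errors out otherwise, rather
than extrapolating.

## Preprocessing and calibration

Zero-phase (forward–backward) Butterworth filters: high-pass 0.5 Hz and
low-pass 70 Hz of order 4, plus a Q=30 notch at 50 Hz. The EOG channels are
low-pass/notch filtered but not high-passed by default: slow horizontal eye
movements live below 0.5 Hz and are *signal* for stage B1. Artifact
screening flags any 1-s epoch whose peak-to-peak amplitude on an EEG
channel exceeds 200 µV (configurable); this amplitude rule replaces visual
screening plus ICA correction, which are out of scope — it is deterministic
and sufficient for synthetic data, but it will not catch low-amplitude
physiological artifacts in real recordings. Flags are sticky and propagate
through every metric. No channel interpolation to a denser montage is
performed: region powers are means over available 10–20 channels, and an
ROI mean gains nothing from interpolated channels.

Calibration uses an eyes-closed segment (≥ 10 s): the reference is the
median posterior-ROI alpha power over its 1-s epochs. Defaults:
`alpha_threshold = 0.25 ×` reference, `slowwave_threshold = 1.0 ×`
reference, low-voltage flag below 10 µV²; the fractions are configuration
parameters because no published threshold table exists for them. Low-voltage
subjects are rejected from staging — alpha-based criteria are meaningless
for them. Because both thresholds are quadratic in signal amplitude, staging
is invariant under a common gain change when calibration is recomputed from
the equally scaled segment (the absolute SEM amplitude criterion and the
artifact limit bound how far this extends).

## Stage classifier

Per 1-s epoch, band powers come from a plain periodogram (1 Hz resolution;
adequate for 4–6 Hz wide bands) averaged over scalp ROIs: anterior
(Fp1/Fp2/F7/F3/Fz/F4/F8), posterior (T5/P3/Pz/P4/T6/O1/O2), global (all 19).
Scalp-ROI powers stand in for source-space powers used by the published
implementation; this is a declared deviation — no bit-for-bit replication
is attempted. Decision ladder:

1. spindle/K-complex marker in the epoch → C. Markers are consumed from a
   file, mirroring manual expert marking; `detect_events_auto` provides a
   clearly non-canonical amplitude–duration detector for synthetic runs.
2. slow-wave power (2–7 Hz, global) ≥ threshold while alpha stays below its
   threshold → B2/3. The 2–7 Hz band covers theta plus upper delta while
   staying clear of the 0.5 Hz high-pass roll-off. Giving slow-wave
   dominance precedence over a simultaneous alpha peak (and alpha
   precedence when both thresholds are exceeded, via the alpha-below
   condition) is this implementation's resolution of an unspecified corner
   case, flagged for sensitivity analysis.
3. alpha (max of anterior/posterior ROI power) ≥ threshold → A branch; the
   anterior/posterior power ratio r selects A1 (r < 0.5), A2 (0.5 ≤ r < 1),
   A3 (r ≥ 1). The ratio absorbs the amplitude decrease that accompanies
   frontalization, since anterior alpha is absolutely weaker; the cut
   points are config defaults, not published constants.
4. slow-eye-movement flag → B1. The SEM detector low-passes both EOG traces
   at 0.7 Hz and flags epochs whose padded window (±0.5 s) shows ≥ 25 µV
   peak-to-peak deflections on both traces with left/right correlation
   ≤ −0.5 (true horizontal eye movements are anti-phase at the outer
   canthi; in-phase drifts are rejected).
5. otherwise → 0.

Individual-alpha-frequency (IAF ± 2 Hz) banding is available but off by
default; the fixed 8–12 Hz band is the primary mode.

## Synthetic data

**Stage courses** are minute-level Markov chains on the stage ladder
(per-minute descend/ascend probabilities, floor/ceiling bounds, blocked
moves stay), expanded to seconds with ±8 s boundary jitter; C events are
planted inside B2/3 minutes with a per-minute entry probability. The four
regulation types differ only in parameters (descend/ascend, floor,
ceiling, start):

| type | descend | ascend | states | intent |
|------|---------|--------|--------|--------|
| adaptive | 0.26 | 0.02 | 0…B2/3 (+C) | graded decline across 20 min |
| unstable | 0.88 | 0.01 | 0…B2/3 (+C) | collapse within the first quartile |
| stable | 0.35 | 0.35 | A3…A1, start A2 | constant mid-alpha, no B/C |
| hyperstable | 0.30 | 0.08 | A1/0 | retention at the highest stages |

No quantitative trajectory statistics are published for these types, so the
defaults are calibrated internally against the verbal definitions and the
module's own contracts: hyperstable courses contain only 0/A1 (hence score
14); stable courses never reach B2/3 or C; unstable courses reach a B stage
within the first quartile with probability > 0.9 (exact chain enumeration);
the four types are re-identified from their MVV courses by the prototype
assigner in ≈ 85–90 % of runs at 20-minute duration.

**Signals** are sums of shaped noise: per-channel 1/f background (10 µV
rms), a coherent 8–12 Hz alpha carrier applied with stage-dependent region
gains (posterior rms 18/16/13 µV for A1/A2/A3 with anterior/posterior power
ratios 0.2/0.7/1.5), a global 2–7 Hz carrier in B2/3 (30 µV rms; 12 µV in
C), anti-phase 0.3 Hz / 100 µV EOG waves during B1 runs, and
Hanning-windowed spindle (13 Hz, 0.7 s, 30 µV) or biphasic K-complex (1 s,
75 µV) events centered in C seconds, each with an emitted marker. Using one
coherent alpha carrier per recording makes the frontalization ratio nearly
noise-free, which is what keeps A2/A3 recall high; amplitudes were chosen so
that default thresholds separate the stages with multiples-of-threshold
margins at 1-s periodogram resolution while staying under the 200 µV
artifact limit. The generator deliberately omits much of what makes real
EEG hard: ocular/muscle/cardiac artifacts (beyond SEMs), alpha blocking
dynamics, spectral nonstationarity within a stage, inter-subject spectral
variability, volume-conduction structure. Passing recovery tests therefore
demonstrates internal consistency of the chain, not field performance on
clinical recordings.

**Cohorts.** One root seed drives everything through
`numpy.random.SeedSequence.spawn` (per subject: type draw, course,
covariates), so cohorts are bit-reproducible. Covariates follow
`value = intercept + slope × ASS + N(0, sd)` with clipping; defaults couple
a high score to lower sleep efficiency, more wake after sleep onset, higher
arousal index and higher insomnia/stress-reactivity scores, with means and
spreads in the range typical of clinical insomnia samples. Default
mixtures (patients 40 % hyperstable / 40 % stable / 15 % adaptive / 5 %
unstable; controls 55 % adaptive / 30 % unstable / 10 % stable / 5 %
hyperstable) realize a stability-enriched patient group against declining
controls.

## Statistics

Mann–Whitney U uses midranks; p-values are exact (full enumeration, via
scipy) when the pooled sample has ≤ 16 observations and no ties, else a
tie-corrected normal approximation with continuity correction, with the
deviate reported. Spearman correlations use midranks with exact permutation
p-values for n ≤ 9 and the t-approximation otherwise. Chi-square is the
Pearson statistic without continuity correction (df = k−1 on a 2×k table),
warning below expected counts of 5; an optional one-sided mode halves the
upper-tail p for directed frequency-shift hypotheses. The median split
assigns values strictly above/below the sample median and alternates
median-tied values toward the smaller group, so even-sized groups with a
well-defined median split evenly (e.g. 34 → 17/17). No multiple-testing
correction is applied anywhere, matching the descriptive single-test
reporting the pipeline emulates. One-tailed tests are used only for the
directed hypotheses (higher patient stability; negative score–sleep-
efficiency and positive score–arousal-index correlations).

## Prototype model

Default curves: hyperstable constant 6; stable constant 5; adaptive linear
6 → 2 across the recording; unstable the same drop completed within the
first quarter, then flat at 2. Only the shape classes are fixed by the
model — the numeric curves are parameterized (`PrototypeParams`) so
alternative families (e.g. exponential declines) can be swapped in. The
three-type model replaces the stable/hyperstable pair with a single
constant-6 prototype. Assignment minimizes the sum of squared deviations
with pairwise deletion of missing minutes; exact ties (measure-zero) break
toward the more stable prototype.

## Problem sizes and determinism

The test suite exercises the chain at the sizes a reviewer can rerun
casually: 20 signal-level recordings of 175 s for classifier recall, 200
stage-level replicate cohorts of 34 + 25 subjects for the group-contrast
and type-recovery properties, 500 courses against the exact chain
enumeration, and full-permutation oracles up to n = 16 (rank tests). All
randomness flows from fixed seeds or derandomized hypothesis profiles; the
pipeline report is byte-identical per seed.

## Known limitations

- The 14-level score table and the prototype curve values are principled
  reconstructions, not published constants; both carry config hooks.
- Scalp-ROI powers, the amplitude-only artifact rule and the absence of
  ICA mean real-recording performance is untested here.
- The B2/3-vs-alpha precedence rule and the SEM detector construction are
  implementation decisions in territory the stage definitions leave open.
- Stage C is only as good as its markers: with no marker file and the
  automatic detector disabled, sleep onset is invisible to the classifier.
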