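# Methods

This note documents the models, algorithms, defaults and design choices
behind `speechscreen`, and what the synthetic-data experiments do and do
not demonstrate about real recordings.

## Signal model and acoustic extraction

Input audio is mono float in [−1, 1]; multi-channel input is averaged with
a warning.  A subject's utterance intervals (a TSV of start/end seconds)
are concatenated and the joined signal is peak-normalized to 1.0 before
analysis, so per-period amplitudes lie on the 0–1 scale the shimmer
definition assumes.

### Pitch

F0 is estimated frame-wise by autocorrelation: Hann windows three
floor-periods long (40 ms at the default 75 Hz floor), stepped by 10 ms.
Before analysis the signal is low-passed at 1.9 × the pitch ceiling —
periodicity detection rides on the low harmonics, and formant-band content
only decorrelates the autocorrelation when cycle lengths fluctuate.  The
frame autocorrelation is divided by the window's own autocorrelation to
remove the taper-induced decay across lags.  Candidate peaks in the lag
range [1/ceiling, 1/floor] compete with an octave cost of 0.1 per octave
toward lower frequencies, which breaks the near-ties between a period and
its multiples; the winner is refined by parabolic interpolation and
accepted as voiced when its normalized height exceeds the voicing
threshold (default 0.45).  Defaults: floor 75 Hz, ceiling 500 Hz — common
phonetics practice; all parameters are config-exposed.

On clean synthetic voices from 100–300 Hz the recovered mean F0 is within
2 Hz of the target (verified per run by the acceptance script).

### Middle-seven F0 summary

Per-utterance mean F0s are sorted ascending and the median plus the three
values immediately below and above are retained.  With fewer than seven
utterances the list is padded with repeats of the median, keeping the
feature dimensionality fixed; this case is otherwise unspecified, and
padding preserves the central tendency without inventing spread.  With an
even count the lower-middle order statistic serves as the median element.

### Glottal pulses, jitter and shimmer

Pulses are marked by a period-synchronous peak search: within each voiced
span the search seeds at the largest absolute peak, then steps forward and
backward by the local period (from the pitch track), refining each pulse
to the absolute-amplitude maximum within ±0.45 period.  Cycles whose peak
falls below 10% of the span maximum are coasted over (the walk keeps
stepping without recording a pulse), and pulses below 40% of the median
pulse amplitude are discarded, which rejects resonator ring-down picks at
voicing onsets and offsets.  Amplitudes are per-period peak absolute
sample values; because the joined signal is peak-normalized they lie in
[0, 1].

Jitter and shimmer are exact evaluations of the relative local formulas
(mean absolute successive difference over the mean) on the extracted
periods and amplitudes.  The pulse-marking step is an approximation: on
synthetic voices the measured jitter is strictly increasing in the
injected cycle-length perturbation (the property the cohort statistics
rely on) but overestimates its magnitude at high perturbation levels,
where cycle boundaries become genuinely ambiguous.  Value-level agreement
with any particular phonetic toolkit is not a goal.

### MFCC

Frames of 15 ms stepped by 5 ms, Hann-windowed, power spectrum, 26
triangular mel filters spanning 0 to Nyquist, log energies, orthonormal
DCT-II; coefficients 1–6 are kept — the 0th (energy) coefficient is
excluded, reading "MFCC1" as the first non-energy coefficient.  No
pre-emphasis.  Per-coefficient mean and population (ddof = 0) standard
deviation over frames are the features.  Only window and step were fixed
by the upstream protocol; filter count and coefficient conventions follow
standard practice and are config-exposed.

### Formants

The signal is resampled to 10 kHz and an order-10 autocorrelation-method
linear prediction runs in a 25 ms Gaussian window centred on each pulse.
Root angles of the prediction polynomial give candidate resonances;
candidates with bandwidth ≥ 400 Hz (bandwidth = −ln ρ · fs/π for root
radius ρ) or within 90 Hz of DC/Nyquist are discarded; the four lowest
surviving frequencies per pulse, and the per-formant median over pulses,
are reported.  A pulse resolving fewer than four resonances contributes
only to those it resolved.  No pre-emphasis is applied: the synthetic
source is spectrally flat, and the choice is config-visible.  Round-trip
recovery of generator resonances (500/1500/2500/3500 Hz) is within 10%.

## Linguistic extraction

Transcripts arrive pre-tokenized and POS-tagged (JSON-lines or two-column
text); the package's contract deliberately starts at tagged tokens, which
keeps the features language-agnostic and exactly testable.  The default
tag-class mapping covers Penn Chinese Treebank tags (noun NN/NR/NT, verb
VV/VC/VE, pronoun PN, adjective JJ/VA, numeral CD/OD); any tagset can be
mapped via configuration.

Type–token ratios are computed over width/case-normalized (NFKC,
lowercase) surface forms and over the pooled characters of all tokens.
Information words are nouns, verbs, adjectives and numerals.  The
information-unit scorer credits each lexicon concept at most once
(presence-based): entity concepts match literal surface patterns
(multi-word patterns match consecutive tokens), and action concepts match
an agent pattern followed by an action pattern within a 10-token window —
actions are phrases ("boy taking a cookie") and ordered co-occurrence
within a short window is the weakest matching rule that still demands both
constituents.  Occurrence-weighted counting is available behind a flag.
The shipped lexicon has 3 people, 2 places, 12 objects and 7 actions, with
English surface forms; Chinese patterns can be appended to any list.

The density-of-information-units summary and the information-word ratio
are treated as the same feature, preserving the fixed 10-feature count.

## Permutation tests

For each feature the statistic is |mean difference| between HC and the
impaired group (AD, or CI = AD ∪ MCI).  Two-sided is the default because
group differences in both directions are of interest; a one-sided mode
exists.  When the number of label arrangements C(n, n_a) ≤ 20,000 the null
distribution is enumerated exactly and p is the exact tie-inclusive tail
fraction; otherwise 10,000 seeded shuffles are drawn and
p = (1 + hits)/(n_perm + 1), the add-one correction that keeps sampled
p-values positive.  Ties are compared with a relative tolerance of 1e−9 so
floating-point noise cannot split exact ties.  No multiple-testing
correction is applied by default (per-feature reporting); Benjamini–
Hochberg is available behind a flag.

Calibration: with 1,000 null simulations at the reference group sizes
(22 vs 30) the rejection rate at α = 0.05 lies within the binomial band
[0.03, 0.07], and sampled p-values agree with exhaustive ones to within
0.02 for groups of ≤ 8.

## Normalization and classification

Features are z-scored within each gender stratum (population sd), removing
gender-driven offsets such as F0; a feature constant within a stratum is
passed through as zeros with a warning.  Normalization is computed on the
full table before LOO, matching the upstream protocol's ordering; this
leaks a small amount of held-out information into the scaling, which is
documented here, and a fold-wise variant can be built from the
`GenderStratifiedScaler` directly.

Five classifier families are evaluated: logistic regression (L2, C = 1),
Gaussian naive Bayes, random forest (N ∈ 3…15, seeded), RBF SVM
(γ = "scale", C ∈ 0.1, 0.4, …, 2.5) and kNN (uniform weights, k ∈ 1…8,
capped at the LOO training-fold size).  For each grid point a full LOO
pass predicts every subject from a model trained on the rest; the grid
point with the highest LOO accuracy is selected, ties going to the
smallest hyperparameter so selection is deterministic.  This non-nested
selection reports the selected point's own validation accuracy — the
conventional but optimistically biased reading; a nested, leakage-free
mode (`nested=True`) re-selects the grid point inside every training fold
and is the methodologically safer variant.  The positive class is the
impaired group, so sensitivity measures the ability to detect cognitive
decline.  Metrics are exact functions of the confusion counts; a metric
with a zero denominator is explicitly undefined (None), never silently 0.

## Synthetic data

`gen_voice` produces a glottal pulse train (period multiplied per cycle by
1 + jitter_level·g, amplitude by 1 + shimmer_level·h, g, h standard normal
clipped to ±3) filtered through a cascade of two-pole resonators at four
formant frequencies (bandwidths 80/120/160/200 Hz), peak-normalized to
0.9.  `gen_transcript` realizes exact tag-class counts via
largest-remainder rounding (remainder ties to the earlier class in a fixed
order) and embeds requested information units so the scorer is guaranteed
to credit them; filler tokens are two-syllable pseudo-words drawn from a
finite vocabulary, screened against the lexicon so no accidental credit
occurs.  `gen_feature_cohort` draws independent Gaussians per feature per
subject around per-group means.

The cohort defaults are the study conditions: 22 HC / 30 AD / 40 MCI
subjects, 52/92 female, and per-feature HC/AD/CI means taken from a
published 92-subject community screening cohort; MCI means are derived
from the AD and pooled-CI means via the group sizes.  Within-group sds are
not published; the default sd equals the HC–AD mean separation (Cohen's
d ≈ 1 for HC vs AD, floored at 5% of the HC mean magnitude), a realistic
effect size for features that separated the groups in that cohort.  The
self-contained pipeline demo additionally maps group membership to voice
profiles (higher F0 and perturbation with impairment) and transcript
profiles (POS mixtures at the group reference ratios, Poisson counts of
mentioned information units shrinking with impairment).

What the generator does not emulate: background noise, reverberation,
recording-channel effects, disfluencies, ASR errors, within-subject
correlation between features, non-Gaussian feature distributions, or
integer-valued unit counts (cohort draws are continuous).  Passing tests
therefore demonstrate correctness of the measurement and inference
machinery under the stated statistical model, not field performance on
community recordings.

## Numerical choices and degenerate inputs

Periods and amplitudes require N ≥ 2; jitter/shimmer on fewer raise an
undefined-feature error, as does an all-zero amplitude sequence or a
subject with no voiced frame.  Constant pooled data give p = 1.  The LPC
autocorrelation gets a 1e−9 ridge on the zero-lag term.  Formant medians
use nanmedian over pulses and are sorted ascending on return.  Missing
features are reported as errors, never silently imputed.

## Experiment problem sizes

The acceptance experiments use: 5 voices for pitch recovery, 3 for formant
recovery, 10 seeds × 3 levels for perturbation monotonicity, 1,000 null
simulations (n_perm = 999) for type-I calibration, 100 replicates for
planted-effect power, 20 replicates each for the chance-level and
planted-signal classification experiments, and 2-second voices at 16 kHz
throughout — sizes at which every check is stable across seeds while the
whole suite runs comfortably on one CPU.

## Known limitations

- Pulse marking is a peak-search approximation; measured jitter saturates
  the ordering, not the magnitude, of injected perturbation at high
  levels.
- The published headline accuracies of the cohort the generator is
  patterned on are not reproducible here: they depend on that cohort's
  raw recordings, which are not deposited.  The evaluation machinery
  reproduces the report formats and all metric identities instead.
- Non-nested grid selection is optimistically biased; use `nested=True`
  for unbiased estimates.
- The information-unit matcher is lexical; paraphrases outside the
  lexicon's surface patterns are not credited.
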