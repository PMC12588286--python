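# Methods

`tonosyl` re-creates, at desk scale, a real-time decoding stack that turns
multichannel cortical recordings of overt Mandarin speech into character
sequences. This note documents the model assumptions, the choices that were
genuinely open, and what the synthetic benchmark does and does not show.

## Signal model and feature extraction

The physiological signal of interest is high-gamma activity (HGA): the
analytic amplitude of the ~70–170 Hz band, a proxy for local population
firing in ventral sensorimotor cortex. Two extraction pipelines coexist:

- **Offline (analysis)**: bad-channel rejection → common average reference
  over good channels → polyphase downsampling to 400 Hz → zero-phase IIR
  notch at 50 Hz and all harmonics below Nyquist → Gaussian band-pass
  70–150 Hz → Hilbert analytic amplitude → per-channel z-score over time.
  The "Gaussian filter" is a single Gaussian magnitude window in the
  frequency domain, centered on the band with σ equal to a quarter of the
  bandwidth (edges at 2σ); multi-band averaging is deliberately not used.
  The step order (downsample before notch/band-pass) is fixed.
- **Streaming (decoding)**: per-sample common average reference → causal IIR
  notch bank → third-order Butterworth band-pass 70–170 Hz → causal analytic
  envelope → mean over a 50-ms window stepped every 10 ms (100-Hz frames) →
  z-score with *fixed* per-channel parameters estimated from earlier
  character-reading sessions (SD floored at 1e-8).

  A true Hilbert transform is non-causal. The streaming envelope uses a
  Hamming-windowed type-III FIR Hilbert transformer (63 ms of taps by
  default) for the quadrature component and a matching group-delay line for
  the in-phase component; the group delay ((N−1)/2 samples, ~31 ms at
  1 kHz) is reported in the pipeline's latency accounting. The FIR is
  evaluated as an explicit fixed-length windowed dot product rather than a
  library convolution so that chunked and one-shot processing agree
  *bitwise* — the chunk-partition invariance contract is exact, not
  approximate.

The two pipelines intentionally differ (band edges, phase behavior); tests
require only that they localize a synthetic burst at the same time within a
frame plus the causal group delay, not that they agree numerically.

### Signal-to-noise quality metric

Per channel and per 60-s window (30-s step): band-pass 1.5–250 Hz → Hilbert
envelope → 100-ms bin means → bins above the window's mean envelope are
"high activity". Signal = peak-to-peak envelope within contiguous high runs
of ≥400 ms; noise = envelope RMS over low periods;
SNR = 20·log10(mean run PP / mean low RMS). Both PP and RMS are taken on the
envelope (the printed procedure does not bind them to the raw trace); a
window without a qualifying run is reported missing, never zero. The metric
is invariant to a global rescaling of the signal.

## Synthetic sessions

The generator's defaults define the study conditions; they are not tuned per
test. Each base syllable is assigned a sparse nonnegative electrode weight
vector (30% of electrodes by default) and a Beta-shaped temporal kernel
(shape parameters drawn in [1.5, 4], duration 0.6 s). Each of the four
lexical tones modulates a partially overlapping electrode subset (20%) with
a pitch-like ramp: level, rising, dipping, falling. The per-channel signal
is `A(t) · carrier + noise + line`, where `A` is 1 plus the scaled templates
(syllable gain 3, tone gain 2), the carrier is 70–150 Hz Gaussian noise
normalized to unit mean envelope, white noise has SD 0.3, and an optional
50-Hz sinusoid (amplitude 0.5) emulates line contamination. Neural
activation *leads* the acoustic onset by 120 ms, reflecting articulatory
preparation; without this lead a neural onset detector is structurally late
relative to acoustic ground truth. Audio is an envelope-only proxy: a
flat-top noise burst (10-ms cosine ramps) per syllable — sufficient for
power-threshold onset detection, with no acoustic content.

What this emulates: spatially distributed, temporally structured,
label-dependent amplitude modulation recoverable through the actual
extraction math. What it does not: non-stationarity across days, electrode
drift, articulator-level structure shared between similar syllables,
co-articulation, or realistic tone acoustics. Passing tests therefore show
the *machinery* is correct and identifiable, not that real cortical data
would reach these accuracies.

Dictionaries map each tonal syllable to a configurable number of synthetic
homophone characters (unique CJK codepoints) with Dirichlet-drawn priors;
corpora are drawn from a seeded sparse-successor Markov process so a fitted
trigram model has structure to exploit.

## Speech-onset detection

Audio: causal 25-ms short-time power, moving-average smoothing, threshold at
1.6× the mean smoothed power, upward crossings, refractory suppression.

Neural: for each 100-Hz frame a 15-frame (±70 ms) contextual vector over all
channels, reduced to its top 50 principal components and scored by a
two-class linear discriminant whose posterior is the onset probability. The
trace is smoothed over 2 frames; an onset is declared when it exceeds 0.45
for 14 consecutive frames. The declared time is the *run start* (the rule's
other reading, run end, is a constant 140 ms later and would only shift the
latency bookkeeping). Fixed algorithmic latency = 70 ms future context +
140 ms decision rule = 210 ms, exposed as a computed property.

Training labels were a genuinely open choice. Frames in [−30, +300] ms
around a true onset are positive, with a 380-ms guard band excluded from
the negatives. The positive window must comfortably exceed the 140-ms
consecutive-window rule — a narrow symmetric margin (e.g. ±30 ms) produces
a probability trace that can never stay high for 14 frames, and no onset is
ever declared. The refractory period is 0.6 s, just beyond the 0.6-s
syllable response, so one syllable cannot re-trigger. Threshold/consecutive
defaults are kept at 0.45/14 and are exposed to the random-search tuner
(`tune_onset`), which maximizes F1 with a ±150-ms match window.

## Dual-stream decoders

Input: 1000-ms segments of 100-Hz features from −300 to +700 ms around
onset (100 frames × good channels). Architecture: two blocks, each a
two-layer bidirectional LSTM followed by layer normalization and dropout
(0.3), then a per-timestep linear head; per-timestep class distributions
are averaged over the segment, which keeps the output on the simplex.
Bidirectional outputs are direction-concatenated, so the reference
dimensions 250→500→200 correspond to 250 and 100 hidden units per
direction. The input dimension is always the count of good channels, never
hard-coded.

The network, its backward pass, Adam, the plateau learning-rate schedule
(halve on stale validation loss), mixup (per-batch λ ~ Beta(0.2, 0.2),
applied to both streams), cross-entropy and focal loss are implemented in
numpy with hand-derived gradients, verified against central finite
differences in the test suite. The tone stream trains with focal loss
(γ = 2) because tone proportions are imbalanced; γ = 0 reproduces
cross-entropy exactly. Training keeps the best-validation-accuracy
checkpoint with ties broken toward lower validation loss, so continued
training sharpens probabilities after accuracy saturates; an optional early
exit at 99.9% validation accuracy bounds cross-validation cost.
Fine-tuning (sentence task) is continued training from a warm start at a
tenth of the learning rate. All randomness (initialization, shuffling,
mixup, dropout) flows from one seed; training is reproducible to the bit on
one machine.

Evaluation follows the offline protocol: 10 disjoint test folds of 10%
each; the remaining 90% splits 70/30 into training (63% of the total) and
validation (27%); median fold accuracy with a 99% bootstrap CI (1000
resamples of fold accuracies). The folds are disjoint partitions — if the
original protocol drew independent 10% samples instead, fold accuracies
would be slightly correlated but the median estimate essentially unchanged.
Learning curves subsample repetitions per syllable (5/10/15/20, all
available if fewer) and inventory sizes (10 seeded random subsets per
size).

## Fusion and language model

Character score = Σ over tonal syllables mapping to the character of
p_syll(base) · p_tone(tone) · prior(char | tonal syllable), renormalized
over the covered mass; the top 10 candidates (log scores, lexicographic
ties) feed a beam search (width 10 by default) scored as
Σ neural log-likelihood + λ·Σ trigram log-probability with boundary-padded
histories, including the end-of-sentence term. λ is not identified by the
published description; the default is 1.0 and it is reported in every
output. The lattice has one position per detected onset (word-by-word
reading with deliberate pauses), so no insertion/deletion model is needed.

The trigram LM uses recursive add-k (Lidstone) interpolation
(k = 0.1): trigram → bigram → unigram. Every conditional distribution sums
to one exactly, which the tests assert; Kneser–Ney is unnecessary at the
toy-corpus scale of a predefined sentence set.

Metrics: CAR = position-wise correct characters / ground-truth length
(length mismatches count as errors), in percent; CPM = characters per
minute over the session duration.

## Electrode statistics

Trial windows default to (−500, +500) ms around onset with a (−700, −500)
baseline; balanced sampling draws up to 1000 segments (all, logged, when
fewer are available).

- *Speech-responsive*: per-trial mean baseline vs. instantaneous HGA,
  paired t-tests, Bonferroni over electrodes × time points, significant run
  ≥ 200 ms (80 points at 400 Hz; at other rates the millisecond criterion
  governs).
- *Syllable / manner discriminative*: pointwise one-way F, suprathreshold
  (F > 3.0) spatiotemporal clusters under grid adjacency (4-connectivity:
  distance ≤ 1.2 × the 3-mm pitch — a cutoff below √2 is required for
  4-connectivity), cluster mass = summed F against a 1000-permutation
  label-shuffle null of the maximum mass, cluster α = 0.05. Within
  surviving clusters, pairwise Welch t-tests (FDR by default; Bonferroni
  available) flag an electrode that separates ≥3 levels for ≥200 ms.
- *Tone*: balanced pointwise four-level ANOVA, Bonferroni, ≥200-ms run.
- *Place of articulation* (labial vs. lingual): pointwise two-sided Welch
  test at p < 0.05, ≥200-ms run. The groups are independent trial sets, so
  an unpaired test is the defensible reading.

The clustering and mass computation are cross-checked against MNE-Python's
spatio-temporal cluster test on a shared fixture.

*Gradient saliency*: cross-entropy loss of the trained decoder against the
true labels, backpropagated to the input; per electrode, absolute gradients
are summed over time per trial, averaged over trials, normalized so the top
electrode scores 1; the selection mask is the shortest descending prefix
reaching 90% of the total.

## Real-time pipeline and problem sizes

`run_realtime` replays raw data in 10-ms chunks through the streaming
extractor, detects onsets (audio power or the neural detector), assembles a
segment once +700 ms of post-onset features exist, runs both decoders,
maps to candidates, and beam-decodes each sentence with and without the LM
on identical onset sets. Reports carry per-sentence CAR both ways, session
CPM, onset F1 (±200-ms matching to ground truth), and a latency account
(streaming group delay + onset decision latency + 700-ms segment wait).

Problem sizes in the shipped tests are chosen for single-CPU runs: 16–64
electrodes, 4–20 base syllables, reduced recurrent widths (16/8 hidden
units per direction), and 200 permutations for the cluster null. The
identifiability demonstration (noise-free session, unique homophones,
sentence fine-tuning) reaches CAR 100% and onset F1 1.0; the
parameter-recovery benchmark (20 syllables × 4 tones × 30 trials, moderate
noise) is scored by 10-fold CV against 10× chance. These sizes are the
package's benchmark conditions, not statements about the full-scale system.

## Known limitations

- The streaming envelope approximation trades ~31 ms of group delay for
  causality; alternative approximations (e.g. complex demodulation) are not
  implemented.
- The LM weight λ, mixup α, dropout, and focal γ are defaults, not fitted;
  the published source for this design does not identify them.
- TextGrid support is read-only, single interval tier, with a fixed
  `syllable+tone+character` label convention.
- No artifact rejection beyond bad-channel flagging; no re-referencing
  other than common average; no EDF/BrainVision readers.
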