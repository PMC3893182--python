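# Methods note

This note records the model implemented by `iedreview`, the parameters and
their defaults, what the synthetic generator does and does not emulate, the
numerical choices that matter for reproducibility, and the known limitations.

## 1. Model and procedure

### 1.1 Signal path

All analysis runs on a canonical 19-electrode 10–20 layout
(Fp1 Fp2 F3 F4 C3 C4 P3 P4 O1 O2 F7 F8 T3 T4 T5 T6 Fz Cz Pz), in µV.
Recordings are read from EDF, resampled to 100 Hz, and band-pass filtered
0.5–30 Hz. Three montages can be derived from the common-reference signal:

- `common_reference` — identity;
- `bipolar` — the 18-pair longitudinal ("double banana") chain;
- `laplacian` — each electrode minus the mean of its 10–20 neighbours
  (neighbour table in `iedreview/data/montages.yaml`).

### 1.2 Templates and training

A template is one marked epoch: a single channel of a single montage,
duration 212–860 ms at 100 Hz, stored verbatim. Training replays each
template over every same-montage channel of the whole training set using the
normalized sliding correlation; windows with correlation > 0.85 (strict) are
its detections, labelled true iff they overlap a marked event on that
channel. From the labelled detections a template receives:

- **counts** T/F and reliability T/(T+F) (optionally Laplace-smoothed
  (T+1)/(T+F+2); off by default);
- **match-feature bounds**: the min/max of each feature over its true
  detections, widened by 10 % of the span;
- a **linear classifier** over the four match features, fit as a
  class-balanced linear SVM (C = 1.0) on standardized features with the
  scaler folded back into the stored weight vector and bias, so the persisted
  gate is a plain `w·f + b > 0`. Templates with only true (or only false)
  detections get a trivial accept (reject) gate.

The four match features between an epoch `e` and template `w`:

| feature | definition |
| --- | --- |
| correlation | Pearson r(e, w), clipped to [−1, 1] |
| matching_variance | var(e − g·w), g the least-squares gain e·w / w·w |
| amplitude_difference | abs(ptp(e) − ptp(w)) |
| background_ratio | RMS(e) / RMS(preceding 1 s); 1.0 with no preceding signal |

Pruning removes templates with T+F = 0, with T = 0, or with
0 < T < `min_true` (default 2) and F = 0. The database is one versioned HDF5
file.

### 1.3 Detection and grouping

Detection slides each template over every channel of its montage; local
maxima of the correlation trace above the threshold, at least one template
length apart, that pass the bounds and classifier become nominations.

Grouping condenses nominations in two deterministic steps:

1. **Same channel:** single-linkage merge of nominations whose interval
   overlap exceeds 0.75 of the shorter interval (strict; exactly 0.75 does
   not merge). Channel-groups with fewer than 3 members are discarded.
2. **Across channels:** channel-groups sorted by onset; the earliest unmerged
   one seeds a group and absorbs every channel-group whose onset starts
   strictly within 1.0 s of the seed's onset.

Group certainty aggregates member evidence `c_i · r_i` (correlation clamped
to [0, 1] times template reliability) with a noisy-OR,
`1 − Π(1 − c_i r_i)`; `mean` and `max` aggregators are selectable.

### 1.4 Review and feedback

Pending groups are presented in batches (default 10) in descending certainty,
ties broken by earlier onset then group id, so sessions replay exactly.
Outcomes are confirm / reject / unsure. Counting is **per detection**: a
confirm adds ΔT = 1 per member nomination (a template contributing twice
moves by two), a reject adds ΔF = 1 per member, unsure adds nothing — the
same bookkeeping used to accumulate T/F during training. After each batch the
session recomputes effective reliabilities from base counts + session deltas
and re-ranks every pending group. The persistent database changes only at
`finalize` (idempotent); an abandoned session leaves it untouched. Confirmed
groups are exported as event annotations.

`simulate_review` replaces the human: a presented group is confirmed iff its
interval temporally overlaps a ground-truth event (truth carries no channel
detail; an optional onset tolerance widens the match). It returns
per-iteration cumulative counts of distinct truth events confirmed, from
which recall curves are computed. A `random` presentation order (seeded) is
available as a baseline policy.

## 2. Parameters

| parameter | default | unit / range |
| --- | --- | --- |
| target sample rate | 100 | Hz |
| band-pass | 0.5 – 30 | Hz, 4th-order Butterworth, zero phase |
| detection threshold | 0.85 | Pearson correlation, strict > |
| template duration | 0.212 – 0.860 | s |
| same-channel overlap | 0.75 | fraction of shorter interval, strict > |
| minimum group members | 3 | nominations |
| cross-channel merge window | 1.0 | s, strict < |
| review batch size | 10 | groups |
| simulated review length | 15 | iterations |
| SVM | C = 1.0 | class-balanced, linear |
| prune `min_true` | 2 | true detections |
| certainty aggregator | noisy_or | noisy_or / mean / max |

## 3. Synthetic generator: scope

The generator exists so the pipeline can be exercised and scored end to end
without clinical data. It emulates, per 19-channel recording:

- 1/f background (flat below 1 Hz) at 15 µV RMS with slow (0.05 Hz) gain
  modulation and a posterior 8.5–11.5 Hz alpha rhythm strongest on
  O1/O2/P3/P4/T5/T6;
- four spike-wave families (sharp difference-of-Gaussians spike followed by a
  half-sine slow wave) with distinct focus channels, polarities, durations
  (0.30–0.60 s), and spread to neighbouring electrodes at reduced gain;
  events are injected additively at known, non-overlapping times with
  ±10 % amplitude and duration jitter (durations quantized to the sample
  grid) — these are the ground truth;
- distractor transients (default 2/min): spikes with a randomized slow-wave
  tail on a random channel, *not* part of the truth. They supply false
  candidates during training (negative examples for the classifiers) and a
  realistic false-positive burden during review.

It does **not** emulate eye blinks, muscle or electrode artifacts, sleep
architecture, inter-subject morphology variability, or realistic spatial
fields; focus channels are fixed per family. Training marks are generated
only on the common-reference montage; the bipolar and Laplacian pathways are
implemented and unit-tested but not exercised by the default dataset.

Dataset defaults: 3 training + 3 evaluation recordings, 5 min each, ≈ 1
injected IED/min. Training annotations carry the visible channels; evaluation
truth carries timing only. All generation is deterministic in a single root
seed.

## 4. Numerical choices

- **Sliding correlation** is computed with FFT convolution plus running
  window sums, clipped to [−1, 1]; windows with variance below 1e-12 score 0.
  It matches a per-window Pearson loop to 1e-9 (acceptance test 1).
- **Preprocessing order** is resample first, band-pass last. Polyphase
  resampling leaves ~−50 dB stopband leakage; filtering afterwards makes the
  output band-limited by construction, so a second pass through `preprocess`
  changes interior samples by < 1e-6 (measured ≈ 5e-9). The 0.5 Hz high-pass
  corner has |H|² = 0.5 at the band edge, so transients from the recording's
  ends persist for tens of seconds: the idempotence property holds on the
  interior excluding 30 s margins.
- **EDF I/O**: the package includes a minimal 16-bit EDF writer (1-second
  records) used for fixtures and synthetic data. It inverts the exact EDF
  digital↔physical mapping with header-string-rounded physical ranges, so a
  write/read round trip errs by at most half a digital quantization step.
- **Determinism**: every stochastic step (generation, random-order review)
  takes an explicit seed; child seeds are drawn below 2³¹ from a root
  generator. Training, detection, grouping, and certainty ranking are fully
  deterministic, including tie-breaks.

## 5. Design choices that lack a single canonical form

- **Reliability** is the plain ratio T/(T+F). A Laplace-smoothed variant is
  available for fresh templates but is off by default; pruning guarantees
  T+F ≥ 1 for every stored template.
- **Group certainty** is a noisy-OR of `c_i · r_i`: bounded in [0, 1], uses
  exactly the two per-member evidence terms, and rewards corroboration by
  several reliable templates. Mean and max are provided as alternatives since
  other bounded aggregations are equally defensible.
- **Per-detection counting** for review feedback mirrors the training-phase
  bookkeeping; an alternative (one count per template per group) would damp
  the feedback. "Unsure" contributes no deltas and is excluded from exports.

## 6. Desk-scale problem sizes and limitations

The default problem size (3 × 5-min training recordings, ≈ 50 templates,
3 × 5-min evaluation) is chosen to keep the full test suite and the summary
script inside desktop runtimes. Consequences and limitations:

- With few training events per family, a template can end up with tight
  bounds or be pruned, so occasionally an injected event is not covered by
  any group; recall of *detectable* events is therefore the primary curve,
  with the detectable fraction reported alongside.
- The synthetic families are far better separated from background than
  clinical IED morphology is from real EEG; at this scale the certainty
  ranking typically saturates within one or two iterations and the measured
  false-positive burden (distractor groups) is low. These numbers
  characterize the synthetic benchmark, not expected clinical performance.
- The advantage of certainty ranking over random presentation is bounded by
  the pool size per recording; with small pools both policies reach high
  recall quickly, and the comparison (mean iterations to 80 % recall) is
  reported rather than assumed.
- Human review time, GUI interaction, and real-time acquisition are out of
  scope; the interactive CLI mode is a minimal terminal prompt.
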