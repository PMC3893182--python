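# iedreview

Self-adapting detection of inter-ictal epileptiform discharges (IEDs) in
multichannel scalp EEG: template matching proposes candidate events, an
iterative certainty-ranked review presents them to a reviewer in batches, and
every confirm/reject decision feeds back into the template database so the
system keeps improving while it is being used.

## How it works

**Training.** A reviewer marks example IEDs on an annotated EEG. Each marked
epoch (212–860 ms, one channel of one montage) becomes a *template*. Every
template is replayed over the whole training set: each window whose Pearson
correlation with the template exceeds 0.85 is a detection, labelled true or
false by whether it overlaps a marked event. From these labelled detections
each template gets

- lifetime counts T (true) and F (false), giving a *reliability* T/(T+F);
- a linear classifier (maximum-margin SVM) over four match features —
  correlation, matching variance, amplitude difference, and the ratio of
  epoch RMS to the preceding second of background;
- acceptance bounds on those features from its true detections.

Templates that never detect, only detect falsely, or detect trivially few
events are pruned. The survivors are stored in a single versioned HDF5
database file.

**Detection.** Each template in the database scans every channel of its
montage with an FFT-based normalized sliding correlation. Windows above the
0.85 threshold that pass the template's feature bounds and classifier become
*nominations*.

**Grouping.** Nominations on the same channel merge when they overlap by more
than 75 % of the shorter interval; merged events with fewer than three member
nominations are discarded; surviving channel-events merge across channels
when their onsets fall within one second. Each group gets a certainty in
[0, 1] by a noisy-OR over its members' correlation × reliability products.

**Review.** Groups are presented in batches of ten, highest certainty first.
Confirming or rejecting a group adds one true or false count per member
detection; within the session the affected templates' effective reliabilities
are recomputed and all remaining groups re-ranked, so one rejected template
family immediately sinks every group that depends on it. At the end of the
session the count deltas are written back to the database; an abandoned
session never touches it. A simulated reviewer (confirm iff the group
overlaps a ground-truth event) provides headless evaluation and recall
curves.

**Synthetic data.** Since clinical EEG cannot ship with a code repository,
the package generates its own test signals: 19-channel 1/f background with
posterior alpha rhythm, four spike-wave families injected at known times
(the ground truth), and non-epileptiform distractor transients that exercise
the false-positive path. See `docs/methods.md` for what the generator does
and does not emulate.

## Worked example

Everything below is a real transcript (seed 7).

```bash
$ iedreview synth --out data --seed 7
INFO iedreview: wrote 3 training and 3 evaluation recordings to data

$ iedreview train --data data --db db.h5
INFO iedreview: trained 47 templates (49 extracted) -> db.h5

$ iedreview detect --db db.h5 --recording data/eval-7-0.edf --out nominations.csv
INFO iedreview: 322 nominations from 47 templates -> nominations.csv

$ iedreview review --db db.h5 --nominations nominations.csv --out review \
    --truth data/eval_truth.csv --recording-id eval-7-0
INFO iedreview: review complete: 4 confirmed, 1 iterations, db updated at db.h5
```

The 322 raw nominations condense into five groups; all four injected IEDs in
this five-minute recording are confirmed in the first batch and the one
distractor group is rejected:

```
$ head -4 review/groups.csv
group_id,start_s,duration_s,channels,n_members,certainty,status
g0000,6.010000,0.420000,F3,4,0.963220593,rejected
g0001,79.490000,0.470000,F7;T3;T5,90,1.000000000,confirmed
g0002,146.810000,0.470000,O1;O2;P3;P4,93,1.000000000,confirmed

$ head -3 review/recall_curve.csv
iteration,cumulative_confirmed,cumulative_presented
1,4,5
2,4,5
```

## Package layout

| Module | Role |
| --- | --- |
| `iedreview.eeg_io` | EDF read/write, resample + band-pass preprocessing, montage derivations, annotation CSVs |
| `iedreview.synthetic` | Seeded background, spike-wave families, distractors, dataset builder |
| `iedreview.matching` | FFT sliding Pearson correlation and peak picking |
| `iedreview.template_db` | Template extraction, match features, SVM training, pruning, HDF5 persistence |
| `iedreview.detection` | Scanning recordings with the database; nomination CSVs |
| `iedreview.grouping` | Same-channel and cross-channel merging; noisy-OR certainty |
| `iedreview.review` | Batched review sessions, feedback deltas, finalize, simulated reviewer |
| `iedreview.cli` | `iedreview synth / train / detect / review / report` |

`docs/methods.md` documents the model, all parameters, the scope of the
synthetic generator, numerical choices, and limitations.
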