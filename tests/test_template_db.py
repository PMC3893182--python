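"""Template extraction, match features (with independent oracles), training
counts vs a brute-force scan, pruning table, reliability, persistence."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iedreview.config import TARGET_RATE
from iedreview.eeg_io import CANONICAL_CHANNELS, EEGRecording, EventAnnotation, derive_montage
from iedreview.matching import candidate_peaks, sliding_correlation
from iedreview.template_db import (
    FEATURE_NAMES,
    PRECEDING_SAMPLES,
    MatchFeatures,
    Template,
    TemplateDatabase,
    apply_count_deltas,
    compute_match_features,
    extract_templates,
    load_db,
    prune,
    reliability,
    save_db,
    scan_template,
    train_templates,
)


class TestReliability:
    def test_examples(self):
        assert reliability(3, 1) == pytest.approx(0.75)
        assert reliability(7, 7) == pytest.approx(0.5)
        assert reliability(5, 0) == pytest.approx(1.0)
        assert reliability(0, 4) == pytest.approx(0.0)

    def test_smoothed_variant(self):
        assert reliability(0, 0, smoothing=True) == pytest.approx(0.5)
        assert reliability(3, 1, smoothing=True) == pytest.approx(4 / 6)

    def test_undefined_without_detections(self):
        with pytest.raises(ValueError, match="undefined"):
            reliability(0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            reliability(-1, 2)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(t=st.integers(0, 50), f=st.integers(0, 50))
    def test_bounded_and_monotone_in_t(self, t, f):
        if t + f == 0:
            return
        r = reliability(t, f)
        assert 0.0 <= r <= 1.0
        assert reliability(t + 1, f) >= r


class TestExtraction:
    def test_one_template_per_valid_mark(self, preprocessed_training, extracted_templates):
        _, anns = preprocessed_training
        valid = [a for a in anns if a.channel and 0.212 <= a.duration_s <= 0.860]
        assert len(extracted_templates) == len(valid)

    def test_waveform_is_verbatim_slice(self, preprocessed_training):
        recs, anns = preprocessed_training
        tpls = extract_templates(recs, anns)
        by_id = {r.recording_id: r for r in recs}
        tpl, ann = tpls[0], [a for a in anns if a.channel][0]
        rec = derive_montage(by_id[ann.recording_id], ann.montage)
        start = int(round(ann.onset_s * TARGET_RATE))
        stop = start + int(round(ann.duration_s * TARGET_RATE))
        np.testing.assert_array_equal(tpl.waveform, rec.channel(ann.channel)[start:stop])
        assert tpl.montage == ann.montage
        assert tpl.source_channel == ann.channel

    def test_invalid_marks_skipped(self, preprocessed_training):
        recs, _ = preprocessed_training
        rid = recs[0].recording_id
        bad = [
            EventAnnotation(rid, onset_s=1.0, duration_s=0.1),  # no channel
            EventAnnotation("nosuch", onset_s=1.0, duration_s=0.5, channel="C3"),
            EventAnnotation(rid, onset_s=1.0, duration_s=0.1, channel="C3"),  # too short
            EventAnnotation(rid, onset_s=1e6, duration_s=0.5, channel="C3"),  # past end
            EventAnnotation(rid, onset_s=1.0, duration_s=0.5, channel="C3",
                            montage="bipolar"),  # C3 not a bipolar channel
        ]
        assert extract_templates(recs, bad) == []

    def test_template_duration_validation(self):
        with pytest.raises(ValueError, match="duration"):
            Template("x", np.zeros(10), "common_reference", "C3")
        with pytest.raises(ValueError, match="duration"):
            Template("x", np.zeros(90), "common_reference", "C3")

    def test_template_ids_unique(self, extracted_templates):
        ids = [t.template_id for t in extracted_templates]
        assert len(ids) == len(set(ids))


class TestMatchFeatures:
    def _template(self, w):
        return Template("f:common_reference:C3:0", w, "common_reference", "C3")

    def test_identical_epoch(self, rng):
        w = rng.normal(size=40) * 50
        f = compute_match_features(w.copy(), rng.normal(size=100), self._template(w))
        assert f.correlation == pytest.approx(1.0, abs=1e-9)
        assert f.matching_variance == pytest.approx(0.0, abs=1e-9)
        assert f.amplitude_difference == pytest.approx(0.0, abs=1e-9)

    def test_oracle_recomputation(self, rng):
        # each feature recomputed independently from its definition
        w = rng.normal(size=50) * 30
        epoch = 1.3 * w + rng.normal(size=50) * 5
        preceding = rng.normal(size=100) * 10
        f = compute_match_features(epoch, preceding, self._template(w))
        assert f.correlation == pytest.approx(np.corrcoef(epoch, w)[0, 1], abs=1e-9)
        gain = epoch @ w / (w @ w)
        assert f.matching_variance == pytest.approx(np.var(epoch - gain * w), abs=1e-9)
        assert f.amplitude_difference == pytest.approx(
            abs((epoch.max() - epoch.min()) - (w.max() - w.min())), abs=1e-9
        )
        assert f.background_ratio == pytest.approx(
            np.sqrt(np.mean(epoch**2)) / np.sqrt(np.mean(preceding**2)), abs=1e-9
        )

    def test_background_ratio_defaults_to_one_without_context(self, rng):
        w = rng.normal(size=40)
        f = compute_match_features(w, np.array([]), self._template(w))
        assert f.background_ratio == 1.0

    def test_flat_epoch_is_degenerate(self, rng):
        w = rng.normal(size=40)
        f = compute_match_features(np.zeros(40), np.ones(10), self._template(w))
        assert f.degenerate
        assert not self._template(w).passes_gates(f)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            compute_match_features(np.zeros(30), np.array([]),
                                   self._template(rng.normal(size=40)))

    def test_vector_order_matches_names(self):
        f = MatchFeatures(0.9, 2.0, 3.0, 4.0)
        np.testing.assert_array_equal(f.as_vector(), [0.9, 2.0, 3.0, 4.0])
        assert FEATURE_NAMES == (
            "correlation", "matching_variance", "amplitude_difference", "background_ratio"
        )


class TestGates:
    def _tpl(self, **kw):
        rng = np.random.default_rng(0)
        base = dict(template_id="g:common_reference:C3:0", waveform=rng.normal(size=40),
                    montage="common_reference", source_channel="C3", t_count=1, f_count=1)
        base.update(kw)
        return Template(**base)

    def test_bounds_gate(self):
        bounds = np.array([[0.8, 1.0], [0.0, 10.0], [0.0, 50.0], [0.5, 5.0]])
        tpl = self._tpl(bounds=bounds, weights=np.zeros(4), bias=1.0)
        assert tpl.passes_gates(MatchFeatures(0.9, 5.0, 20.0, 2.0))
        assert not tpl.passes_gates(MatchFeatures(0.7, 5.0, 20.0, 2.0))  # below low
        assert not tpl.passes_gates(MatchFeatures(0.9, 11.0, 20.0, 2.0))  # above high

    def test_linear_classifier_sign(self):
        tpl = self._tpl(weights=np.array([1.0, 0.0, 0.0, 0.0]), bias=-0.85)
        assert tpl.passes_gates(MatchFeatures(0.9, 0, 0, 1))
        assert not tpl.passes_gates(MatchFeatures(0.8, 0, 0, 1))

    def test_trivial_accept_and_reject(self):
        accept = self._tpl(weights=np.zeros(4), bias=1.0)
        reject = self._tpl(weights=np.zeros(4), bias=-1.0)
        f = MatchFeatures(0.95, 1.0, 1.0, 1.0)
        assert accept.passes_gates(f)
        assert not reject.passes_gates(f)


def _brute_scan_counts(tpl, derived_recs, annotations, threshold=0.85):
    """Independent T/F count: re-walk every channel with the oracle recipe."""
    t = f = 0
    for rec in derived_recs:
        for ci, channel in enumerate(rec.channel_labels):
            trace = sliding_correlation(rec.signal[ci], tpl.waveform)
            for start in candidate_peaks(trace, threshold, tpl.length):
                stop = start + tpl.length
                hit = any(
                    a.recording_id == rec.recording_id and a.channel == channel
                    and a.montage == tpl.montage and a.label == "ied"
                    and int(round(a.onset_s * TARGET_RATE)) < stop
                    and start < int(round((a.onset_s + a.duration_s) * TARGET_RATE))
                    for a in annotations
                )
                t += hit
                f += not hit
    return t, f


class TestTraining:
    def test_counts_match_brute_force_oracle(self, preprocessed_training, trained_db_unpruned):
        recs, anns = preprocessed_training
        derived = [derive_montage(r, "common_reference") for r in recs]
        checked = 0
        for tpl in list(trained_db_unpruned)[:5]:
            t, f = _brute_scan_counts(tpl, derived, anns)
            assert (tpl.t_count, tpl.f_count) == (t, f)
            checked += 1
        assert checked == 5

    def test_scan_labels_sum_to_counts(self, preprocessed_training, trained_db_unpruned):
        recs, anns = preprocessed_training
        derived = [derive_montage(r, "common_reference") for r in recs]
        tpl = next(iter(trained_db_unpruned))
        feats, labels = scan_template(tpl, derived, anns)
        assert len(feats) == len(labels) == tpl.t_count + tpl.f_count
        assert sum(labels) == tpl.t_count

    def test_every_trained_template_has_classifier(self, trained_db_unpruned):
        for tpl in trained_db_unpruned:
            assert tpl.weights is not None and tpl.weights.shape == (4,)
            if tpl.t_count:
                assert tpl.bounds is not None and tpl.bounds.shape == (4, 2)
                assert np.all(tpl.bounds[:, 0] <= tpl.bounds[:, 1])

    def test_mixed_count_templates_have_nontrivial_classifier(self, trained_db_unpruned):
        mixed = [t for t in trained_db_unpruned if t.t_count and t.f_count]
        assert mixed, "fixture should yield at least one template with both classes"
        for tpl in mixed:
            assert np.any(tpl.weights != 0.0)

    def test_survivors_redetect_their_source_event(
        self, trained_db, preprocessed_training
    ):
        recs, anns = preprocessed_training
        derived = {r.recording_id: derive_montage(r, "common_reference") for r in recs}
        ok = total = 0
        for tpl in trained_db:
            rid, _, channel, start = tpl.template_id.rsplit(":", 3)
            start = int(start)
            x = derived[rid].channel(channel)
            trace = sliding_correlation(x, tpl.waveform)
            peaks = candidate_peaks(trace, 0.85, tpl.length)
            hit = any(abs(int(p) - start) < tpl.length for p in peaks)
            if hit:
                epoch = x[start : start + tpl.length]
                feats = compute_match_features(
                    epoch, x[max(0, start - PRECEDING_SAMPLES) : start], tpl
                )
                hit = tpl.passes_gates(feats)
            ok += hit
            total += 1
        assert total > 0
        assert ok / total >= 0.9

    def test_training_is_deterministic(self, extracted_templates, preprocessed_training):
        recs, anns = preprocessed_training
        a = train_templates(copy.deepcopy(extracted_templates[:4]), recs, anns)
        b = train_templates(copy.deepcopy(extracted_templates[:4]), recs, anns)
        for tid in a.templates:
            ta, tb = a.templates[tid], b.templates[tid]
            assert (ta.t_count, ta.f_count) == (tb.t_count, tb.f_count)
            np.testing.assert_array_equal(ta.weights, tb.weights)
            assert ta.bias == tb.bias


class TestPrune:
    def _db(self, counts):
        rng = np.random.default_rng(1)
        db = TemplateDatabase()
        for i, (t, f) in enumerate(counts):
            tid = f"p{i}:common_reference:C3:0"
            db.templates[tid] = Template(tid, rng.normal(size=40),
                                         "common_reference", "C3", t_count=t, f_count=f)
        return db

    def test_prune_table(self):
        counts = [(0, 0), (0, 5), (1, 0), (1, 1), (5, 0)]
        pruned = prune(self._db(counts))
        kept = sorted((t.t_count, t.f_count) for t in pruned)
        assert kept == [(1, 1), (5, 0)]

    def test_min_true_boundary(self):
        assert len(prune(self._db([(2, 0)]), min_true=2)) == 1
        assert len(prune(self._db([(2, 0)]), min_true=3)) == 0
        # false detections exempt a low-T template from the min_true rule
        assert len(prune(self._db([(1, 3)]), min_true=3)) == 1

    def test_prune_preserves_metadata_and_originals(self):
        db = self._db([(3, 1), (0, 0)])
        db.metadata = {"threshold": 0.85}
        pruned = prune(db)
        assert pruned.metadata == db.metadata
        assert len(db) == 2  # original untouched


class TestCountDeltas:
    def _db(self):
        rng = np.random.default_rng(2)
        db = TemplateDatabase()
        for i in range(3):
            tid = f"d{i}:common_reference:C3:0"
            db.templates[tid] = Template(tid, rng.normal(size=40),
                                         "common_reference", "C3", t_count=5, f_count=2)
        return db

    def test_arithmetic(self):
        db = self._db()
        tid = next(iter(db.templates))
        apply_count_deltas(db, {tid: (3, 1)})
        assert (db.templates[tid].t_count, db.templates[tid].f_count) == (8, 3)

    def test_empty_deltas_noop(self):
        db = self._db()
        before = {tid: (t.t_count, t.f_count) for tid, t in db.templates.items()}
        apply_count_deltas(db, {})
        assert before == {tid: (t.t_count, t.f_count) for tid, t in db.templates.items()}

    def test_additivity(self):
        a, b = self._db(), self._db()
        tid = next(iter(a.templates))
        apply_count_deltas(a, {tid: (2, 1)})
        apply_count_deltas(a, {tid: (1, 1)})
        apply_count_deltas(b, {tid: (3, 2)})
        assert (a.templates[tid].t_count, a.templates[tid].f_count) == (
            b.templates[tid].t_count, b.templates[tid].f_count
        )

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError, match="unknown"):
            apply_count_deltas(self._db(), {"missing": (1, 0)})

    def test_negative_result_rejected(self):
        db = self._db()
        tid = next(iter(db.templates))
        with pytest.raises(ValueError, match="negative"):
            apply_count_deltas(db, {tid: (-10, 0)})


class TestPersistence:
    def test_round_trip(self, trained_db, tmp_path):
        path = tmp_path / "db.h5"
        save_db(trained_db, path)
        back = load_db(path)
        assert back.version == trained_db.version
        assert back.smoothing == trained_db.smoothing
        assert back.metadata == trained_db.metadata
        assert set(back.templates) == set(trained_db.templates)
        for tid, orig in trained_db.templates.items():
            got = back.templates[tid]
            np.testing.assert_array_equal(got.waveform, orig.waveform)
            assert (got.t_count, got.f_count) == (orig.t_count, orig.f_count)
            assert got.montage == orig.montage
            assert got.source_channel == orig.source_channel
            assert got.bias == orig.bias
            if orig.weights is None:
                assert got.weights is None
            else:
                np.testing.assert_array_equal(got.weights, orig.weights)
            if orig.bounds is None:
                assert got.bounds is None
            else:
                np.testing.assert_array_equal(got.bounds, orig.bounds)

    def test_not_a_database_rejected(self, tmp_path):
        import h5py

        path = tmp_path / "other.h5"
        with h5py.File(path, "w") as fh:
            fh.create_dataset("x", data=[1, 2, 3])
        with pytest.raises(ValueError, match="not a template database"):
            load_db(path)

    def test_version_mismatch_rejected(self, trained_db, tmp_path):
        import h5py

        path = tmp_path / "future.h5"
        save_db(trained_db, path)
        with h5py.File(path, "r+") as fh:
            fh.attrs["format_version"] = 99
        with pytest.raises(ValueError, match="version 99"):
            load_db(path)

    def test_corrupted_file_rejected(self, tmp_path):
        path = tmp_path / "garbage.h5"
        path.write_bytes(b"this is not hdf5 at all" * 10)
        with pytest.raises((ValueError, OSError)):
            load_db(path)
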