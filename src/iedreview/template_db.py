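"""The template database: extraction, match features, training, pruning,
persistence and lifetime count updates.

Each template is one annotated spike-wave epoch (a single channel in a
single montage, 0.212-0.860 s at 100 Hz) together with everything the
detector needs to reuse it: a linear classifier over four match features,
per-feature acceptance bounds learned from its true detections, and the
lifetime counts of true (T) and false (F) adjudicated detections from which
its reliability T/(T+F) is derived.  Reliability is what lets the review
phase rank nominations and keep adapting: counts are updated after every
completed review.

Training replays detection on the training set itself: each template scans
all same-montage recordings, every epoch correlating above the nomination
threshold is labelled by whether it overlaps an annotated event on that
channel, and the labelled feature vectors train the classifier and set the
counts.  Templates that never detect, only detect falsely, or detect a
trivially small number of events are pruned.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path

import h5py
import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .config import DEFAULT_THRESHOLD, TARGET_RATE, TEMPLATE_MAX_S, TEMPLATE_MIN_S
from .eeg_io import MONTAGES, EEGRecording, EventAnnotation, derive_montage
from .matching import candidate_peaks, sliding_correlation

logger = logging.getLogger(__name__)

DB_FORMAT_VERSION = 1
FEATURE_NAMES = ("correlation", "matching_variance", "amplitude_difference", "background_ratio")

#: Preceding-background context used by the background_ratio feature (1 s).
PRECEDING_SAMPLES = TARGET_RATE


def reliability(t_count: int, f_count: int, smoothing: bool = False) -> float:
    """Lifetime fraction of true among adjudicated detections.

    Plain ratio T/(T+F); with ``smoothing`` a Laplace-smoothed
    (T+1)/(T+F+2) variant that is defined even for fresh templates.
    """
    if t_count < 0 or f_count < 0:
        raise ValueError("counts must be nonnegative")
    if smoothing:
        return (t_count + 1) / (t_count + f_count + 2)
    if t_count + f_count == 0:
        raise ValueError("reliability undefined for a template with no adjudicated detections")
    return t_count / (t_count + f_count)


@dataclasses.dataclass
class MatchFeatures:
    """Relationship between a detected epoch and the template that found it.

    * ``correlation``: Pearson correlation, in [-1, 1].
    * ``matching_variance``: variance (uV^2) of the residual after scaling
      the template onto the epoch by its least-squares gain.
    * ``amplitude_difference``: absolute peak-to-peak difference (uV).
    * ``background_ratio``: epoch RMS over the RMS of up to 1 s of signal
      preceding it (1.0 when no preceding signal exists).
    """

    correlation: float
    matching_variance: float
    amplitude_difference: float
    background_ratio: float
    degenerate: bool = False

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.correlation, self.matching_variance,
             self.amplitude_difference, self.background_ratio]
        )


@dataclasses.dataclass
class Template:
    """One stored IED waveform plus its classifier and lifetime counts."""

    template_id: str
    waveform: np.ndarray
    montage: str
    source_channel: str
    t_count: int = 0
    f_count: int = 0
    weights: np.ndarray | None = None  # linear classifier over FEATURE_NAMES
    bias: float = 0.0
    bounds: np.ndarray | None = None  # (n_features, 2) [low, high] gates

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        dur = self.waveform.size / TARGET_RATE
        if not (TEMPLATE_MIN_S <= dur <= TEMPLATE_MAX_S):
            raise ValueError(
                f"template duration {dur:.3f} s outside [{TEMPLATE_MIN_S}, {TEMPLATE_MAX_S}] s"
            )
        if self.montage not in MONTAGES:
            raise ValueError(f"unknown montage {self.montage!r}")
        if self.t_count < 0 or self.f_count < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def length(self) -> int:
        return self.waveform.size

    def reliability(self, smoothing: bool = False) -> float:
        return reliability(self.t_count, self.f_count, smoothing)

    def passes_gates(self, features: MatchFeatures) -> bool:
        """Property-bound gate followed by the linear classifier."""
        if features.degenerate:
            return False
        vec = features.as_vector()
        if self.bounds is not None:
            if np.any(vec < self.bounds[:, 0]) or np.any(vec > self.bounds[:, 1]):
                return False
        if self.weights is None:
            return True
        return float(np.dot(self.weights, vec) + self.bias) > 0.0


@dataclasses.dataclass
class TemplateDatabase:
    templates: dict[str, Template] = dataclasses.field(default_factory=dict)
    metadata: dict = dataclasses.field(default_factory=dict)
    smoothing: bool = False
    version: int = DB_FORMAT_VERSION

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates.values())

    def montages(self) -> list[str]:
        return sorted({t.montage for t in self})

    def template_reliability(self, template_id: str) -> float:
        return self.templates[template_id].reliability(self.smoothing)


# ---------------------------------------------------------------------------
# Extraction and features
# ---------------------------------------------------------------------------

def extract_templates(
    recordings: list[EEGRecording], annotations: list[EventAnnotation]
) -> list[Template]:
    """Cut one template per (event, channel, montage) annotation mark.

    Recordings must be preprocessed common-reference at 100 Hz; montages
    named by the annotations are derived on the fly.  Marks outside the
    recording or outside the allowed duration range are skipped with a
    logged reason.
    """
    by_id = {r.recording_id: r for r in recordings}
    derived: dict[tuple[str, str], EEGRecording] = {}
    out: list[Template] = []
    for ann in annotations:
        if ann.channel is None:
            logger.warning("skipping mark without channel at %.3f s", ann.onset_s)
            continue
        rec = by_id.get(ann.recording_id)
        if rec is None:
            logger.warning("skipping mark for unknown recording %s", ann.recording_id)
            continue
        if not (TEMPLATE_MIN_S <= ann.duration_s <= TEMPLATE_MAX_S):
            logger.warning("skipping %.3f s mark: duration outside template range", ann.duration_s)
            continue
        key = (ann.recording_id, ann.montage)
        if key not in derived:
            derived[key] = derive_montage(rec, ann.montage)
        drec = derived[key]
        if ann.channel not in drec.channel_labels:
            logger.warning("skipping mark: channel %s absent in %s montage", ann.channel, ann.montage)
            continue
        start = int(round(ann.onset_s * TARGET_RATE))
        stop = start + int(round(ann.duration_s * TARGET_RATE))
        if start < 0 or stop > drec.n_samples:
            logger.warning("skipping mark outside recording at %.3f s", ann.onset_s)
            continue
        out.append(
            Template(
                template_id=f"{ann.recording_id}:{ann.montage}:{ann.channel}:{start}",
                waveform=drec.channel(ann.channel)[start:stop].copy(),
                montage=ann.montage,
                source_channel=ann.channel,
            )
        )
    return out


def compute_match_features(
    epoch: np.ndarray, preceding: np.ndarray, tpl: Template
) -> MatchFeatures:
    """Compute the four match features between an epoch and a template."""
    epoch = np.asarray(epoch, dtype=float)
    preceding = np.asarray(preceding, dtype=float)
    w = tpl.waveform
    if epoch.size != w.size:
        raise ValueError(f"epoch length {epoch.size} != template length {w.size}")

    ez, wz = epoch - epoch.mean(), w - w.mean()
    e_norm, w_norm = np.sqrt(np.dot(ez, ez)), np.sqrt(np.dot(wz, wz))
    degenerate = e_norm <= 1e-12
    c = 0.0 if degenerate or w_norm <= 1e-12 else float(
        np.clip(np.dot(ez, wz) / (e_norm * w_norm), -1.0, 1.0)
    )

    gain = float(np.dot(epoch, w) / np.dot(w, w)) if np.dot(w, w) > 0 else 0.0
    matching_variance = float(np.var(epoch - gain * w))
    amplitude_difference = float(abs(np.ptp(epoch) - np.ptp(w)))

    rms_epoch = float(np.sqrt(np.mean(epoch**2)))
    if preceding.size:
        rms_prec = float(np.sqrt(np.mean(preceding**2)))
        background_ratio = rms_epoch / max(rms_prec, 1e-12)
    else:
        background_ratio = 1.0
    return MatchFeatures(c, matching_variance, amplitude_difference, background_ratio,
                         degenerate=bool(degenerate))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _annotation_intervals(
    annotations: list[EventAnnotation], recording_id: str, montage: str, channel: str
) -> np.ndarray:
    """Half-open sample intervals of marked events on one derived channel."""
    iv = [
        (int(round(a.onset_s * TARGET_RATE)),
         int(round((a.onset_s + a.duration_s) * TARGET_RATE)))
        for a in annotations
        if a.recording_id == recording_id and a.montage == montage and a.channel == channel
        and a.label == "ied"
    ]
    return np.array(iv, dtype=int).reshape(-1, 2)


def _overlaps_any(start: int, stop: int, intervals: np.ndarray) -> bool:
    if intervals.size == 0:
        return False
    return bool(np.any((intervals[:, 0] < stop) & (start < intervals[:, 1])))


def scan_template(
    tpl: Template,
    derived_recs: list[EEGRecording],
    annotations: list[EventAnnotation],
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[list[MatchFeatures], list[bool]]:
    """Collect labelled supra-threshold detections of one template.

    Every candidate epoch (correlation > threshold, one per template length)
    on any channel of any same-montage recording is labelled true iff it
    overlaps an annotated event on that channel.
    """
    feats: list[MatchFeatures] = []
    labels: list[bool] = []
    m = tpl.length
    for rec in derived_recs:
        for ci, channel in enumerate(rec.channel_labels):
            x = rec.signal[ci]
            trace = sliding_correlation(x, tpl.waveform)
            peaks = candidate_peaks(trace, threshold, m)
            if peaks.size == 0:
                continue
            intervals = _annotation_intervals(annotations, rec.recording_id, tpl.montage, channel)
            for start in peaks:
                stop = start + m
                preceding = x[max(0, start - PRECEDING_SAMPLES): start]
                feats.append(compute_match_features(x[start:stop], preceding, tpl))
                labels.append(_overlaps_any(start, stop, intervals))
    return feats, labels


def _fit_classifier(
    feats: list[MatchFeatures], labels: list[bool], C: float = 1.0
) -> tuple[np.ndarray, float]:
    """Linear maximum-margin separator, scaler folded into the weights."""
    X = np.array([f.as_vector() for f in feats])
    y = np.array(labels, dtype=int)
    scaler = StandardScaler().fit(X)
    scale = np.where(scaler.scale_ > 0, scaler.scale_, 1.0)
    svm = LinearSVC(C=C, class_weight="balanced", dual=False).fit(
        (X - scaler.mean_) / scale, y
    )
    w = svm.coef_[0] / scale
    b = float(svm.intercept_[0] - np.dot(svm.coef_[0], scaler.mean_ / scale))
    return w, b


def _true_feature_bounds(feats: list[MatchFeatures], labels: list[bool]) -> np.ndarray | None:
    true_vecs = np.array([f.as_vector() for f, is_t in zip(feats, labels) if is_t])
    if true_vecs.size == 0:
        return None
    lo, hi = true_vecs.min(axis=0), true_vecs.max(axis=0)
    span = hi - lo
    pad = np.where(span > 0, 0.1 * span, np.maximum(0.1 * np.abs(lo), 1e-9))
    return np.stack([lo - pad, hi + pad], axis=1)


def train_templates(
    templates: list[Template],
    recordings: list[EEGRecording],
    annotations: list[EventAnnotation],
    threshold: float = DEFAULT_THRESHOLD,
    C: float = 1.0,
    smoothing: bool = False,
) -> TemplateDatabase:
    """Train every template against the full training set.

    Sets each template's T/F counts, its linear classifier (trivial accept
    when only true detections exist; trivial reject when none or only false
    ones) and its property bounds.  Deterministic given its inputs.
    """
    db = TemplateDatabase(smoothing=smoothing)
    montages_needed = sorted({t.montage for t in templates})
    derived = {
        mont: [derive_montage(r, mont) for r in recordings] for mont in montages_needed
    }
    for tpl in templates:
        feats, labels = scan_template(tpl, derived[tpl.montage], annotations, threshold)
        tpl.t_count = int(sum(labels))
        tpl.f_count = int(len(labels) - sum(labels))
        if tpl.t_count and tpl.f_count:
            tpl.weights, tpl.bias = _fit_classifier(feats, labels, C)
        elif tpl.t_count:
            tpl.weights, tpl.bias = np.zeros(len(FEATURE_NAMES)), 1.0
        else:
            tpl.weights, tpl.bias = np.zeros(len(FEATURE_NAMES)), -1.0
        tpl.bounds = _true_feature_bounds(feats, labels)
        db.templates[tpl.template_id] = tpl
    db.metadata = {
        "training_recordings": sorted({r.recording_id for r in recordings}),
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "threshold": threshold,
        "n_extracted": len(templates),
    }
    return db


def prune(db: TemplateDatabase, min_true: int = 2) -> TemplateDatabase:
    """Discard templates that never help.

    Removed: zero detections (T+F == 0); only false detections (T == 0,
    F > 0); and a small number of correct detections with no false ones
    (0 < T < min_true, F == 0).
    """
    kept = {}
    for tid, t in db.templates.items():
        if t.t_count + t.f_count == 0:
            continue
        if t.t_count == 0:
            continue
        if t.f_count == 0 and t.t_count < min_true:
            continue
        kept[tid] = t
    return TemplateDatabase(templates=kept, metadata=dict(db.metadata),
                            smoothing=db.smoothing, version=db.version)


def apply_count_deltas(
    db: TemplateDatabase, deltas: dict[str, tuple[int, int]]
) -> TemplateDatabase:
    """Add (dT, dF) to each template's lifetime counts, in place."""
    unknown = sorted(set(deltas) - set(db.templates))
    if unknown:
        raise KeyError(f"unknown template ids in deltas: {unknown}")
    for tid, (dt, df) in deltas.items():
        tpl = db.templates[tid]
        if tpl.t_count + dt < 0 or tpl.f_count + df < 0:
            raise ValueError(f"deltas would make counts negative for {tid}")
        tpl.t_count += dt
        tpl.f_count += df
    return db


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_db(db: TemplateDatabase, path: str | Path) -> None:
    """Write the database to a single versioned HDF5 container."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = db.version
        fh.attrs["smoothing"] = db.smoothing
        fh.attrs["metadata"] = json.dumps(db.metadata)
        grp = fh.create_group("templates")
        for tid, t in db.templates.items():
            g = grp.create_group(tid)
            g.create_dataset("waveform", data=t.waveform)
            g.attrs["montage"] = t.montage
            g.attrs["source_channel"] = t.source_channel
            g.attrs["t_count"] = t.t_count
            g.attrs["f_count"] = t.f_count
            g.attrs["bias"] = t.bias
            if t.weights is not None:
                g.create_dataset("weights", data=t.weights)
            if t.bounds is not None:
                g.create_dataset("bounds", data=t.bounds)


def load_db(path: str | Path) -> TemplateDatabase:
    with h5py.File(path, "r") as fh:
        if "format_version" not in fh.attrs:
            raise ValueError(f"{path} is not a template database (no version field)")
        version = int(fh.attrs["format_version"])
        if version != DB_FORMAT_VERSION:
            raise ValueError(
                f"database format version {version} unsupported (expected {DB_FORMAT_VERSION})"
            )
        db = TemplateDatabase(
            metadata=json.loads(fh.attrs["metadata"]),
            smoothing=bool(fh.attrs["smoothing"]),
            version=version,
        )
        for tid, g in fh["templates"].items():
            db.templates[tid] = Template(
                template_id=tid,
                waveform=g["waveform"][()],
                montage=g.attrs["montage"],
                source_channel=g.attrs["source_channel"],
                t_count=int(g.attrs["t_count"]),
                f_count=int(g.attrs["f_count"]),
                weights=g["weights"][()] if "weights" in g else None,
                bias=float(g.attrs["bias"]),
                bounds=g["bounds"][()] if "bounds" in g else None,
            )
    return db
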