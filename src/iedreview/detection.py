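"""Template-based scanning of a recording into per-template IED nominations.

Every template in the database is slid over every channel of its montage
(derived from the preprocessed common-reference recording).  Positions where
the normalized correlation exceeds the nomination threshold (0.85, strict)
become candidates after non-maximum suppression over one template length;
candidates that satisfy the template's property bounds and its linear
classifier become nominations, each carrying the template's current
reliability.  Detection is decoupled from review: nominations round-trip
through a CSV file so a recording can be scanned once and reviewed later.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_THRESHOLD, TARGET_RATE
from .eeg_io import EEGRecording, derive_montage
from .matching import candidate_peaks, sliding_correlation  # re-exported
from .template_db import (
    PRECEDING_SAMPLES,
    MatchFeatures,
    Template,
    TemplateDatabase,
    compute_match_features,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Nomination",
    "sliding_correlation",
    "detect_with_template",
    "detect_all",
    "write_nominations",
    "read_nominations",
]

_NOMINATION_COLUMNS = [
    "template_id", "montage", "channel", "start_s", "duration_s", "correlation", "reliability",
]


@dataclasses.dataclass(frozen=True)
class Nomination:
    """One template's supra-threshold, gate-approved detection."""

    template_id: str
    montage: str
    channel: str
    start: int  # half-open [start, end) in samples at 100 Hz
    end: int
    correlation: float
    reliability: float
    features: MatchFeatures | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty nomination interval")
        if not (-1.0 <= self.correlation <= 1.0):
            raise ValueError("correlation outside [-1, 1]")
        if not (0.0 <= self.reliability <= 1.0):
            raise ValueError("reliability outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def onset_s(self) -> float:
        return self.start / TARGET_RATE

    @property
    def duration_s(self) -> float:
        return self.length / TARGET_RATE


def detect_with_template(
    rec: EEGRecording,
    tpl: Template,
    threshold: float = DEFAULT_THRESHOLD,
    smoothing: bool = False,
) -> list[Nomination]:
    """Scan every channel of a same-montage recording with one template."""
    if rec.montage != tpl.montage:
        raise ValueError(
            f"recording montage {rec.montage!r} does not match template montage {tpl.montage!r}"
        )
    if rec.sample_rate != TARGET_RATE:
        raise ValueError("recording must be preprocessed to 100 Hz before detection")
    r = tpl.reliability(smoothing)
    m = tpl.length
    out: list[Nomination] = []
    for ci, channel in enumerate(rec.channel_labels):
        x = rec.signal[ci]
        if x.size < m:
            continue
        trace = sliding_correlation(x, tpl.waveform)
        for start in candidate_peaks(trace, threshold, m):
            stop = int(start) + m
            preceding = x[max(0, start - PRECEDING_SAMPLES): start]
            feats = compute_match_features(x[start:stop], preceding, tpl)
            if not tpl.passes_gates(feats):
                continue
            out.append(
                Nomination(
                    template_id=tpl.template_id, montage=tpl.montage, channel=channel,
                    start=int(start), end=stop, correlation=float(trace[start]),
                    reliability=r, features=feats,
                )
            )
    return out


def detect_all(
    rec_common: EEGRecording,
    db: TemplateDatabase,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[Nomination]:
    """Run every template of every montage present in the database.

    The needed montages are derived from the preprocessed common-reference
    recording; results are sorted by (montage, channel, start, template_id)
    so the output is deterministic regardless of scan order.
    """
    if rec_common.montage != "common_reference":
        raise ValueError("detect_all expects a common-reference recording")
    if len(db) == 0:
        logger.warning("template database is empty; no nominations possible")
        return []
    noms: list[Nomination] = []
    for montage in db.montages():
        drec = derive_montage(rec_common, montage)
        for tpl in sorted(db, key=lambda t: t.template_id):
            if tpl.montage != montage:
                continue
            noms.extend(detect_with_template(drec, tpl, threshold, db.smoothing))
    noms.sort(key=lambda n: (n.montage, n.channel, n.start, n.template_id))
    return noms


def write_nominations(noms: list[Nomination], path: str | Path) -> None:
    rows = [
        {
            "template_id": n.template_id, "montage": n.montage, "channel": n.channel,
            "start_s": f"{n.onset_s:.6f}", "duration_s": f"{n.duration_s:.6f}",
            "correlation": f"{n.correlation:.9f}", "reliability": f"{n.reliability:.9f}",
        }
        for n in noms
    ]
    pd.DataFrame(rows, columns=_NOMINATION_COLUMNS).to_csv(path, index=False)


def read_nominations(path: str | Path) -> list[Nomination]:
    df = pd.read_csv(path, dtype={"template_id": str, "montage": str, "channel": str})
    missing = set(_NOMINATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"nomination file missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        start = int(round(float(row.start_s) * TARGET_RATE))
        out.append(
            Nomination(
                template_id=row.template_id, montage=row.montage, channel=row.channel,
                start=start, end=start + int(round(float(row.duration_s) * TARGET_RATE)),
                correlation=float(row.correlation), reliability=float(row.reliability),
            )
        )
    return out
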