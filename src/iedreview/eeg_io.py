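"""EDF reading, montage derivation, preprocessing and annotation files.

Recordings enter as common-reference EDF at their native rate (clinical
scalp EEG is typically digitized at 250/256 Hz), are band-pass filtered
0.5-30 Hz with a zero-phase Butterworth filter and resampled to the internal
100 Hz processing rate.  Review and template matching happen in three
derivations: common reference, longitudinal bipolar ("double banana") and a
small Laplacian (electrode minus the mean of its 10-20 neighbours).  The
derivation tables ship as editable YAML (``data/montages.yaml``).

Independent-component eye-blink removal, sometimes applied clinically before
detection, is deliberately not part of this chain; the band-pass is the only
artifact mitigation.

Time convention: all internal intervals are half-open ``[start, end)`` in
samples at 100 Hz, 0-based; annotation files speak seconds.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from fractions import Fraction
from pathlib import Path

import mne
import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .config import BAND_HIGH, BAND_LOW, TARGET_RATE

MONTAGES = ("common_reference", "bipolar", "laplacian")
ANNOTATION_LABELS = ("ied", "rejected", "unsure")
_ANNOTATION_COLUMNS = ["recording_id", "channel", "onset_s", "duration_s", "label"]


def _load_montage_tables() -> dict:
    ref = importlib.resources.files("iedreview").joinpath("data/montages.yaml")
    with ref.open() as fh:
        return yaml.safe_load(fh)

_TABLES = _load_montage_tables()
CANONICAL_CHANNELS: list[str] = list(_TABLES["channel_order"])
BIPOLAR_CHAIN: list[tuple[str, str]] = [tuple(p) for p in _TABLES["bipolar"]]
LAPLACIAN_NEIGHBORS: dict[str, list[str]] = {
    k: list(v) for k, v in _TABLES["laplacian_neighbors"].items()
}


@dataclasses.dataclass
class EEGRecording:
    """Multichannel EEG signal with channel labels and montage tag.

    ``signal`` is a channels x samples float array in microvolts.  All
    channels share one sample rate and length; the montage tag records which
    derivation has been applied.
    """

    channel_labels: list[str]
    sample_rate: float
    signal: np.ndarray
    montage: str = "common_reference"
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples array")
        if self.signal.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{len(self.channel_labels)} labels but {self.signal.shape[0]} signal rows"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.montage not in MONTAGES:
            raise ValueError(f"unknown montage {self.montage!r}; expected one of {MONTAGES}")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.signal[self.channel_labels.index(label)]
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None


@dataclasses.dataclass(frozen=True)
class EventAnnotation:
    """One marked event: onset/duration in seconds from recording start.

    ``channel`` is optional because evaluation-style marks carry only timing,
    while training marks name the channel the waveform was seen on.
    """

    recording_id: str
    onset_s: float
    duration_s: float
    label: str = "ied"
    channel: str | None = None
    montage: str = "common_reference"

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("onset must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")
        if self.label not in ANNOTATION_LABELS:
            raise ValueError(f"label must be one of {ANNOTATION_LABELS}")
        if self.montage not in MONTAGES:
            raise ValueError(f"unknown montage {self.montage!r}")


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------

def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a common-reference recording as a 16-bit EDF file.

    A deliberately small writer for fixtures and synthetic data (no installed
    package writes EDF).  Uses 1-second data records, so the recording length
    must be a whole number of seconds and the rate an integer.
    """
    path = Path(path)
    rate = rec.sample_rate
    if rate != int(rate):
        raise ValueError("EDF writer requires an integer sample rate")
    rate = int(rate)
    if rec.n_samples % rate != 0:
        raise ValueError("EDF writer requires a whole number of seconds")
    n_records = rec.n_samples // rate
    n_sig = len(rec.channel_labels)

    def field(value, width: int) -> bytes:
        s = str(value)
        if len(s) > width:
            s = s[:width]
        return s.ljust(width).encode("ascii")

    # Physical range symmetric around zero; digital range full 16-bit.  The
    # header stores the range as truncated decimal strings, so scaling must
    # use those exact rounded values or the reader would rescale differently.
    phys_max_str = [f"{m:.6g}"[:8] for m in np.maximum(np.abs(rec.signal).max(axis=1), 1.0)]
    phys_max = np.array([float(s) for s in phys_max_str])
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            field("0", 8),
            field("X X X X", 80),
            field(f"Startdate 01-JAN-2000 {rec.recording_id or 'X'} X X", 80),
            field("01.01.00", 8),
            field("00.00.00", 8),
            field(256 * (1 + n_sig), 8),
            field("", 44),
            field(n_records, 8),
            field(1, 8),
            field(n_sig, 4),
        ]
    )
    sig_fields = []
    for spec_width, values in [
        (16, rec.channel_labels),
        (80, ["AgAgCl electrode"] * n_sig),
        (8, ["uV"] * n_sig),
        (8, [f"-{s}"[:8] for s in phys_max_str]),
        (8, phys_max_str),
        (8, [dig_min] * n_sig),
        (8, [dig_max] * n_sig),
        (80, [""] * n_sig),
        (8, [rate] * n_sig),
        (32, [""] * n_sig),
    ]:
        sig_fields.append(b"".join(field(v, spec_width) for v in values))
    header += b"".join(sig_fields)

    # exact inverse of the EDF digital->physical mapping
    span = (dig_max - dig_min) / (2.0 * phys_max)
    digital = np.rint((rec.signal + phys_max[:, None]) * span[:, None] + dig_min)
    digital = digital.clip(dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            sl = digital[:, r * rate : (r + 1) * rate]
            fh.write(sl.tobytes())


def read_recording(path: str | Path, recording_id: str | None = None) -> EEGRecording:
    """Read an EDF file into a common-reference recording at native rate.

    Channels are reordered to the canonical 10-20 ordering; any required
    electrode missing from the file is reported by name.
    """
    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = {name.strip().lower(): i for i, name in enumerate(raw.ch_names)}
    missing = [ch for ch in CANONICAL_CHANNELS if ch.lower() not in labels]
    if missing:
        raise ValueError(
            f"EDF file {path.name} lacks required 10-20 electrodes: {', '.join(missing)}"
        )
    data = raw.get_data()  # volts
    rows = [labels[ch.lower()] for ch in CANONICAL_CHANNELS]
    sig_uv = data[rows] * 1e6
    return EEGRecording(
        channel_labels=list(CANONICAL_CHANNELS),
        sample_rate=float(raw.info["sfreq"]),
        signal=sig_uv,
        montage="common_reference",
        recording_id=recording_id or path.stem,
    )


# ---------------------------------------------------------------------------
# Preprocessing and montages
# ---------------------------------------------------------------------------

def preprocess(rec: EEGRecording) -> EEGRecording:
    """Resample to 100 Hz, then band-pass 0.5-30 Hz with zero phase.

    Resampling uses a polyphase filter at the exact rational rate ratio; the
    4th-order Butterworth band-pass is applied forward-backward
    (``sosfiltfilt``) so event onsets are not shifted between montages.
    Filtering last means the output is band-limited by construction, so
    preprocessing its own output is a no-op up to filter accuracy.
    """
    if rec.sample_rate < TARGET_RATE:
        raise ValueError(
            f"native rate {rec.sample_rate} Hz is below the {TARGET_RATE} Hz target"
        )
    sig = rec.signal
    if rec.sample_rate != TARGET_RATE:
        frac = Fraction(TARGET_RATE, int(round(rec.sample_rate))).limit_denominator(10000)
        sig = sps.resample_poly(sig, frac.numerator, frac.denominator, axis=1)
    sos = sps.butter(4, [BAND_LOW, BAND_HIGH], btype="bandpass", fs=TARGET_RATE, output="sos")
    filtered = sps.sosfiltfilt(sos, sig, axis=1)
    return EEGRecording(
        channel_labels=list(rec.channel_labels),
        sample_rate=float(TARGET_RATE),
        signal=filtered,
        montage=rec.montage,
        recording_id=rec.recording_id,
    )


def derive_montage(rec: EEGRecording, montage: str) -> EEGRecording:
    """Derive a review montage from a common-reference recording.

    ``bipolar`` chains the longitudinal double banana (labels like
    ``Fp1-F7``); ``laplacian`` subtracts the mean of each electrode's 10-20
    neighbours; ``common_reference`` is the identity.
    """
    if rec.montage != "common_reference":
        raise ValueError("montage derivation starts from a common-reference recording")
    if montage == "common_reference":
        return dataclasses.replace(rec, signal=rec.signal.copy())
    if montage == "bipolar":
        idx = {ch: i for i, ch in enumerate(rec.channel_labels)}
        labels = [f"{a}-{b}" for a, b in BIPOLAR_CHAIN]
        sig = np.stack([rec.signal[idx[a]] - rec.signal[idx[b]] for a, b in BIPOLAR_CHAIN])
        return EEGRecording(labels, rec.sample_rate, sig, "bipolar", rec.recording_id)
    if montage == "laplacian":
        idx = {ch: i for i, ch in enumerate(rec.channel_labels)}
        rows = []
        for ch in rec.channel_labels:
            nbrs = LAPLACIAN_NEIGHBORS[ch]
            rows.append(rec.signal[idx[ch]] - rec.signal[[idx[n] for n in nbrs]].mean(axis=0))
        return EEGRecording(
            list(rec.channel_labels), rec.sample_rate, np.stack(rows), "laplacian",
            rec.recording_id,
        )
    raise ValueError(f"unknown montage {montage!r}; expected one of {MONTAGES}")


# ---------------------------------------------------------------------------
# Annotation files
# ---------------------------------------------------------------------------

def write_annotations(events: list[EventAnnotation], path: str | Path) -> None:
    """Write events as CSV (header row, '.' decimal, seconds to >= 3 d.p.)."""
    rows = [
        {
            "recording_id": e.recording_id,
            "channel": e.channel if e.channel is not None else "",
            "onset_s": f"{e.onset_s:.6f}",
            "duration_s": f"{e.duration_s:.6f}",
            "label": e.label,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS).to_csv(path, index=False)


def read_annotations(path: str | Path) -> list[EventAnnotation]:
    df = pd.read_csv(path, dtype={"recording_id": str, "channel": str, "label": str})
    missing = set(_ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    events = []
    for row in df.itertuples(index=False):
        channel = row.channel if isinstance(row.channel, str) and row.channel else None
        events.append(
            EventAnnotation(
                recording_id=row.recording_id,
                channel=channel,
                onset_s=float(row.onset_s),
                duration_s=float(row.duration_s),
                label=row.label,
            )
        )
    return events
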