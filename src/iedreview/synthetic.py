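"""Seeded synthetic scalp EEG with injected spike-wave discharges.

Clinical IED-annotated EEG is rarely shareable, so this module generates the
study conditions instead: 19-channel 10-20 background activity (1/f-weighted
noise plus a posterior-dominant alpha rhythm, with slow amplitude
non-stationarity) into which spike-and-slow-wave events from a handful of
"families" are injected with per-event amplitude/duration jitter, a focal
channel and attenuated spread to neighbours.  Every generator is a pure
function of its seed.

Defaults emulate a sparse clinical picture: about one discharge per minute,
spike peaks well above the ~15 uV RMS background, durations inside the
0.212-0.860 s template range.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import TARGET_RATE, TEMPLATE_MAX_S, TEMPLATE_MIN_S
from .eeg_io import CANONICAL_CHANNELS, EEGRecording, EventAnnotation

#: Channels carrying the posterior-dominant rhythm, with relative strength.
_POSTERIOR_WEIGHTS = {
    "O1": 1.0, "O2": 1.0, "P3": 0.6, "Pz": 0.6, "P4": 0.6, "T5": 0.5, "T6": 0.5,
}

#: Spread channels are listed in training annotations when their gain is at
#: least this visible fraction of the focal amplitude.
VISIBILITY_GAIN = 0.5


@dataclasses.dataclass(frozen=True)
class SpikeWaveParams:
    """Shape and topography of one spike-wave family.

    ``duration`` must lie in the template range [0.212, 0.860] s.  The
    waveform peaks at ``spike_amplitude`` (uV); ``wave_amplitude`` sets the
    slow-wave plateau relative to it.  ``asymmetry`` skews the biphasic
    spike transient.  The event appears at full gain on ``focus_channels``
    and at ``spread_attenuation[label]`` times that on neighbours.
    """

    duration: float
    spike_amplitude: float
    wave_amplitude: float
    polarity: int = 1
    asymmetry: float = 0.5
    focus_channels: tuple[str, ...] = ("Cz",)
    spread_attenuation: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (TEMPLATE_MIN_S <= self.duration <= TEMPLATE_MAX_S):
            raise ValueError(
                f"duration {self.duration} s outside [{TEMPLATE_MIN_S}, {TEMPLATE_MAX_S}] s"
            )
        if self.spike_amplitude <= 0 or self.wave_amplitude <= 0:
            raise ValueError("amplitudes must be positive")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")
        if not self.focus_channels:
            raise ValueError("focus_channels must be nonempty")
        for ch, g in self.spread_attenuation.items():
            if not (0.0 < g <= 1.0):
                raise ValueError(f"spread gain for {ch} must be in (0, 1], got {g}")

    @property
    def visible_channels(self) -> tuple[str, ...]:
        """Focus channels plus spread channels at visible gain."""
        spread = [c for c, g in self.spread_attenuation.items() if g >= VISIBILITY_GAIN]
        return tuple(self.focus_channels) + tuple(spread)


@dataclasses.dataclass(frozen=True)
class InjectedEvent:
    onset_s: float
    duration_s: float
    focus_channels: tuple[str, ...]
    family_id: int
    amplitude_scale: float = 1.0


@dataclasses.dataclass
class GroundTruth:
    """Exact per-event record of what was injected, plus a thinning flag."""

    recording_id: str
    events: list[InjectedEvent]
    thinned: bool = False

    def __len__(self) -> int:
        return len(self.events)


def default_families() -> list[SpikeWaveParams]:
    """Four spike-wave families with distinct foci, durations and polarity."""
    return [
        SpikeWaveParams(0.30, 150.0, 60.0, polarity=-1, asymmetry=0.4,
                        focus_channels=("T3",),
                        spread_attenuation={"F7": 0.6, "T5": 0.6, "C3": 0.3}),
        SpikeWaveParams(0.45, 140.0, 70.0, polarity=-1, asymmetry=0.7,
                        focus_channels=("T4",),
                        spread_attenuation={"F8": 0.6, "T6": 0.6, "C4": 0.3}),
        SpikeWaveParams(0.60, 160.0, 80.0, polarity=1, asymmetry=0.5,
                        focus_channels=("Fz",),
                        spread_attenuation={"F3": 0.6, "F4": 0.6, "Cz": 0.4}),
        SpikeWaveParams(0.35, 190.0, 85.0, polarity=-1, asymmetry=0.6,
                        focus_channels=("O1", "O2"),
                        spread_attenuation={"P3": 0.5, "P4": 0.5}),
    ]


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS noise with a 1/f spectrum above 1 Hz, flat below."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / TARGET_RATE)
    weights = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    weights[0] = 0.0
    x = np.fft.irfft(spec * weights, n=n)
    return x / x.std()


def generate_background(
    n_channels: int = 19,
    duration_s: float = 300.0,
    seed: int = 0,
    rms_uv: float = 15.0,
) -> EEGRecording:
    """Generate seeded 100 Hz background EEG without any discharges.

    Each channel is 1/f-weighted noise at ``rms_uv`` microvolts RMS with a
    slow (0.05 Hz) random amplitude modulation; posterior channels carry an
    additional amplitude-modulated 8-12 Hz rhythm so their spectra peak in
    the alpha band.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * TARGET_RATE))
    labels = CANONICAL_CHANNELS[:n_channels]
    t = np.arange(n) / TARGET_RATE
    sig = np.empty((len(labels), n))
    for i, ch in enumerate(labels):
        base = _pink_noise(rng, n) * rms_uv
        # slow non-stationary gain so pre-event background level varies
        gain = 1.0 + 0.3 * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
        row = base * gain
        w = _POSTERIOR_WEIGHTS.get(ch, 0.0)
        if w > 0:
            f_alpha = rng.uniform(8.5, 11.5)
            envelope = 1.0 + 0.4 * np.sin(2 * np.pi * 0.2 * t + rng.uniform(0, 2 * np.pi))
            row = row + 1.6 * w * rms_uv * envelope * np.sin(
                2 * np.pi * f_alpha * t + rng.uniform(0, 2 * np.pi)
            )
        sig[i] = row
    return EEGRecording(labels, float(TARGET_RATE), sig, "common_reference",
                        recording_id=f"synth-bg-{seed}")


def make_spike_wave(params: SpikeWaveParams, sample_rate: float = TARGET_RATE) -> np.ndarray:
    """Render one spike-and-slow-wave prototype as a sample vector.

    A biphasic spike transient (difference of Gaussians, 20-70 ms) is
    followed by a half-sine slow wave filling the remaining duration.  The
    peak absolute amplitude equals ``spike_amplitude`` exactly; ``polarity``
    flips the whole waveform.
    """
    n = int(round(params.duration * sample_rate))
    t = np.arange(n) / sample_rate
    spike_dur = float(np.clip(0.25 * params.duration, 0.02, 0.07))
    tc = spike_dur / 2.0
    sigma = spike_dur / 6.0
    spike = np.exp(-((t - tc) ** 2) / (2 * sigma**2)) - 0.6 * np.exp(
        -((t - tc - params.asymmetry * sigma) ** 2) / (2 * (1.8 * sigma) ** 2)
    )
    spike /= np.abs(spike).max()
    wave = np.zeros(n)
    tail = t >= spike_dur
    if tail.any():
        wave[tail] = np.sin(np.pi * (t[tail] - spike_dur) / (params.duration - spike_dur))
    raw = params.spike_amplitude * spike + params.wave_amplitude * wave
    raw *= params.spike_amplitude / np.abs(raw).max()
    return params.polarity * raw


def _make_distractor(rng: np.random.Generator, sample_rate: float = TARGET_RATE) -> np.ndarray:
    """A benign sharp transient of variable morphology, random polarity.

    Spans the range from an isolated sharp deflection to a spike-wave
    look-alike (slow-wave tail of random relative size), emulating the
    non-epileptiform sharp activity that causes template false positives.
    """
    dur = rng.uniform(0.22, 0.60)
    n = int(round(dur * sample_rate))
    t = np.arange(n) / sample_rate
    spike_dur = rng.uniform(0.04, 0.10)
    tc = spike_dur / 2.0
    sigma = rng.uniform(0.008, 0.02)
    shape = np.exp(-((t - tc) ** 2) / (2 * sigma**2)) - 0.5 * np.exp(
        -((t - tc - sigma) ** 2) / (2 * (2.0 * sigma) ** 2)
    )
    shape /= np.abs(shape).max()
    tail = t >= spike_dur
    wave = np.zeros(n)
    if tail.any():
        wave[tail] = np.sin(np.pi * (t[tail] - spike_dur) / (dur - spike_dur))
    shape = shape + rng.uniform(0.0, 0.8) * wave
    amp = rng.uniform(60.0, 120.0)
    return rng.choice([-1.0, 1.0]) * amp * shape / np.abs(shape).max()


def inject_events(
    rec: EEGRecording,
    families: list[SpikeWaveParams],
    rate_per_min: float = 1.0,
    jitter: float = 0.1,
    seed: int = 0,
    distractor_rate_per_min: float = 2.0,
) -> tuple[EEGRecording, GroundTruth]:
    """Add spike-wave events to a recording; return it with exact truth.

    Event times are drawn uniformly with a 2 s guard between onsets and a
    2 s margin at both ends; events that cannot be placed are thinned and
    flagged.  Per-event jitter multiplies amplitude and duration by
    ``U(1-jitter, 1+jitter)`` (duration clipped to the template range).

    Sharp non-epileptiform transients are also injected at
    ``distractor_rate_per_min`` on random channels (with a weakly spread
    copy on a second channel).  They are *not* part of the ground truth:
    they emulate the benign sharp activity of real EEG that gives template
    matching its false positives and the review loop something to reject.
    """
    if rec.sample_rate != TARGET_RATE:
        raise ValueError(f"recording must be at {TARGET_RATE} Hz")
    rng = np.random.default_rng(seed)
    sig = rec.signal.copy()
    dur_s = rec.duration_s
    n_target = int(round(rate_per_min * dur_s / 60.0)) if families else 0
    n_distr = int(round(distractor_rate_per_min * dur_s / 60.0))
    truth = GroundTruth(recording_id=rec.recording_id, events=[])
    if n_target == 0 and n_distr == 0:
        return dataclasses.replace(rec, signal=sig), truth

    margin, guard = 2.0, 2.0
    onsets: list[float] = []
    attempts = 0
    while len(onsets) < n_target + n_distr and attempts < 50 * (n_target + n_distr):
        cand = rng.uniform(margin, dur_s - margin - TEMPLATE_MAX_S)
        if all(abs(cand - o) >= guard for o in onsets):
            onsets.append(cand)
        attempts += 1
    if len(onsets) < n_target:
        truth.thinned = True
    distractor_onsets = sorted(onsets[n_target:])
    onsets = sorted(onsets[: n_target])

    idx = {ch: i for i, ch in enumerate(rec.channel_labels)}
    for onset in onsets:
        fam_id = int(rng.integers(len(families)))
        fam = families[fam_id]
        amp_scale = float(rng.uniform(1 - jitter, 1 + jitter))
        dur = float(np.clip(fam.duration * rng.uniform(1 - jitter, 1 + jitter),
                            TEMPLATE_MIN_S, TEMPLATE_MAX_S))
        # quantize to the sample grid so truth durations reproduce the shape
        dur = round(dur * TARGET_RATE) / TARGET_RATE
        wf = make_spike_wave(dataclasses.replace(fam, duration=dur)) * amp_scale
        start = int(round(onset * TARGET_RATE))
        stop = start + len(wf)
        for ch in fam.focus_channels:
            if ch in idx:
                sig[idx[ch], start:stop] += wf
        for ch, gain in fam.spread_attenuation.items():
            if ch in idx:
                sig[idx[ch], start:stop] += gain * wf
        truth.events.append(
            InjectedEvent(onset_s=start / TARGET_RATE, duration_s=len(wf) / TARGET_RATE,
                          focus_channels=tuple(fam.focus_channels), family_id=fam_id,
                          amplitude_scale=amp_scale)
        )
    n_ch = sig.shape[0]
    for onset in distractor_onsets:
        wf = _make_distractor(rng)
        start = int(round(onset * TARGET_RATE))
        ch = int(rng.integers(n_ch))
        sig[ch, start:start + len(wf)] += wf
        # weak spread to an adjacent row so multi-channel merging sees it
        other = (ch + 1) % n_ch
        sig[other, start:start + len(wf)] += 0.4 * wf
    return dataclasses.replace(rec, signal=sig), truth


@dataclasses.dataclass
class DatasetSpec:
    """Desk-scale dataset layout: small but structurally faithful."""

    n_train: int = 3
    n_eval: int = 3
    duration_s: float = 300.0
    rate_per_min: float = 1.0
    distractor_rate_per_min: float = 2.0
    jitter: float = 0.1
    rms_uv: float = 15.0
    families: list[SpikeWaveParams] = dataclasses.field(default_factory=default_families)


def make_dataset(
    spec: DatasetSpec | None = None, seed: int = 0
) -> tuple[
    list[EEGRecording], list[EventAnnotation], list[EEGRecording], list[GroundTruth]
]:
    """Generate a training set and a disjoint evaluation set.

    Training annotations mark each event on every channel where it is
    visible (channel labels included, as a trainer would mark them);
    evaluation ground truth keeps onset/duration only, mirroring how
    evaluation recordings are typically marked without channel detail.
    Jitter draws differ between the two sets.
    """
    spec = spec or DatasetSpec()
    root = np.random.default_rng(seed)
    # independent child seeds; keep them well below 2**31
    seeds = root.integers(0, 2**30, size=2 * (spec.n_train + spec.n_eval))
    train_recs, train_anns, eval_recs, eval_truths = [], [], [], []
    k = 0
    for i in range(spec.n_train):
        bg = generate_background(19, spec.duration_s, seed=int(seeds[k]), rms_uv=spec.rms_uv)
        rec, truth = inject_events(bg, spec.families, spec.rate_per_min, spec.jitter,
                                   seed=int(seeds[k + 1]),
                                   distractor_rate_per_min=spec.distractor_rate_per_min)
        k += 2
        rec = dataclasses.replace(rec, recording_id=f"train-{seed}-{i}")
        train_recs.append(rec)
        for ev in truth.events:
            fam = spec.families[ev.family_id]
            for ch in fam.visible_channels:
                train_anns.append(
                    EventAnnotation(recording_id=rec.recording_id, channel=ch,
                                    onset_s=ev.onset_s, duration_s=ev.duration_s,
                                    label="ied")
                )
    for i in range(spec.n_eval):
        bg = generate_background(19, spec.duration_s, seed=int(seeds[k]), rms_uv=spec.rms_uv)
        rec, truth = inject_events(bg, spec.families, spec.rate_per_min, spec.jitter,
                                   seed=int(seeds[k + 1]),
                                   distractor_rate_per_min=spec.distractor_rate_per_min)
        k += 2
        rec = dataclasses.replace(rec, recording_id=f"eval-{seed}-{i}")
        truth.recording_id = rec.recording_id
        eval_recs.append(rec)
        eval_truths.append(truth)
    return train_recs, train_anns, eval_recs, eval_truths
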