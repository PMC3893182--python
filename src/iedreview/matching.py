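"""FFT-based normalized sliding correlation and candidate peak picking.

The correlation trace is the core primitive of template matching: at every
position it equals the Pearson correlation between the template and the
signal window starting there.  The numerator is a single FFT convolution
with the zero-meaned template (whose window-mean term vanishes because the
zero-meaned template sums to zero); window means and energies come from
running sums, so the whole trace costs O(n log n) instead of O(n m).
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

#: Windows whose energy falls below this are treated as flat (correlation 0).
_VAR_EPS = 1e-12


def sliding_correlation(channel_signal: np.ndarray, waveform: np.ndarray) -> np.ndarray:
    """Pearson correlation of ``waveform`` against every signal window.

    Returns a trace of length ``len(signal) - len(waveform) + 1`` whose value
    at ``i`` is the zero-mean, unit-norm correlation with
    ``signal[i : i + len(waveform)]``.  Zero-variance windows (or a flat
    waveform) yield 0 there.
    """
    x = np.asarray(channel_signal, dtype=float)
    w = np.asarray(waveform, dtype=float)
    m = w.size
    if x.size < m:
        raise ValueError(f"signal length {x.size} < waveform length {m}")
    wz = w - w.mean()
    w_norm = np.sqrt(np.dot(wz, wz))
    n_out = x.size - m + 1
    if w_norm <= _VAR_EPS:
        return np.zeros(n_out)

    num = sps.fftconvolve(x, wz[::-1], mode="valid")
    csum = np.concatenate(([0.0], np.cumsum(x)))
    csum2 = np.concatenate(([0.0], np.cumsum(x * x)))
    win_sum = csum[m:] - csum[:-m]
    win_sum2 = csum2[m:] - csum2[:-m]
    win_ss = win_sum2 - win_sum**2 / m  # sum of squared deviations per window
    # running sums can go slightly negative for flat stretches
    flat = win_ss <= _VAR_EPS * m
    denom = w_norm * np.sqrt(np.where(flat, 1.0, win_ss))
    trace = np.where(flat, 0.0, num / denom)
    return np.clip(trace, -1.0, 1.0)


def candidate_peaks(trace: np.ndarray, threshold: float, min_distance: int) -> np.ndarray:
    """Local maxima of the trace strictly above ``threshold``.

    Non-maximum suppression keeps at most one peak per ``min_distance``
    samples (the higher-correlation peak wins), so one underlying event
    yields one candidate per template.
    """
    if trace.size == 0:
        return np.array([], dtype=int)
    peaks, _ = sps.find_peaks(trace, distance=max(min_distance, 1))
    peaks = peaks[trace[peaks] > threshold]
    # find_peaks needs strict neighbours; a supra-threshold run at the very
    # edge of the trace would otherwise be lost
    for edge in (0, trace.size - 1):
        if trace[edge] > threshold and (peaks.size == 0 or np.abs(peaks - edge).min() >= min_distance):
            interior = trace[max(0, edge - 1): edge + 2]
            if trace[edge] >= interior.max():
                peaks = np.sort(np.append(peaks, edge))
    return peaks
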