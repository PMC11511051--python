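"""Modality-specific filtering, powerline notch, R-peak detection, delineation.

Filters are zero-phase (forward-backward) 4th-order Butterworth designs so
that wave timing — which the delineator and every HRV metric depend on — is
preserved.  QRS detection follows the two-moving-average, knowledge-based
scheme of Elgendi: band-pass to the QRS energy band, square, compare an
event-scale moving average against a beat-scale moving average plus a
relative offset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .iosig import Modality, Signal

logger = logging.getLogger("bioqc")

__all__ = [
    "PeakSeries",
    "bandpass",
    "notch",
    "detect_r_peaks",
    "delineate_waves",
    "elgendi_qrs_band",
    "DELINEATION_WINDOWS",
]

# Elgendi two-moving-average detector constants (published defaults)
ELGENDI_BAND = (8.0, 20.0)      # Hz, QRS energy band
ELGENDI_W1_S = 0.097            # event (QRS) window
ELGENDI_W2_S = 0.611            # beat window
ELGENDI_BETA = 0.08             # offset fraction of mean squared energy
REFRACTORY_S = 0.25

# Delineation search windows relative to the R peak, in seconds.
DELINEATION_WINDOWS = {
    "Q": (-0.060, -0.008, "min"),
    "S": (0.008, 0.060, "min"),
    "P": (-0.250, -0.080, "max"),
    "T": (0.080, 0.400, "max"),   # right edge further truncated at 55% of NN
}


@dataclass(frozen=True)
class PeakSeries:
    """Detected R peaks: times (s), sample indices, and detector metadata."""

    r_times: np.ndarray
    r_indices: np.ndarray
    detector_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        rt = np.asarray(self.r_times, dtype=float)
        ri = np.asarray(self.r_indices, dtype=int)
        object.__setattr__(self, "r_times", rt)
        object.__setattr__(self, "r_indices", ri)
        if rt.size != ri.size:
            raise ValueError("times and indices must align")
        if rt.size >= 2 and np.min(np.diff(rt)) <= 0:
            raise ValueError("peak times must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.r_times.size)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _check_length(signal: Signal, lo: float) -> None:
    # forward-backward 4th order: require ~3 settling lengths of the slowest pole
    settle = 3.0 / max(lo, 1.0 / signal.duration) if lo > 0 else 0.0
    min_n = max(50, int(settle * signal.fs / 10))
    if signal.n < min_n:
        raise ValueError("record too short to filter")


def bandpass(signal: Signal, lo: float, hi: float) -> Signal:
    """Zero-phase 4th-order Butterworth band-pass (low-pass when lo == 0).

    ``hi`` above 0.45*fs is clipped there with a logged warning (e.g. an
    EMG band of 10-2000 Hz at fs = 1000 Hz becomes 10-450 Hz).
    """
    if not (0 <= lo < hi):
        raise ValueError("need 0 <= lo < hi")
    nyq_cap = 0.45 * signal.fs
    if hi > nyq_cap:
        logger.warning("band upper edge %.6g Hz clipped to %.6g Hz "
                       "(0.45 * fs)", hi, nyq_cap)
        hi = nyq_cap
    if lo >= hi:
        raise ValueError("band collapsed after Nyquist clipping")
    _check_length(signal, lo)
    if lo <= 0:
        sos = sps.butter(4, hi, btype="lowpass", fs=signal.fs, output="sos")
    else:
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=signal.fs,
                         output="sos")
    y = sps.sosfiltfilt(sos, signal.samples)
    return signal.replace_samples(y)


def notch(signal: Signal, f0: float = 60.0, q: float = 30.0) -> Signal:
    """Zero-phase IIR notch at ``f0`` Hz with quality factor ``q``."""
    if f0 >= signal.fs / 2:
        raise ValueError("notch frequency must be below Nyquist")
    b, a = sps.iirnotch(f0, q, fs=signal.fs)
    y = sps.filtfilt(b, a, signal.samples)
    return signal.replace_samples(y)


def elgendi_qrs_band(signal: Signal) -> Signal:
    """The detector's internal QRS-energy band-pass (8-20 Hz, zero-phase)."""
    sos = sps.butter(3, ELGENDI_BAND, btype="bandpass", fs=signal.fs,
                     output="sos")
    return signal.replace_samples(sps.sosfiltfilt(sos, signal.samples))


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(signal: Signal) -> PeakSeries:
    """Two-moving-average knowledge-based QRS detection.

    Pipeline: band-pass 8-20 Hz -> square -> moving averages over an event
    window W1 = 97 ms and a beat window W2 = 611 ms -> blocks where
    MA_event > MA_beat + beta * mean(squared) and block width >= W1 each
    yield one R peak (argmax of the squared energy, earliest sample on
    ties); peaks closer than 250 ms keep the larger energy.

    All thresholds are relative, so detection is invariant to global
    amplitude scaling.
    """
    if signal.duration < 5.0:
        raise ValueError("record too short for QRS detection (need >= 5 s)")
    fs = signal.fs
    filt = elgendi_qrs_band(signal).samples
    energy = filt ** 2
    w1 = max(1, int(round(ELGENDI_W1_S * fs)))
    w2 = max(w1 + 1, int(round(ELGENDI_W2_S * fs)))
    ma_event = uniform_filter1d(energy, w1, mode="nearest")
    ma_beat = uniform_filter1d(energy, w2, mode="nearest")
    offset = ELGENDI_BETA * float(energy.mean())
    active = ma_event > (ma_beat + offset)
    edges = np.flatnonzero(np.diff(active.astype(np.int8)))
    starts = edges[::2] + 1 if active[0] == 0 else np.r_[0, edges[1::2] + 1]
    # recompute block boundaries robustly
    idx = np.flatnonzero(active)
    if idx.size == 0:
        raise ValueError("no QRS detected")
    block_breaks = np.flatnonzero(np.diff(idx) > 1)
    block_starts = np.r_[idx[0], idx[block_breaks + 1]]
    block_ends = np.r_[idx[block_breaks], idx[-1]]
    peaks = []
    for b0, b1 in zip(block_starts, block_ends):
        if (b1 - b0 + 1) < w1:
            continue
        rel = int(np.argmax(energy[b0:b1 + 1]))  # earliest on ties
        peaks.append(b0 + rel)
    if not peaks:
        raise ValueError("no QRS detected")
    # refractory: drop the weaker of any pair closer than 250 ms
    refr = int(round(REFRACTORY_S * fs))
    kept: list[int] = []
    for p in peaks:
        if kept and (p - kept[-1]) < refr:
            if energy[p] > energy[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)
    ri = np.asarray(kept, dtype=int)
    meta = {"band_hz": ELGENDI_BAND, "w1_s": ELGENDI_W1_S,
            "w2_s": ELGENDI_W2_S, "beta": ELGENDI_BETA,
            "offset": offset, "refractory_s": REFRACTORY_S}
    return PeakSeries(signal.t0 + ri / fs, ri, meta)


# ---------------------------------------------------------------------------
# P-QRS-T delineation
# ---------------------------------------------------------------------------

def delineate_waves(signal: Signal, peaks: PeakSeries) -> pd.DataFrame:
    """Windowed extremum search for P, Q, S, T around each detected R peak.

    Returns a DataFrame with one row per beat and columns
    ``{W}_time`` / ``{W}_amp`` for W in P, Q, R, S, T; a wave whose search
    window falls off the record (or is emptied by NN truncation) is marked
    absent with NaN.  Amplitudes are read from the supplied (filtered)
    signal.  Ties in the extremum search resolve to the earliest sample.
    """
    if peaks.n < 1:
        raise ValueError("need at least one R peak")
    fs = signal.fs
    x = signal.samples
    rows = []
    r_ind = peaks.r_indices
    for k, (ri, rt) in enumerate(zip(r_ind, peaks.r_times)):
        row = {"beat": k, "R_time": rt, "R_amp": x[ri]}
        nn_s = None
        if k + 1 < peaks.n:
            nn_s = peaks.r_times[k + 1] - rt
        for wave, (w_lo, w_hi, mode) in DELINEATION_WINDOWS.items():
            lo_s, hi_s = w_lo, w_hi
            if wave == "T" and nn_s is not None:
                hi_s = min(hi_s, 0.55 * nn_s)
            i0 = ri + int(round(lo_s * fs))
            i1 = ri + int(round(hi_s * fs))
            if i0 < 0 or i1 > x.size - 1 or i1 <= i0:
                row[f"{wave}_time"] = np.nan
                row[f"{wave}_amp"] = np.nan
                continue
            seg = x[i0:i1 + 1]
            j = int(np.argmin(seg) if mode == "min" else np.argmax(seg))
            row[f"{wave}_time"] = signal.t0 + (i0 + j) / fs
            row[f"{wave}_amp"] = seg[j]
        rows.append(row)
    df = pd.DataFrame(rows)
    order = ["beat"] + [f"{w}_{f}" for w in ("P", "Q", "R", "S", "T")
                        for f in ("time", "amp")]
    return df[order]
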