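"""EEG spectral analysis: STFT, periodogram PSD, band power, alpha detection.

The PSD is the classical periodogram |X(f)|^2 / N, one-sided, with a Hann
window and window-power compensation by default so that the integral of the
curve matches the time-domain variance (Parseval); ``raw=True`` restores the
literal rectangular-window periodogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .iosig import Signal, slice_signal

__all__ = [
    "Spectrogram",
    "PSDCurve",
    "AlphaVerdict",
    "stft",
    "psd",
    "band_power",
    "band_integral",
    "alpha_detect",
    "pre_post_event_fft",
]


@dataclass(frozen=True)
class Spectrogram:
    """STFT magnitude: ``magnitude[i, j]`` is uV at time ``times[i]``, freq
    ``freqs[j]``."""

    times: np.ndarray
    freqs: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self):
        if self.magnitude.shape != (self.times.size, self.freqs.size):
            raise ValueError("magnitude must be times x freqs")


@dataclass(frozen=True)
class PSDCurve:
    """One-sided power spectral density (uV^2/Hz) on a uniform frequency grid."""

    freqs: np.ndarray
    psd: np.ndarray
    n: int
    meta: dict = field(default_factory=dict)

    def total_power(self) -> float:
        return band_integral(self.freqs, self.psd, self.freqs[0], self.freqs[-1])


@dataclass(frozen=True)
class AlphaVerdict:
    """Alpha-rhythm presence decision for one epoch.

    ``ratio`` compares per-Hz alpha-band power against the mean per-Hz power
    of two flank bands chosen outside the alpha band (and away from slow
    ocular artifacts and the mains region); ``present`` iff the ratio clears
    the configured threshold.  ``alpha_amplitude_range`` is the 5th-95th
    percentile span of the 8-13 Hz analytic envelope, doubled to read as
    peak-to-peak microvolts.
    """

    epoch: tuple
    alpha_power: float
    flank_power: float
    ratio: float
    present: bool
    alpha_amplitude_range: tuple
    evaluable: bool = True


# ---------------------------------------------------------------------------

def stft(signal: Signal, window_len: float = 2.0,
         overlap: float = 0.5) -> Spectrogram:
    """Hann-windowed short-time Fourier transform (magnitude spectrogram).

    Frequency resolution is 1/window_len (0.5 Hz at the 2 s default), which
    resolves the 8-13 Hz alpha band comfortably.
    """
    if signal.duration < 2 * window_len:
        raise ValueError("record shorter than two STFT windows")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    nper = int(round(window_len * signal.fs))
    hop = max(1, int(round(nper * (1 - overlap))))
    win = sps.get_window("hann", nper)
    sft = sps.ShortTimeFFT(win, hop=hop, fs=signal.fs, fft_mode="onesided",
                           scale_to="magnitude")
    # p0/p1 chosen so every window lies fully inside the record
    p0 = int(np.ceil(sft.lower_border_end[1]))
    p1 = int(sft.upper_border_begin(signal.n)[1])
    if p1 <= p0:
        p0, p1 = 0, None
    z = sft.stft(signal.samples, p0=p0, p1=p1)
    mag = np.abs(z).T  # -> times x freqs
    times = signal.t0 + sft.t(signal.n, p0=p0, p1=p1)
    return Spectrogram(times=np.asarray(times), freqs=sft.f.copy(),
                       magnitude=mag)


def psd(signal: Signal, raw: bool = False) -> PSDCurve:
    """Periodogram PSD of the full slice (|X(f)|^2 / N, one-sided).

    By default a Hann window with power compensation controls leakage;
    ``raw=True`` uses the rectangular window (the literal definition).
    """
    if signal.n < 256:
        raise ValueError("need at least 256 samples for a PSD")
    window = "boxcar" if raw else "hann"
    f, p = sps.periodogram(signal.samples, fs=signal.fs, window=window,
                           scaling="density", detrend=False)
    return PSDCurve(freqs=f, psd=p, n=signal.n,
                    meta={"window": window, "scaling": "density",
                          "units": "uV^2/Hz", "fs": signal.fs})


def band_integral(freqs: np.ndarray, values: np.ndarray,
                  lo: float, hi: float) -> float:
    """Trapezoidal integral of a sampled curve over [lo, hi].

    Band edges falling between grid points are linearly interpolated, so
    adjacent bands tile exactly: the integrals over [a,b] and [b,c] sum to
    the integral over [a,c].
    """
    if hi < lo:
        raise ValueError("inverted band")
    if hi == lo:
        return 0.0
    lo = max(lo, float(freqs[0]))
    hi = min(hi, float(freqs[-1]))
    if hi <= lo:
        return 0.0
    inner = (freqs > lo) & (freqs < hi)
    grid = np.concatenate([[lo], freqs[inner], [hi]])
    vals = np.interp(grid, freqs, values)
    return float(np.trapezoid(vals, grid))


def band_power(curve: PSDCurve, lo: float, hi: float) -> float:
    """Power (uV^2) in the band [lo, hi) of a PSD curve."""
    return band_integral(curve.freqs, curve.psd, lo, hi)


# ---------------------------------------------------------------------------
# Alpha-wave presence
# ---------------------------------------------------------------------------

def _alpha_envelope_range(signal: Signal, band: tuple) -> tuple:
    """Peak-to-peak amplitude range of the band-passed analytic envelope."""
    sos = sps.butter(4, band, btype="bandpass", fs=signal.fs, output="sos")
    nb = sps.sosfiltfilt(sos, signal.samples)
    env = np.abs(sps.hilbert(nb))
    lo, hi = np.percentile(env, [5, 95])
    return (2 * float(lo), 2 * float(hi))


def alpha_detect(signal: Signal, epochs: list[tuple],
                 band: tuple = (8.0, 13.0),
                 flanks: tuple = ((4.0, 7.0), (14.0, 17.0)),
                 ratio_threshold: float = 2.0) -> list[AlphaVerdict]:
    """Decide alpha-rhythm presence per epoch.

    For each epoch the PSD is integrated over the alpha band and both flank
    bands; powers are normalised per Hz and alpha is declared present when
    the alpha/flank ratio reaches ``ratio_threshold``.  The decision is
    ratio-based, hence invariant to global amplitude scaling.  Epochs
    shorter than 4 s are returned as not evaluable.
    """
    out = []
    for (a, b) in epochs:
        if b - a < 4.0:
            out.append(AlphaVerdict((a, b), np.nan, np.nan, np.nan, False,
                                    (np.nan, np.nan), evaluable=False))
            continue
        seg = slice_signal(signal, a, b)
        curve = psd(seg)
        a_pow = band_power(curve, *band)
        a_den = a_pow / (band[1] - band[0])
        f_dens = [band_power(curve, lo, hi) / (hi - lo) for lo, hi in flanks]
        f_den = float(np.mean(f_dens))
        ratio = a_den / f_den if f_den > 0 else np.inf
        amp_range = _alpha_envelope_range(seg, band)
        out.append(AlphaVerdict((a, b), a_pow, f_den * (band[1] - band[0]),
                                float(ratio), bool(ratio >= ratio_threshold),
                                amp_range))
    return out


def pre_post_event_fft(signal: Signal, event_time: float,
                       pre_len: float, post_len: float,
                       band: tuple = (8.0, 13.0),
                       flanks: tuple = ((4.0, 7.0), (14.0, 17.0)),
                       ratio_threshold: float = 2.0
                       ) -> tuple[PSDCurve, PSDCurve, AlphaVerdict, AlphaVerdict]:
    """Sliced FFT around a behavioural event (e.g. eye opening).

    Computes the PSD and an alpha verdict on ``[event - pre_len, event)``
    and ``[event, event + post_len)`` separately; contrasting the two curves
    demonstrates the presence and disappearance of the alpha rhythm.
    """
    t0, t1 = event_time - pre_len, event_time + post_len
    if t0 < signal.t0 or t1 > signal.t_end:
        raise ValueError("pre/post slices fall outside the record")
    pre = slice_signal(signal, t0, event_time)
    post = slice_signal(signal, event_time, t1)
    kw = dict(band=band, flanks=flanks, ratio_threshold=ratio_threshold)
    v_pre = alpha_detect(signal, [(t0, event_time)], **kw)[0]
    v_post = alpha_detect(signal, [(event_time, t1)], **kw)[0]
    return psd(pre), psd(post), v_pre, v_post
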