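"""Channel-agnostic comparison metrics: SNR, cross-correlation, EMG bursts.

SNR follows SNR = 10 log10(A_signal^2 / A_noise^2) = 20 log10(A_signal /
A_noise) with A the demeaned RMS of the designated signal and noise epochs.
The cross-correlation coefficient is the literal normalised inner product
rho = sum x_i y_i / sqrt(sum x_i^2 sum y_i^2) — no mean removal, no lag
search; a centered variant is available because correlating spectra or HRV
parameter vectors conventionally removes the mean first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .iosig import Signal, slice_signal

__all__ = [
    "SNRResult",
    "BurstMetrics",
    "snr",
    "xcorr",
    "emg_burst_metrics",
]


@dataclass(frozen=True)
class SNRResult:
    snr_db: float
    a_signal_rms: float
    a_noise_rms: float
    signal_epoch: tuple | None = None
    noise_epoch: tuple | None = None


@dataclass(frozen=True)
class BurstMetrics:
    """Per-grip-epoch amplitude statistics and the force-monotonicity flag."""

    epochs: list            # dicts: interval, force_level, rms_uv, ptp_uv
    monotonic: bool


def _as_array(x) -> np.ndarray:
    if isinstance(x, Signal):
        return x.samples
    return np.asarray(x, dtype=float)


def _demeaned_rms(x: np.ndarray) -> float:
    x = x - x.mean()
    return float(np.sqrt(np.mean(x ** 2)))


def snr(signal_epoch, noise_epoch, signal_interval: tuple | None = None,
        noise_interval: tuple | None = None) -> SNRResult:
    """Signal-to-noise ratio in dB between two epochs (arrays or Signals).

    Each epoch has its mean removed (electrode offset) before the RMS is
    taken.  Raises on a zero-RMS noise epoch.
    """
    a_sig = _demeaned_rms(_as_array(signal_epoch))
    a_noise = _demeaned_rms(_as_array(noise_epoch))
    if a_noise == 0:
        raise ValueError("undefined SNR: noise epoch has zero RMS")
    return SNRResult(snr_db=20.0 * math.log10(a_sig / a_noise),
                     a_signal_rms=a_sig, a_noise_rms=a_noise,
                     signal_epoch=signal_interval, noise_epoch=noise_interval)


def xcorr(x, y, centered: bool = False) -> float:
    """Normalised cross-correlation of two equal-length segments.

    The literal zero-lag formula by default; ``centered=True`` removes each
    segment's mean first (the conventional choice when correlating averaged
    spectra or parameter vectors).  The value lies in [-1, 1]; negative
    values are reported as-is, not clamped.
    """
    xa, ya = _as_array(x), _as_array(y)
    if xa.size != ya.size:
        raise ValueError("segments must have equal length")
    if centered:
        xa, ya = xa - xa.mean(), ya - ya.mean()
    nx, ny = float(np.dot(xa, xa)), float(np.dot(ya, ya))
    if nx == 0 or ny == 0:
        raise ValueError("zero-norm input")
    return float(np.dot(xa, ya) / math.sqrt(nx * ny))


def emg_burst_metrics(signal: Signal,
                      epochs: list[tuple[tuple[float, float], int]],
                      tolerance: float = 0.05) -> BurstMetrics:
    """Amplitude of grip-epoch EMG activity versus force level.

    Per epoch (mean removed): RMS and peak-to-peak in microvolts.  The
    monotonicity flag is true iff RMS strictly increases across ascending
    distinct force levels, where an increase must exceed ``tolerance``
    (5% by default) to count — near-equal RMS at distinct labelled levels
    reads as a monotonicity failure.
    """
    rows = []
    for (a, b), level in epochs:
        if a < signal.t0 or b > signal.t_end:
            raise ValueError(f"epoch [{a}, {b}) outside record")
        seg = slice_signal(signal, a, b).samples
        seg = seg - seg.mean()
        rows.append({"t_start": a, "t_end": b, "force_level": int(level),
                     "rms_uv": float(np.sqrt(np.mean(seg ** 2))),
                     "ptp_uv": float(np.ptp(seg))})
    by_level: dict[int, list[float]] = {}
    for r in rows:
        by_level.setdefault(r["force_level"], []).append(r["rms_uv"])
    levels = sorted(by_level)
    means = [float(np.mean(by_level[L])) for L in levels]
    monotonic = all(hi > lo * (1 + tolerance)
                    for lo, hi in zip(means, means[1:]))
    return BurstMetrics(epochs=rows, monotonic=monotonic)
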