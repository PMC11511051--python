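"""Synthetic biopotential generators with analytic ground truth.

Each generator reproduces the statistical structure the analysis pipeline
assumes — ECG with P/QRS/T morphology riding on an RR process with LF/HF
modulation, force-graded EMG bursts, EEG whose 8-13 Hz alpha rhythm is
present only while the eyes are closed — and returns enough ground truth
(R-peak times, epoch labels, exact noise traces) to compute an independent
oracle value for every downstream metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .iosig import Modality, Signal

__all__ = [
    "NNGenSpec",
    "ECGMorphology",
    "NoiseSpec",
    "NNSeries",
    "generate_nn_series",
    "synthesize_ecg",
    "synthesize_emg",
    "synthesize_eeg",
    "add_noise",
    "DEFAULT_MORPHOLOGY",
]


def _demeaned_rms(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


@dataclass(frozen=True)
class NNSeries:
    """Beat times (s, strictly increasing) and the NN intervals they imply.

    ``nn[k] = (beat_times[k+1] - beat_times[k]) * 1000`` in milliseconds.
    ``valid`` flags intervals that survived artifact/ectopy rejection; the
    generators emit all-valid series.
    """

    beat_times: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self):
        bt = np.asarray(self.beat_times, dtype=float)
        object.__setattr__(self, "beat_times", bt)
        if bt.size < 2:
            raise ValueError("NNSeries needs at least 2 beats")
        if np.any(np.diff(bt) <= 0):
            raise ValueError("beat times must be strictly increasing")
        v = self.valid
        v = np.ones(bt.size - 1, bool) if v is None else np.asarray(v, bool)
        if v.size != bt.size - 1:
            raise ValueError("valid mask must have one entry per interval")
        object.__setattr__(self, "valid", v)

    @property
    def nn(self) -> np.ndarray:
        """All NN intervals in ms (including rejected ones)."""
        return np.diff(self.beat_times) * 1000.0

    @property
    def nn_valid(self) -> np.ndarray:
        return self.nn[self.valid]

    @property
    def nn_times(self) -> np.ndarray:
        """Time of each surviving interval (time of its closing beat)."""
        return self.beat_times[1:][self.valid]

    @property
    def span(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])


@dataclass(frozen=True)
class NNGenSpec:
    """Parameters of the simulated RR (NN-interval) process.

    The NN sequence is a mean level plus two sinusoidal modulations — one
    inside the LF band (0.04-0.15 Hz, sympathetic/baroreflex rhythm) and
    one inside the HF band (0.15-0.4 Hz, respiratory sinus arrhythmia) —
    plus white Gaussian jitter:

        NN_k = mean_nn + a_lf sin(2 pi f_lf t_k) + a_hf sin(2 pi f_hf t_k) + e_k

    with beat times the cumulative sum of the NN values.
    """

    mean_nn: float = 800.0          # ms; 75 bpm resting adult
    lf_mod: tuple = (0.1, 30.0)     # (Hz, ms)
    hf_mod: tuple = (0.25, 20.0)    # (Hz, ms)
    jitter_sd: float = 5.0          # ms
    n_beats: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.mean_nn <= 0:
            raise ValueError("mean_nn must be positive")
        if self.lf_mod[1] < 0 or self.hf_mod[1] < 0 or self.jitter_sd < 0:
            raise ValueError("modulation amplitudes and jitter must be >= 0")
        if self.n_beats < 2:
            raise ValueError("need at least 2 beats")


@dataclass(frozen=True)
class ECGMorphology:
    """Gaussian kernel per wave: (amplitude uV, center offset s from R, width s).

    The defaults give a textbook upright sinus beat: dominant R spike,
    small opposite-sign Q and S, low round P and T.
    """

    p: tuple = (150.0, -0.20, 0.025)
    q: tuple = (-100.0, -0.025, 0.010)
    r: tuple = (1000.0, 0.0, 0.012)
    s: tuple = (-150.0, 0.025, 0.010)
    t: tuple = (300.0, 0.30, 0.060)

    def __post_init__(self):
        if abs(self.r[0]) <= max(abs(self.q[0]), abs(self.s[0])):
            raise ValueError("R amplitude must dominate Q and S")
        for name in ("p", "q", "r", "s", "t"):
            if getattr(self, name)[2] <= 0:
                raise ValueError(f"{name} width must be positive")

    def waves(self):
        return {"P": self.p, "Q": self.q, "R": self.r, "S": self.s, "T": self.t}


DEFAULT_MORPHOLOGY = ECGMorphology()


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: baseline wander + powerline + white Gaussian.

    When ``target_snr_db`` is set, the white component is scaled (the
    structured components stay fixed) so that the total demeaned noise RMS
    hits the target exactly under SNR = 20 log10(A_signal / A_noise).
    """

    baseline: tuple = (0.3, 5.0)    # (Hz <= 0.5, amplitude uV)
    powerline: tuple = (60.0, 5.0)  # (Hz, amplitude uV)
    white_sd: float = 5.0           # uV; ignored when target_snr_db is set
    target_snr_db: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.baseline[0] > 0.5:
            raise ValueError("baseline wander frequency must be <= 0.5 Hz")


# ---------------------------------------------------------------------------
# NN process and ECG
# ---------------------------------------------------------------------------

def generate_nn_series(spec: NNGenSpec) -> NNSeries:
    """Simulate the NN-interval process of :class:`NNGenSpec`.

    Deterministic under a fixed seed.  Raises if any generated NN drops to
    250 ms or below (non-physiologic for sinus rhythm).
    """
    rng = np.random.default_rng(spec.seed)
    f_lf, a_lf = spec.lf_mod
    f_hf, a_hf = spec.hf_mod
    nn = np.empty(spec.n_beats - 1)
    t = 0.0
    for k in range(spec.n_beats - 1):
        val = (spec.mean_nn
               + a_lf * math.sin(2 * math.pi * f_lf * t)
               + a_hf * math.sin(2 * math.pi * f_hf * t)
               + (rng.normal(0.0, spec.jitter_sd) if spec.jitter_sd > 0 else 0.0))
        if val <= 250.0:
            raise ValueError(f"non-physiologic NN: {val:.1f} ms at beat {k}")
        nn[k] = val
        t += val / 1000.0
    beat_times = np.concatenate([[0.0], np.cumsum(nn) / 1000.0])
    return NNSeries(beat_times)


def synthesize_ecg(nn: NNSeries, morph: ECGMorphology = DEFAULT_MORPHOLOGY,
                   fs: float = 1000.0) -> tuple[Signal, np.ndarray]:
    """Render an ECG trace as a sum of Gaussian wave kernels.

    Each beat contributes five Gaussians (P, Q, R, S, T) placed relative to
    its beat time; the returned R times equal the beat times exactly.

    Returns
    -------
    (signal, r_times)
    """
    if fs < 250:
        raise ValueError("undersampled ECG: fs must be >= 250 Hz")
    beat_times = nn.beat_times
    # leave room for the P wave of the first beat and the T wave of the last
    pad = 0.5
    n = int(round((beat_times[-1] + pad) * fs)) + 1
    tgrid = np.arange(n) / fs
    x = np.zeros(n)
    for amp, off, width in ECGMorphology.waves(morph).values():
        if amp == 0:
            continue
        centers = beat_times + off
        # evaluate each kernel only on a +-5 sigma window for speed
        half = int(math.ceil(5 * width * fs))
        for c in centers:
            i0 = max(0, int(round(c * fs)) - half)
            i1 = min(n, int(round(c * fs)) + half + 1)
            if i1 <= i0:
                continue
            dt = tgrid[i0:i1] - c
            x[i0:i1] += amp * np.exp(-0.5 * (dt / width) ** 2)
    sig = Signal(x, fs=fs, modality=Modality.ECG, t0=0.0,
                 channel_label="synthetic-ecg")
    return sig, beat_times.copy()


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------

def _bandlimited_white(n: int, fs: float, lo: float, hi: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS zero-mean noise with an ideal flat band [lo, hi] Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    x -= x.mean()
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def synthesize_emg(epochs: list[tuple[tuple[float, float], int]],
                   duration: float = 30.0, fs: float = 1000.0,
                   seed: int = 0,
                   rms_per_level: float = 50.0,
                   baseline_rms: float = 1.0) -> tuple[Signal, list[dict]]:
    """Force-graded surface-EMG activity bursts.

    ``epochs`` is a list of ``((t_start, t_end), force_level)`` with levels
    in 1..3.  Inside an epoch the trace is 20-450 Hz band-limited noise with
    RMS ``rms_per_level * level`` microvolts; outside, quiescent baseline
    noise of ~1 uV RMS (well under the 2 uV quiescence bound).

    Returns the signal and a ground-truth list of per-epoch dicts.
    """
    iv = sorted(epochs, key=lambda e: e[0][0])
    for (a, b), (c, d) in zip([e[0] for e in iv], [e[0] for e in iv][1:]):
        if c < b:
            raise ValueError("overlapping EMG epochs")
    for (a, b), lvl in iv:
        if not (0 <= a < b <= duration):
            raise ValueError("epoch outside record")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    hi = min(450.0, 0.45 * fs)
    x = _bandlimited_white(n, fs, 20.0, hi, rng) * baseline_rms
    truth = []
    for (a, b), level in iv:
        i0, i1 = int(round(a * fs)), int(round(b * fs))
        target = rms_per_level * level
        burst = _bandlimited_white(i1 - i0, fs, 20.0, hi, rng) * target
        x[i0:i1] = burst
        truth.append({"t_start": a, "t_end": b, "force_level": int(level),
                      "rms_uv": target})
    sig = Signal(x, fs=fs, modality=Modality.EMG, channel_label="synthetic-emg")
    return sig, truth


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def _pink_background(n: int, fs: float, rms: float,
                     rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped background limited to 0.5-45 Hz with the requested RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(f)
    band = (f >= 0.5) & (f <= 45.0)
    shape[band] = 1.0 / np.sqrt(f[band])
    x = np.fft.irfft(spec * shape, n)
    x -= x.mean()
    cur = np.sqrt(np.mean(x ** 2))
    return x * (rms / cur) if cur > 0 else x


def synthesize_eeg(timeline: list[tuple[tuple[float, float], str]],
                   fs: float = 1000.0, seed: int = 0,
                   alpha_freq: float = 10.0,
                   alpha_pp_range: tuple = (10.0, 14.0),
                   background_rms: float = 5.0,
                   artifact_amp: float = 60.0) -> tuple[Signal, list[dict]]:
    """Scalp-EEG emulator driven by a behavioural state timeline.

    ``timeline`` tiles the record with ``((t_start, t_end), state)`` where
    state is one of ``eyes_closed``, ``eyes_open_calm``, ``eyes_open_moving``.
    A 1/f background (0.5-45 Hz) is always present.  ``eyes_closed`` epochs
    add an amplitude-modulated alpha sinusoid (default 10 Hz, inside the
    8-13 Hz band) whose peak-to-peak envelope sweeps ``alpha_pp_range``
    (default within the clinically typical 5-20 uV).  ``eyes_open_moving``
    adds large sub-4 Hz ocular transient artifacts.
    """
    states = {"eyes_closed", "eyes_open_calm", "eyes_open_moving"}
    iv = sorted(timeline, key=lambda e: e[0][0])
    for (a, b), st in iv:
        if st not in states:
            raise ValueError(f"unknown state {st!r}")
        if b <= a:
            raise ValueError("empty state interval")
    for (a, b), (c, d) in zip([e[0] for e in iv], [e[0] for e in iv][1:]):
        if c < b:
            raise ValueError("overlapping EEG state intervals")
    duration = iv[-1][0][1]
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    tgrid = np.arange(n) / fs
    x = _pink_background(n, fs, background_rms, rng)
    truth = []
    pp_lo, pp_hi = alpha_pp_range
    for (a, b), state in iv:
        i0, i1 = int(round(a * fs)), int(round(b * fs))
        seg_t = tgrid[i0:i1]
        if state == "eyes_closed" and pp_hi > 0:
            # peak-to-peak envelope sweeps [pp_lo, pp_hi] at 0.4 Hz
            pp = 0.5 * (pp_lo + pp_hi) + 0.5 * (pp_hi - pp_lo) * np.sin(
                2 * np.pi * 0.4 * (seg_t - a))
            phase = rng.uniform(0, 2 * np.pi)
            x[i0:i1] += (pp / 2.0) * np.sin(2 * np.pi * alpha_freq * seg_t + phase)
        elif state == "eyes_open_moving":
            # a few large slow ocular deflections (< 4 Hz)
            n_art = max(1, int((b - a) / 2.0))
            for _ in range(n_art):
                c = rng.uniform(a + 0.3, b - 0.3)
                w = rng.uniform(0.15, 0.4)  # sigma in s -> energy below ~2 Hz
                x[i0:i1] += artifact_amp * np.exp(-0.5 * ((seg_t - c) / w) ** 2)
        truth.append({"t_start": a, "t_end": b, "state": state,
                      "alpha_pp_uv": [pp_lo, pp_hi] if state == "eyes_closed" else None})
    sig = Signal(x, fs=fs, modality=Modality.EEG, channel_label="synthetic-eeg")
    return sig, truth


# ---------------------------------------------------------------------------
# Noise injection
# ---------------------------------------------------------------------------

def add_noise(signal: Signal, spec: NoiseSpec
              ) -> tuple[Signal, float, np.ndarray]:
    """Inject baseline wander + powerline + white noise into a clean signal.

    With ``target_snr_db`` set, the white component is scaled so that the
    demeaned RMS of the *total* noise trace satisfies
    ``SNR = 20 log10(rms(signal) / rms(noise))`` exactly; the structured
    components are left untouched.  Returns the noisy signal, the achieved
    SNR in dB (``inf`` when the noise is identically zero) and the exact
    noise trace for oracle use.
    """
    rng = np.random.default_rng(spec.seed)
    t = signal.times()
    fixed = (spec.baseline[1] * np.sin(2 * np.pi * spec.baseline[0] * t)
             + spec.powerline[1] * np.sin(2 * np.pi * spec.powerline[0] * t))
    white_unit = rng.standard_normal(signal.n)
    if spec.target_snr_db is None:
        noise = fixed + spec.white_sd * white_unit
    else:
        target_rms = _demeaned_rms(signal.samples) / 10 ** (spec.target_snr_db / 20)
        f = fixed - fixed.mean()
        w = white_unit - white_unit.mean()
        # solve ||f + alpha w||^2 = N * target_rms^2 for alpha >= 0
        a2 = float(np.dot(w, w))
        a1 = 2.0 * float(np.dot(f, w))
        a0 = float(np.dot(f, f)) - signal.n * target_rms ** 2
        if a0 > 0:
            raise ValueError(
                "noise floor exceeds target: structured noise alone is "
                f"louder than the {spec.target_snr_db} dB budget")
        disc = a1 * a1 - 4 * a2 * a0
        alpha = (-a1 + math.sqrt(disc)) / (2 * a2) if a2 > 0 else 0.0
        noise = fixed + alpha * white_unit
    noise_rms = _demeaned_rms(noise)
    if noise_rms == 0:
        achieved = float("inf")
    else:
        achieved = 20 * math.log10(_demeaned_rms(signal.samples) / noise_rms)
    noisy = signal.replace_samples(signal.samples + noise)
    return noisy, achieved, noise
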