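"""Core signal containers, tabular I/O, annotations, configuration, and reports.

All signals are uniformly sampled biopotential traces in microvolts.  Time is
in seconds; sample ``i`` of a signal lives at ``t0 + i / fs`` (0-based).  All
intervals are half-open ``[t_start, t_end)`` so that sliced spectra never
double-count boundary samples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("bioqc")

__all__ = [
    "Modality",
    "Signal",
    "Annotation",
    "PipelineConfig",
    "QualityReport",
    "SignalParseError",
    "SignalFormatError",
    "read_signal",
    "read_annotations",
    "slice_signal",
    "write_report",
    "read_report",
]


class SignalParseError(ValueError):
    """A delimited-text signal file contained rows that could not be parsed."""


class SignalFormatError(ValueError):
    """A signal file was structurally invalid (e.g. non-uniform time stamps)."""


class Modality(str, Enum):
    ECG = "ECG"
    EMG = "EMG"
    EEG = "EEG"
    OTHER = "OTHER"


@dataclass
class Signal:
    """A uniformly sampled biopotential trace.

    Parameters
    ----------
    samples:
        Sample values in microvolts, finite, at least two samples.
    fs:
        Sampling rate in Hz (strictly positive).
    modality:
        One of ECG / EMG / EEG / OTHER; used to pick modality-specific
        filter bands downstream.
    t0:
        Time of the first sample in seconds.
    channel_label:
        Free-text electrode/channel label (metadata only).
    """

    samples: np.ndarray
    fs: float
    modality: Modality = Modality.OTHER
    t0: float = 0.0
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError("signal must contain at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite (no NaN/Inf)")
        if not (self.fs > 0):
            raise ValueError("fs must be > 0")
        self.modality = Modality(self.modality)

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record extent in seconds (time covered by the half-open span)."""
        return self.n / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def replace_samples(self, samples: np.ndarray) -> "Signal":
        """A copy of this signal carrying new sample values (same clock)."""
        return Signal(np.asarray(samples, dtype=float), self.fs, self.modality,
                      self.t0, self.channel_label)


@dataclass(frozen=True)
class Annotation:
    """A labelled event: an interval ``[t_start, t_end)`` or an instant.

    Instants are encoded as ``t_start == t_end``.  Typical labels:
    ``eyes_open_at`` (instant), ``grip_epoch``, ``noise_epoch``.
    """

    label: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not (0 <= self.t_start <= self.t_end):
            raise ValueError("annotation requires 0 <= t_start <= t_end")

    @property
    def is_instant(self) -> bool:
        return self.t_start == self.t_end


@dataclass
class PipelineConfig:
    """Tunable parameters shared across the pipeline.

    Band edges are expressed in Hz and clipped to 0.45*fs at filter time
    (with a logged warning) when a requested edge exceeds the usable range,
    e.g. the 2000 Hz EMG upper edge at a 1000 Hz sampling rate.
    """

    bands: dict = field(default_factory=lambda: {
        "ECG": (0.3, 100.0),
        "EMG": (10.0, 2000.0),
        "EEG": (0.3, 50.0),
    })
    notch_hz: float = 60.0
    notch_q: float = 30.0
    stft_window_s: float = 2.0
    stft_overlap: float = 0.5
    hrv_bands: dict = field(default_factory=lambda: {
        "vlf": (0.0, 0.04),
        "lf": (0.04, 0.15),
        "hf": (0.15, 0.4),
    })
    hrv_resample_hz: float = 4.0
    alpha_band: tuple = (8.0, 13.0)
    alpha_flanks: tuple = ((4.0, 7.0), (14.0, 17.0))
    alpha_ratio_threshold: float = 2.0
    slice_on_out_of_range: str = "error"  # or "clip"
    seed: int = 0

    def validate(self, fs: float) -> None:
        for name, (lo, hi) in {**self.bands, **self.hrv_bands}.items():
            if not (0 <= lo < hi):
                raise ValueError(f"band {name!r}: need 0 <= lo < hi, got {(lo, hi)}")
        if not (0 < self.notch_hz):
            raise ValueError("notch frequency must be positive")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


@dataclass
class QualityReport:
    """Structured run report.

    ``header`` carries provenance (config echo, seed, input files); each
    entry of ``sections`` is a nested key/value tree produced by one analysis
    stage.  Stages that could not run are recorded as
    ``{"not_computed": reason}`` so that a partial run still round-trips.
    """

    header: dict = field(default_factory=dict)
    sections: dict = field(default_factory=dict)

    def add(self, name: str, payload: Mapping) -> None:
        self.sections[name] = _plain(payload)

    def mark_not_computed(self, name: str, reason: str) -> None:
        self.sections[name] = {"not_computed": reason}


def _plain(obj):
    """Recursively convert numpy scalars/arrays to plain Python types."""
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, Enum):
        return obj.value
    return obj


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-delimited numeric table, header optional."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise SignalParseError(f"{path}: empty file")
    # Autodetect delimiter and an optional header row.
    first = text.splitlines()[0]
    sep = "\t" if ("\t" in first and "," not in first) else ","
    try:
        df = pd.read_csv(path, sep=sep, header=None, comment="#",
                         skip_blank_lines=True)
    except Exception as exc:  # malformed CSV structure
        raise SignalParseError(f"{path}: {exc}") from exc
    # Drop a header row of non-numeric labels if present.
    if df.iloc[0].apply(lambda v: not _is_number(v)).any():
        df = df.iloc[1:].reset_index(drop=True)
    return df


def _is_number(v) -> bool:
    try:
        return np.isfinite(float(v))
    except (TypeError, ValueError):
        return False


def _numeric_column(df: pd.DataFrame, col: int, path: Path) -> np.ndarray:
    vals = pd.to_numeric(df.iloc[:, col], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(vals))
    if bad.size:
        # +1 for 1-based line numbering; header rows were already stripped.
        raise SignalParseError(
            f"{path}: non-numeric or non-finite value in column {col} "
            f"at data row {bad[0] + 1}: {df.iloc[bad[0], col]!r}")
    return vals


def read_signal(path: str | Path, fs: float | None = None,
                modality: Modality | str = Modality.OTHER,
                units: str = "uV") -> Signal:
    """Read a delimited-text signal file.

    The file holds either one value column (uniform sampling implied; ``fs``
    is then required) or ``time_s,value`` columns, in which case ``fs`` is
    inferred from the median sample spacing when not given.  Values are
    interpreted as microvolts unless ``units="mV"``, which converts.

    Raises
    ------
    SignalParseError
        On non-numeric rows (the offending row is named).
    SignalFormatError
        When two-column time stamps deviate from uniform spacing by more
        than 1% of the nominal period.
    """
    path = Path(path)
    df = _read_table(path)
    scale = {"uV": 1.0, "mV": 1000.0}[units]
    if df.shape[1] == 1:
        if fs is None:
            raise SignalFormatError(f"{path}: one-column file requires fs")
        values = _numeric_column(df, 0, path) * scale
        return Signal(values, fs=fs, modality=Modality(modality), t0=0.0,
                      channel_label=path.stem)
    t = _numeric_column(df, 0, path)
    values = _numeric_column(df, 1, path) * scale
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise SignalFormatError(f"{path}: time stamps not strictly increasing")
    period = float(np.median(dt))
    if np.max(np.abs(dt - period)) > 0.01 * period:
        raise SignalFormatError(
            f"{path}: non-uniform time stamps (jitter beyond 1% of the "
            f"{period:.6g} s nominal period)")
    fs_inferred = 1.0 / period
    if fs is not None and abs(fs_inferred - fs) > 0.01 * fs:
        raise SignalFormatError(
            f"{path}: time column implies fs={fs_inferred:.6g} Hz, "
            f"declared fs={fs:.6g} Hz")
    return Signal(values, fs=fs if fs is not None else fs_inferred,
                  modality=Modality(modality), t0=float(t[0]),
                  channel_label=path.stem)


def write_signal(signal: Signal, path: str | Path,
                 with_time: bool = True) -> None:
    """Write a signal as ``time_s,value_uV`` (or single-column) CSV."""
    path = Path(path)
    if with_time:
        df = pd.DataFrame({"time_s": signal.times(), "value_uV": signal.samples})
    else:
        df = pd.DataFrame({"value_uV": signal.samples})
    df.to_csv(path, index=False, float_format="%.9g")


def read_annotations(path: str | Path) -> list[Annotation]:
    """Read ``label,t_start,t_end`` rows (header optional)."""
    path = Path(path)
    df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    if df.shape[1] != 3:
        raise SignalParseError(f"{path}: annotation rows need 3 columns")
    if not _is_number(df.iloc[0, 1]):
        df = df.iloc[1:].reset_index(drop=True)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(Annotation(str(row.iloc[0]).strip(),
                                  float(row.iloc[1]), float(row.iloc[2])))
        except (TypeError, ValueError) as exc:
            raise SignalParseError(f"{path}: bad annotation at row {i + 1}: {exc}")
    return out


# ---------------------------------------------------------------------------
# Slicing
# ---------------------------------------------------------------------------

def slice_signal(signal: Signal, t_start: float, t_end: float,
                 clip: bool = False) -> Signal:
    """Extract the half-open sub-signal ``[t_start, t_end)``.

    Sample ``i`` is kept iff ``t_start <= t0 + i/fs < t_end``.  Out-of-range
    intervals raise by default; with ``clip=True`` they are clipped to the
    record extent.
    """
    if t_end <= t_start:
        raise ValueError("empty slice: t_end must exceed t_start")
    if t_start < signal.t0 - 1e-12 or t_end > signal.t_end + 1e-12:
        if clip:
            t_start = max(t_start, signal.t0)
            t_end = min(t_end, signal.t_end)
        else:
            raise ValueError(
                f"slice [{t_start}, {t_end}) outside record "
                f"[{signal.t0}, {signal.t_end})")
    # half-open index range; ceil on the left edge, exclusive right edge
    i0 = int(np.ceil((t_start - signal.t0) * signal.fs - 1e-9))
    i1 = int(np.ceil((t_end - signal.t0) * signal.fs - 1e-9))
    i0 = max(i0, 0)
    i1 = min(i1, signal.n)
    if i1 - i0 < 2:
        raise ValueError("empty slice")
    return Signal(signal.samples[i0:i1].copy(), signal.fs, signal.modality,
                  t0=signal.t0 + i0 / signal.fs,
                  channel_label=signal.channel_label)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(report: QualityReport, path: str | Path) -> None:
    """Emit a machine-readable JSON report plus a human-readable summary.

    The JSON file lands at ``path``; a flat text summary is written next to
    it with a ``.txt`` suffix.  Numbers keep full double precision in the
    JSON (well beyond 6 significant digits).
    """
    path = Path(path)
    payload = {"header": _plain(report.header), "sections": _plain(report.sections)}
    try:
        path.write_text(json.dumps(payload, indent=2))
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
    lines = ["bioqc quality report", "=" * 21]
    for k, v in report.header.items():
        lines.append(f"{k}: {v}")
    for name, section in report.sections.items():
        lines.append("")
        lines.append(f"[{name}]")
        lines.extend(_flat_lines(section, prefix="  "))
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")


def _flat_lines(tree, prefix: str) -> list[str]:
    out = []
    if isinstance(tree, Mapping):
        for k, v in tree.items():
            if isinstance(v, (Mapping, list)):
                out.append(f"{prefix}{k}:")
                out.extend(_flat_lines(v, prefix + "  "))
            else:
                out.append(f"{prefix}{k}: {v}")
    elif isinstance(tree, list):
        for i, v in enumerate(tree):
            if isinstance(v, (Mapping, list)):
                out.append(f"{prefix}- [{i}]")
                out.extend(_flat_lines(v, prefix + "  "))
            else:
                out.append(f"{prefix}- {v}")
    else:
        out.append(f"{prefix}{tree}")
    return out


def read_report(path: str | Path) -> QualityReport:
    """Parse a JSON report back into a :class:`QualityReport`."""
    payload = json.loads(Path(path).read_text())
    return QualityReport(header=payload["header"], sections=payload["sections"])
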