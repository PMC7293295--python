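"""WAV I/O, intensity contours, pause detection/removal and truncation.

The intensity contour is expressed in dB relative to the loudest frame of the
recording (so its maximum is 0 dB).  A pause is a maximal run of frames more
than 25 dB below that reference lasting at least 100 ms — a relative rule, so
every operation in this module is invariant to global gain changes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .errors import AudioFormatError, ParameterError

__all__ = [
    "AudioRecording",
    "IntensityContour",
    "read_wav",
    "write_wav",
    "compute_intensity",
    "detect_pauses",
    "remove_pauses",
    "truncate",
]

#: guard against log(0) in dB computations
LOG_EPS = 1e-10


@dataclass
class AudioRecording:
    """A mono recording with subject/task/state metadata.

    ``samples`` are floats nominally in [-1, 1]; ``sample_rate`` in Hz.
    """

    samples: np.ndarray
    sample_rate: int
    subject_id: str | None = None
    task: str | None = None
    state: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ParameterError("AudioRecording samples must be a 1-D (mono) vector")
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples must be finite")

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.sample_rate


@dataclass
class IntensityContour:
    """Frame-level intensity in dB relative to the loudest frame (max = 0 dB)."""

    frame_times: np.ndarray  # frame start times, seconds
    level_db: np.ndarray
    frame_s: float
    step_s: float

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        self.level_db = np.asarray(self.level_db, dtype=np.float64)
        if self.frame_times.shape != self.level_db.shape:
            raise ParameterError("frame_times and level_db must have equal length")


def read_wav(path: str | Path) -> AudioRecording:
    """Read a PCM WAV file, scaling integer PCM into [-1, 1].

    Stereo input is downmixed to mono by channel averaging (with a warning).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        sr, data = wavfile.read(path)
    except Exception as exc:  # scipy raises bare ValueError on corrupt files
        raise AudioFormatError(f"could not read {path} as PCM WAV: {exc}") from exc
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"unsupported WAV sample format {data.dtype}")
    if samples.ndim == 2:
        warnings.warn(f"{path.name}: stereo input downmixed to mono", stacklevel=2)
        samples = samples.mean(axis=1)
    return AudioRecording(samples=samples, sample_rate=int(sr))


def write_wav(rec: AudioRecording, path: str | Path) -> None:
    """Write a recording as 16-bit PCM WAV."""
    pcm = np.clip(np.round(rec.samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(Path(path), rec.sample_rate, pcm)


def _frame_starts(n_samples: int, sr: int, frame_s: float, step_s: float) -> np.ndarray:
    win = int(round(frame_s * sr))
    hop = int(round(step_s * sr))
    if n_samples < win:
        raise ParameterError(
            f"recording shorter than one frame ({n_samples} samples < {win})"
        )
    n_frames = (n_samples - win) // hop + 1
    return np.arange(n_frames) * hop


def compute_intensity(
    rec: AudioRecording, frame_s: float = 0.032, step_s: float = 0.010
) -> IntensityContour:
    """Per-frame level 10*log10(mean squared amplitude + eps), shifted so the
    loudest frame sits at 0 dB."""
    if not (frame_s >= step_s > 0):
        raise ParameterError("require frame_s >= step_s > 0")
    sr = rec.sample_rate
    win = int(round(frame_s * sr))
    starts = _frame_starts(rec.samples.size, sr, frame_s, step_s)
    hop = int(round(step_s * sr))
    frames = np.lib.stride_tricks.sliding_window_view(rec.samples, win)[::hop]
    frames = frames[: starts.size]
    level = 10.0 * np.log10(np.mean(frames**2, axis=1) + LOG_EPS)
    level -= level.max()
    return IntensityContour(
        frame_times=starts / sr, level_db=level, frame_s=frame_s, step_s=step_s
    )


def detect_pauses(
    contour: IntensityContour,
    threshold_db: float = -25.0,
    min_duration_s: float = 0.100,
) -> list[tuple[float, float]]:
    """Maximal sub-threshold runs spanning at least ``min_duration_s``.

    Returns half-open [start, end) intervals in seconds; a run of frames
    i..j maps to [t_i, t_j + frame_s).
    """
    if contour.level_db.size == 0:
        raise ParameterError("empty intensity contour")
    below = contour.level_db < threshold_db
    pauses: list[tuple[float, float]] = []
    edges = np.flatnonzero(np.diff(np.r_[False, below, False]))
    for lo, hi in zip(edges[::2], edges[1::2]):
        start = contour.frame_times[lo]
        end = contour.frame_times[hi - 1] + contour.frame_s
        if end - start >= min_duration_s:
            pauses.append((float(start), float(end)))
    return pauses


def _validate_intervals(
    intervals: list[tuple[float, float]], duration: float
) -> None:
    prev_end = 0.0
    for start, end in intervals:
        if not (0.0 <= start < end <= duration + 1e-9):
            raise ParameterError(f"interval ({start}, {end}) outside [0, {duration}]")
        if start < prev_end - 1e-9:
            raise ParameterError("pause intervals must be sorted and non-overlapping")
        prev_end = end


def remove_pauses(
    rec: AudioRecording, pauses: list[tuple[float, float]]
) -> AudioRecording:
    """Concatenate the complement of the pause intervals.

    An empty result (pauses covering the whole recording) is returned as an
    empty recording for downstream handling.
    """
    if not pauses:
        return replace(rec, samples=rec.samples.copy())
    _validate_intervals(pauses, rec.duration)
    sr = rec.sample_rate
    keep = np.ones(rec.samples.size, dtype=bool)
    for start, end in pauses:
        keep[int(round(start * sr)) : int(round(end * sr))] = False
    return replace(rec, samples=rec.samples[keep])


def truncate(rec: AudioRecording, max_duration_s: float) -> AudioRecording:
    """First ``max_duration_s`` seconds (whole recording if already shorter)."""
    if max_duration_s <= 0:
        raise ParameterError("max_duration_s must be positive")
    n = int(round(max_duration_s * rec.sample_rate))
    return replace(rec, samples=rec.samples[:n].copy())


def pauses_to_csv(pauses: list[tuple[float, float]], path: str | Path) -> None:
    """Export pause intervals as a 2-column CSV (start_s, end_s)."""
    with open(path, "w") as fh:
        fh.write("start_s,end_s\n")
        for start, end in pauses:
            fh.write(f"{start:.6f},{end:.6f}\n")
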