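"""Syllable-nuclei speech-tempo features.

Syllable nuclei are located as intensity peaks that rise above the silence
threshold (-25 dB relative to the loudest frame) and stand at least
``min_dip_db`` above the intensity dip that follows them.  Inter-nucleus
intervals are summarised twice: as raw gaps ("NS", pauses included) and with
the pause time each gap spans subtracted out ("NSnp").
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema

from .audio import AudioRecording, IntensityContour, compute_intensity, detect_pauses
from .descriptors import PROSODIC_DESCRIPTORS, summarize_distribution
from .errors import ParameterError

__all__ = [
    "NucleusTrack",
    "detect_syllable_nuclei",
    "inter_syllable_intervals",
    "prosodic_feature_vector",
    "PROSODIC_FEATURE_NAMES",
]

PROSODIC_FEATURE_NAMES = tuple(
    f"{prefix} ({d})" for prefix in ("NS", "NSnp") for d in PROSODIC_DESCRIPTORS
)


@dataclass
class NucleusTrack:
    """Ordered syllable-nucleus times with the recording's pause intervals."""

    times: np.ndarray  # seconds, strictly increasing
    duration: float
    pauses: list[tuple[float, float]] = field(default_factory=list)
    step_s: float = 0.010

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.size and (
            np.any(np.diff(self.times) <= 0)
            or self.times[0] < 0
            or self.times[-1] >= self.duration
        ):
            raise ParameterError("nucleus times must be strictly increasing within [0, duration)")


def detect_syllable_nuclei(
    rec: AudioRecording,
    frame_s: float = 0.032,
    step_s: float = 0.010,
    silence_threshold_db: float = -25.0,
    min_dip_db: float = 2.0,
) -> NucleusTrack:
    """Locate syllable nuclei on the intensity contour.

    Candidate peaks are local intensity maxima above the relative silence
    threshold, scanned in time order; a candidate is kept when it rises at
    least ``min_dip_db`` above the minimum level between it and the
    previously kept nucleus (or the start of the recording).  The dip
    requirement merges the ripple maxima on the flanks of one loud syllable
    into a single nucleus.
    """
    if rec.duration < 0.5:
        raise ParameterError("recording must be at least 0.5 s for nucleus detection")
    contour = compute_intensity(rec, frame_s, step_s)
    level = contour.level_db
    peaks = argrelextrema(level, np.greater)[0]
    peaks = peaks[level[peaks] > silence_threshold_db]
    kept: list[int] = []
    for p in peaks:
        prev = kept[-1] if kept else 0
        dip = level[prev : p + 1].min()
        if level[p] - dip >= min_dip_db:
            kept.append(int(p))
    # nucleus time = frame centre of the peak frame
    times = contour.frame_times[np.asarray(kept, dtype=int)] + frame_s / 2.0 if kept else np.empty(0)
    pauses = detect_pauses(contour, silence_threshold_db)
    return NucleusTrack(times=times, duration=rec.duration, pauses=pauses, step_s=step_s)


def inter_syllable_intervals(track: NucleusTrack, variant: str = "with_pauses") -> np.ndarray:
    """Successive inter-nucleus gaps in seconds.

    ``with_pauses``: raw differences.  ``without_pauses``: each gap is reduced
    by the summed pause time it spans; gaps that would vanish are floored at
    one frame step.
    """
    if track.times.size < 2:
        raise ParameterError("need at least 2 nuclei to form intervals")
    gaps = np.diff(track.times)
    if variant == "with_pauses":
        return gaps
    if variant != "without_pauses":
        raise ParameterError(f"unknown variant {variant!r}")
    starts, ends = track.times[:-1], track.times[1:]
    reduced = gaps.copy()
    for p_start, p_end in track.pauses:
        overlap = np.minimum(ends, p_end) - np.maximum(starts, p_start)
        reduced -= np.clip(overlap, 0.0, None)
    return np.maximum(reduced, track.step_s)


def prosodic_feature_vector(rec: AudioRecording, **detect_kwargs) -> dict[str, float]:
    """8 descriptors x {NS, NSnp} = 16 named speech-tempo features.

    Returns an all-NaN vector (with a warning) when fewer than 3 nuclei are
    found, so downstream tables can drop the subject pairwise.
    """
    track = detect_syllable_nuclei(rec, **detect_kwargs)
    if track.times.size < 3:
        warnings.warn(
            f"only {track.times.size} syllable nuclei detected; "
            "prosodic features are missing for this recording",
            stacklevel=2,
        )
        return {name: float("nan") for name in PROSODIC_FEATURE_NAMES}
    out: dict[str, float] = {}
    for prefix, variant in (("NS", "with_pauses"), ("NSnp", "without_pauses")):
        desc = summarize_distribution(inter_syllable_intervals(track, variant))
        for d in PROSODIC_DESCRIPTORS:
            out[f"{prefix} ({d})"] = desc[d]
    return out


def nuclei_to_csv(track: NucleusTrack, path) -> None:
    """Export nucleus times as a 1-column CSV."""
    with open(path, "w") as fh:
        fh.write("time_s\n")
        for t in track.times:
            fh.write(f"{t:.6f}\n")
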