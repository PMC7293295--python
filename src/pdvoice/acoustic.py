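"""Mel-frequency cepstral analysis and the 130-feature acoustic vector.

Thirteen MFCCs are computed on 25 ms frames stepped every 10 ms of the
pause-removed recording; the first coefficient is replaced by the log of the
total frame energy so that overall loudness is carried explicitly.  Each of
the 13 coefficient distributions is then summarised by 10 statistics, giving
130 named features per recording.

The cepstral chain is the textbook one: pre-emphasis, framing, Hamming
window, power spectrum, 26 triangular mel filters up to Nyquist, natural log,
orthonormal DCT-II.  Because a global gain change only shifts the log mel
energies by a constant, coefficients 2..13 are gain-invariant while
coefficient 1 (log energy) shifts by 2*log(gain).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct

from .audio import AudioRecording
from .descriptors import ACOUSTIC_DESCRIPTORS, summarize_distribution
from .errors import ParameterError

__all__ = [
    "MFCCMatrix",
    "mel_filterbank",
    "compute_mfcc",
    "acoustic_feature_vector",
    "ACOUSTIC_FEATURE_NAMES",
]

LOG_EPS = 1e-10

#: deterministic feature naming/order: coefficient-major, then descriptor
ACOUSTIC_FEATURE_NAMES = tuple(
    f"MFCC #{k} ({d})" for k in range(1, 14) for d in ACOUSTIC_DESCRIPTORS
)


@dataclass
class MFCCMatrix:
    """frames x 13 coefficient matrix; column 0 is log total frame energy."""

    coeffs: np.ndarray
    window_s: float
    step_s: float
    sample_rate: int

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64)
        if self.coeffs.ndim != 2 or self.coeffs.shape[0] < 1:
            raise ParameterError("MFCCMatrix needs at least one frame")
        if not np.all(np.isfinite(self.coeffs)):
            raise ParameterError("MFCC coefficients must be finite")


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, nfft: int, sample_rate: int) -> np.ndarray:
    """Triangular mel filters from 0 Hz to Nyquist, (n_filters, nfft//2+1)."""
    mel_pts = np.linspace(0.0, _hz_to_mel(sample_rate / 2.0), n_filters + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bins = np.floor((nfft + 1) * hz_pts / sample_rate).astype(int)
    fbank = np.zeros((n_filters, nfft // 2 + 1))
    for m in range(1, n_filters + 1):
        lo, mid, hi = bins[m - 1], bins[m], bins[m + 1]
        for k in range(lo, mid):
            fbank[m - 1, k] = (k - lo) / max(mid - lo, 1)
        for k in range(mid, hi):
            fbank[m - 1, k] = (hi - k) / max(hi - mid, 1)
    return fbank


def filterbank_centers_hz(n_filters: int, sample_rate: int) -> np.ndarray:
    """Center frequencies of the mel filters in Hz."""
    mel_pts = np.linspace(0.0, _hz_to_mel(sample_rate / 2.0), n_filters + 2)
    return _mel_to_hz(mel_pts)[1:-1]


def log_mel_energies(
    rec: AudioRecording,
    window_s: float = 0.025,
    step_s: float = 0.010,
    n_filters: int = 26,
    preemphasis: float = 0.97,
) -> tuple[np.ndarray, np.ndarray]:
    """(frames x n_filters log mel energies, per-frame log total energy)."""
    sr = rec.sample_rate
    win = int(round(window_s * sr))
    hop = int(round(step_s * sr))
    if rec.samples.size < win:
        raise ParameterError(
            f"recording too short for MFCC analysis: needs at least "
            f"{window_s * 1000:.0f} ms ({win} samples), got {rec.samples.size}"
        )
    emphasized = np.append(rec.samples[0], rec.samples[1:] - preemphasis * rec.samples[:-1])
    n_frames = (emphasized.size - win) // hop + 1
    frames = np.lib.stride_tricks.sliding_window_view(emphasized, win)[::hop][:n_frames]
    log_energy = np.log(np.sum(frames**2, axis=1) + LOG_EPS)
    nfft = 1 << (win - 1).bit_length()
    spectrum = np.fft.rfft(frames * np.hamming(win), n=nfft)
    power = (np.abs(spectrum) ** 2) / nfft
    fbank = mel_filterbank(n_filters, nfft, sr)
    return np.log(power @ fbank.T + LOG_EPS), log_energy


def compute_mfcc(
    rec: AudioRecording,
    window_s: float = 0.025,
    step_s: float = 0.010,
    n_coeff: int = 13,
    n_filters: int = 26,
    preemphasis: float = 0.97,
) -> MFCCMatrix:
    """MFCC matrix of a (pause-removed) recording.

    Frame count is floor((duration - window)/step) + 1.  Coefficient 1 is the
    log total frame energy; coefficients 2..n_coeff are DCT-II of the log mel
    energies.
    """
    log_mel, log_energy = log_mel_energies(rec, window_s, step_s, n_filters, preemphasis)
    ceps = dct(log_mel, type=2, axis=1, norm="ortho")[:, :n_coeff]
    ceps[:, 0] = log_energy
    return MFCCMatrix(coeffs=ceps, window_s=window_s, step_s=step_s, sample_rate=rec.sample_rate)


def acoustic_feature_vector(mfcc: MFCCMatrix) -> dict[str, float]:
    """The 130 named features: 10 descriptors for each of the 13 coefficients."""
    out: dict[str, float] = {}
    for k in range(mfcc.coeffs.shape[1]):
        desc = summarize_distribution(mfcc.coeffs[:, k])
        for d in ACOUSTIC_DESCRIPTORS:
            out[f"MFCC #{k + 1} ({d})"] = desc[d]
    return out
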