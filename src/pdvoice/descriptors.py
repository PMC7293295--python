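"""Distribution descriptors shared by the acoustic, prosodic and semantic features.

Conventions (used identically everywhere):

* percentiles: linear interpolation between order statistics;
* variance: sample variance (ddof=1);
* skewness / kurtosis: Fisher definitions without small-sample bias
  correction; kurtosis is excess kurtosis; both defined as 0 for a
  zero-variance sample;
* mode: midpoint of the most populated histogram bin with Freedman-Diaconis
  bin width, falling back to the median when the IQR is degenerate;
* md: the median (pct50); iqr: pct75 - pct25.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import ParameterError

__all__ = [
    "summarize_distribution",
    "ACOUSTIC_DESCRIPTORS",
    "PROSODIC_DESCRIPTORS",
    "SEMANTIC_DESCRIPTORS",
]

#: the 10 statistics summarising each MFCC coefficient distribution
ACOUSTIC_DESCRIPTORS = (
    "mn", "vn", "kur", "sk", "mod",
    "pct10", "pct25", "pct50", "pct75", "pct90",
)
#: the 8 statistics summarising inter-syllable interval distributions
PROSODIC_DESCRIPTORS = ("pct10", "pct90", "mod", "mn", "vn", "sk", "kur", "iqr")
#: the 6 statistics summarising word-to-seed similarity distributions
SEMANTIC_DESCRIPTORS = ("md", "pct10", "pct90", "sk", "kur", "iqr")


def _mode_fd(values: np.ndarray) -> float:
    """Midpoint of the fullest Freedman-Diaconis histogram bin."""
    q25, q75 = np.percentile(values, [25, 75])
    iqr = q75 - q25
    if iqr <= 0 or values.max() == values.min():
        return float(np.median(values))
    width = 2.0 * iqr * values.size ** (-1.0 / 3.0)
    # cap the bin count: heavy-tailed samples with a tiny IQR would otherwise
    # request an absurd histogram
    n_bins = int(np.clip(np.ceil((values.max() - values.min()) / width), 1, 1024))
    counts, edges = np.histogram(values, bins=n_bins)
    i = int(np.argmax(counts))  # first maximal bin on ties
    return float(0.5 * (edges[i] + edges[i + 1]))


def summarize_distribution(values) -> dict[str, float]:
    """All supported descriptors of a real-valued sample as a name->value dict.

    Requires at least 2 finite values.  Callers pick the subset they need
    (``ACOUSTIC_DESCRIPTORS`` etc.).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ParameterError("summarize_distribution needs at least 2 finite values")
    pct = np.percentile(values, [10, 25, 50, 75, 90])
    var = float(np.var(values, ddof=1))
    # relative degeneracy guard: float residue on identical values must not
    # feed the moment ratios (catastrophic cancellation)
    if np.sqrt(var) <= 1e-9 * max(1.0, float(np.abs(values).max())):
        sk = kur = 0.0
    else:
        sk = float(stats.skew(values, bias=True))
        kur = float(stats.kurtosis(values, fisher=True, bias=True))
    return {
        "mn": float(np.mean(values)),
        "vn": var,
        "kur": kur,
        "sk": sk,
        "mod": _mode_fd(values),
        "pct10": float(pct[0]),
        "pct25": float(pct[1]),
        "pct50": float(pct[2]),
        "pct75": float(pct[3]),
        "pct90": float(pct[4]),
        "md": float(pct[2]),
        "iqr": float(pct[3] - pct[1]),
    }
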