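"""Time-domain (statistical) features: kurtosis, skewness, peak-to-peak
amplitude and the three Hjorth parameters, computed per epoch per channel.

All moments use population (1/T) normalization over the T samples of one
epoch.  The derivative inside the Hjorth parameters is realized as a first
difference; mobility and complexity are ratios, so the sampling-interval
factor cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..exceptions import DegenerateSignalError, DomainError
from ..preprocess import EpochSet

TIME_FEATURE_NAMES = (
    "kurtosis",
    "skewness",
    "ptp_amp",
    "activity",
    "mobility",
    "complexity",
)


@dataclass(frozen=True)
class HjorthTriple:
    """Activity (variance, uV^2), mobility (mean-frequency proxy) and
    complexity (bandwidth proxy; ~1 for a pure sinusoid)."""

    activity: float
    mobility: float
    complexity: float


def _as_clean_1d(x, min_len: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_len:
        raise DomainError(f"{name} needs at least {min_len} samples, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name}: input contains non-finite values")
    return arr


def kurtosis(x) -> float:
    """Population (non-excess) fourth standardized moment; ~3 for Gaussian
    data, 1 for a two-point alternating sequence."""
    arr = _as_clean_1d(x, 4, "kurtosis")
    centred = arr - arr.mean()
    var = np.mean(centred**2)
    if var <= 0:
        raise DegenerateSignalError("kurtosis undefined for zero-variance signal")
    return float(np.mean(centred**4) / var**2)


def skewness(x) -> float:
    """Population third standardized moment."""
    arr = _as_clean_1d(x, 3, "skewness")
    centred = arr - arr.mean()
    var = np.mean(centred**2)
    if var <= 0:
        raise DegenerateSignalError("skewness undefined for zero-variance signal")
    return float(np.mean(centred**3) / var**1.5)


def ptp_amplitude(x) -> float:
    """max(x) - min(x)."""
    arr = _as_clean_1d(x, 1, "ptp_amplitude")
    return float(arr.max() - arr.min())


def hjorth(x) -> HjorthTriple:
    """Hjorth activity/mobility/complexity with first-difference derivative.

    activity = var(x); mobility = sqrt(var(dx)/var(x));
    complexity = mobility(dx)/mobility(x).  A signal whose first difference
    is constant (e.g. a linear ramp) has mobility 0 and, by convention,
    complexity 0 with a warning.
    """
    arr = _as_clean_1d(x, 3, "hjorth")
    var0 = float(np.var(arr))
    if var0 <= 0:
        raise DegenerateSignalError("Hjorth parameters undefined for constant signal")
    d1 = np.diff(arr)
    d2 = np.diff(d1)
    var1 = float(np.var(d1))
    var2 = float(np.var(d2)) if d2.size else 0.0
    mobility = float(np.sqrt(var1 / var0))
    if var1 <= 0:
        warnings.warn(
            "first difference has zero variance; mobility and complexity set to 0",
            stacklevel=2,
        )
        return HjorthTriple(var0, 0.0, 0.0)
    complexity = float(np.sqrt(var2 / var1) / mobility)
    return HjorthTriple(var0, mobility, complexity)


def extract_time_features(epochs: EpochSet) -> pd.DataFrame:
    """One row per epoch, columns ``time__<feature>__<channel>`` (6 features
    per channel).  Degenerate signals yield NaN cells."""
    if epochs.n_epochs == 0:
        raise DomainError("empty EpochSet")
    cols = {
        f"time__{feat}__{ch}": np.full(epochs.n_epochs, np.nan)
        for ch in epochs.channel_names
        for feat in TIME_FEATURE_NAMES
    }
    for e in range(epochs.n_epochs):
        for c, ch in enumerate(epochs.channel_names):
            x = epochs.data[e, c]
            try:
                k = kurtosis(x)
                s = skewness(x)
                hj = hjorth(x)
            except DegenerateSignalError:
                continue
            cols[f"time__kurtosis__{ch}"][e] = k
            cols[f"time__skewness__{ch}"][e] = s
            cols[f"time__ptp_amp__{ch}"][e] = ptp_amplitude(x)
            cols[f"time__activity__{ch}"][e] = hj.activity
            cols[f"time__mobility__{ch}"][e] = hj.mobility
            cols[f"time__complexity__{ch}"][e] = hj.complexity
    # column order: features nested inside channels, channels in montage order
    ordered = [
        f"time__{feat}__{ch}"
        for ch in epochs.channel_names
        for feat in TIME_FEATURE_NAMES
    ]
    return pd.DataFrame(cols, columns=ordered)
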