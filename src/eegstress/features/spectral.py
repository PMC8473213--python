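"""Multitaper power spectral density and relative band power.

The PSD of each 1 s epoch is the equal-weight average of K = 2*NW - 1
direct spectral estimates, each using one discrete prolate spheroidal
(DPSS) taper.  Relative power of a band is its integrated PSD as a
percentage of the total over the six canonical bands (1-30 Hz), so the six
values sum to 100 for every epoch and channel and are invariant to signal
amplitude scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.signal.windows import dpss

from ..bands import BAND_NAMES, BandDefinition, CANONICAL_BANDS
from ..exceptions import DegenerateSignalError, DomainError
from ..preprocess import EpochSet


@dataclass
class SpectralEstimate:
    """One-sided multitaper PSD over a uniform frequency grid.

    ``psd`` integrates (sum * df) to the signal variance; ``tapers`` are the
    K orthonormal DPSS sequences used; ``nw`` is the time-bandwidth
    product, so the normalized half-bandwidth is W = nw / n_samples.
    """

    psd: np.ndarray
    freqs: np.ndarray
    tapers: np.ndarray
    k: int
    nw: float
    dt: float

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    @property
    def w(self) -> float:
        return self.nw / self.tapers.shape[1]


@lru_cache(maxsize=8)
def _dpss_cached(n: int, nw: float, k: int) -> np.ndarray:
    return dpss(n, nw, Kmax=k)  # rows orthonormal (2-norm)


def multitaper_psd(x, fs: float, nw: float = 4.0) -> SpectralEstimate:
    """Multitaper PSD of one epoch-channel sample sequence.

    Applies K = 2*NW - 1 DPSS tapers to the whole epoch, averages the K
    tapered periodograms with equal weight, and returns the one-sided
    estimate on a grid of resolution fs / len(x).
    """
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 8:
        raise DomainError(f"need at least 8 samples, got {arr.size}")
    if nw < 1:
        raise DomainError(f"NW must be >= 1, got {nw}")
    k = int(2 * nw - 1)
    if k < 1 or nw >= arr.size / 2:
        raise DomainError(f"NW={nw} too large for {arr.size} samples")
    try:
        tapers = _dpss_cached(arr.size, float(nw), k)
    except Exception as exc:
        raise DomainError(f"taper computation failed: {exc}") from exc
    n = arr.size
    spectra = np.fft.rfft(tapers * arr[np.newaxis, :], axis=1)
    pk = (np.abs(spectra) ** 2) / fs  # two-sided density per taper
    # fold negative frequencies into the one-sided estimate
    pk[:, 1:] *= 2.0
    if n % 2 == 0:
        pk[:, -1] /= 2.0  # Nyquist bin is not duplicated
    psd = pk.mean(axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return SpectralEstimate(psd=psd, freqs=freqs, tapers=tapers, k=k,
                            nw=float(nw), dt=1.0 / fs)


def band_relative_power(
    est: SpectralEstimate,
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
) -> dict[str, float]:
    """Relative power (percent) per band.

    Bands are integrated on the PSD grid over [low, high); the highest band
    includes its upper edge.  The total is the sum over the given bands
    only, so the percentages sum to 100 exactly.
    """
    f = est.freqs
    lo = min(b.low for b in bands)
    hi = max(b.high for b in bands)
    if f[0] > lo or f[-1] < hi:
        raise DomainError(
            f"PSD grid [{f[0]}, {f[-1]}] does not cover the bands [{lo}, {hi}]"
        )
    top = max(bands, key=lambda b: b.high)
    powers: dict[str, float] = {}
    for band in bands:
        if band is top:
            mask = (f >= band.low) & (f <= band.high)
        else:
            mask = (f >= band.low) & (f < band.high)
        powers[band.name] = float(est.psd[mask].sum() * est.df)
    total = sum(powers.values())
    if total <= 0:
        raise DegenerateSignalError("total band power is zero")
    return {name: 100.0 * p / total for name, p in powers.items()}


def extract_spectral_features(
    epochs: EpochSet,
    nw: float = 4.0,
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
) -> pd.DataFrame:
    """One row per epoch, columns ``freq__relpow_<band>__<channel>``
    (6 bands per channel).  Degenerate spectra yield NaN cells."""
    if epochs.n_epochs == 0:
        raise DomainError("empty EpochSet")
    names = [b.name for b in bands]
    cols = {
        f"freq__relpow_{band}__{ch}": np.full(epochs.n_epochs, np.nan)
        for ch in epochs.channel_names
        for band in names
    }
    for e in range(epochs.n_epochs):
        for c, ch in enumerate(epochs.channel_names):
            try:
                est = multitaper_psd(epochs.data[e, c], epochs.fs, nw=nw)
                rp = band_relative_power(est, bands)
            except DegenerateSignalError:
                continue
            for band in names:
                cols[f"freq__relpow_{band}__{ch}"][e] = rp[band]
    ordered = [
        f"freq__relpow_{band}__{ch}"
        for ch in epochs.channel_names
        for band in names
    ]
    return pd.DataFrame(cols, columns=ordered)
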