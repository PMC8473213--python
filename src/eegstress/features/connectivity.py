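"""Phase-locking-value (PLV) functional-connectivity networks.

For each frequency band the continuous preprocessed record is band-pass
filtered, the instantaneous phase of every channel is taken from the
analytic (Hilbert) signal, and for every unordered channel pair the PLV

    PLV_ij = | (1/T) * sum_t exp(i * (phi_i(t) - phi_j(t))) |

is evaluated over the T samples of each epoch.  PLV lies in [0, 1]
(1 = fixed phase relation, 0 = no synchronization), is symmetric in the
pair, and is invariant to per-channel amplitude scaling.  Band filtering
happens before epoch slicing so 1 s epochs carry no per-epoch filter edge
artifacts; k channels yield k*(k-1)/2 pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from ..bands import BandDefinition, CANONICAL_BANDS
from ..exceptions import DegenerateSignalError, DomainError
from ..preprocess import EEGRecording, EpochSet, bandpass_filter, design_fir_bandpass

logger = logging.getLogger(__name__)


@dataclass
class PhaseSeries:
    """Analytic signal and its instantaneous phase in (-pi, pi]."""

    analytic: np.ndarray
    phase: np.ndarray


def analytic_phase(x_band) -> PhaseSeries:
    """Instantaneous phase of an already band-limited signal via the
    Hilbert-transform analytic signal."""
    arr = np.asarray(x_band, dtype=float).ravel()
    if arr.size < 16:
        raise DomainError(f"need at least 16 samples, got {arr.size}")
    if np.allclose(arr, 0.0):
        raise DegenerateSignalError("all-zero signal has no phase")
    analytic = hilbert(arr)
    return PhaseSeries(analytic=analytic, phase=np.angle(analytic))


def plv_pair(phase_i: np.ndarray | PhaseSeries, phase_j: np.ndarray | PhaseSeries) -> float:
    """PLV of two equal-length phase series."""
    pi_ = phase_i.phase if isinstance(phase_i, PhaseSeries) else np.asarray(phase_i)
    pj_ = phase_j.phase if isinstance(phase_j, PhaseSeries) else np.asarray(phase_j)
    if pi_.shape != pj_.shape:
        raise DomainError(f"phase length mismatch: {pi_.shape} vs {pj_.shape}")
    if pi_.size < 16:
        raise DomainError("need at least 16 samples")
    return float(np.abs(np.exp(1j * (pi_ - pj_)).mean()))


def pair_count(k: int) -> int:
    """Number of unordered channel pairs, k*(k-1)/2."""
    if k < 1:
        raise DomainError(f"channel count must be >= 1, got {k}")
    return k * (k - 1) // 2


def channel_pairs(channel_names) -> list[tuple[str, str]]:
    """Unordered pairs in lexicographic order of channel name."""
    return list(combinations(sorted(channel_names), 2))


def plv_network(
    rec: EEGRecording,
    epochs: EpochSet,
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
    transition: float = 1.0,
) -> pd.DataFrame:
    """Per-epoch PLV feature table over all bands and channel pairs.

    ``rec`` must be the continuous preprocessed recording the epochs were
    cut from; ``epochs.starts`` locates each epoch in it.  Columns are
    ``plv__<band>__<chA>-<chB>`` with pairs in lexicographic order.
    """
    if rec.n_channels < 2:
        raise DomainError("connectivity needs at least 2 channels")
    if not epochs.starts:
        raise DomainError("EpochSet carries no start indices into the recording")
    nyq = rec.fs / 2
    for band in bands:
        if band.high >= nyq:
            raise DomainError(f"band {band.name} exceeds Nyquist {nyq} Hz")
    spe = epochs.samples_per_epoch
    idx = {name: i for i, name in enumerate(rec.channel_names)}
    pairs = channel_pairs(rec.channel_names)
    group_delay = len(design_fir_bandpass(bands[0].low, bands[0].high, rec.fs,
                                          transition)) // 2
    if min(epochs.starts) < group_delay or (
        max(epochs.starts) + spe > rec.n_samples - group_delay
    ):
        logger.warning(
            "epochs lie within one filter group delay (%d samples) of the "
            "record edges; PLV there may carry edge transients", group_delay,
        )
    data: dict[str, np.ndarray] = {}
    for band in bands:
        filtered = bandpass_filter(rec, band.low, band.high, transition=transition)
        phases = np.angle(hilbert(filtered.data, axis=1))
        for a, b in pairs:
            expdiff = np.exp(1j * (phases[idx[a]] - phases[idx[b]]))
            vals = np.empty(epochs.n_epochs)
            for e, start in enumerate(epochs.starts):
                vals[e] = np.abs(expdiff[start : start + spe].mean())
            data[f"plv__{band.name}__{a}-{b}"] = vals
    return pd.DataFrame(data)


def mean_plv_matrix(
    table: pd.DataFrame, band: str, channel_names, epochs_mask=None
) -> np.ndarray:
    """Symmetric k x k matrix of epoch-averaged PLV for one band
    (diagonal 1), assembled from a ``plv_network`` feature table."""
    names = list(channel_names)
    k = len(names)
    mat = np.eye(k)
    for a, b in channel_pairs(names):
        col = f"plv__{band}__{a}-{b}"
        if col not in table.columns:
            raise DomainError(f"missing column {col}")
        vals = table[col] if epochs_mask is None else table.loc[epochs_mask, col]
        v = float(vals.mean())
        ia, ib = names.index(a), names.index(b)
        mat[ia, ib] = mat[ib, ia] = v
    return mat


def write_plv_matrix(
    path: str | Path, matrix: np.ndarray, channel_names
) -> Path:
    """Plain-text symmetric matrix with a channel-name header row/column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = list(channel_names)
    lines = ["\t".join(["channel"] + names)]
    for i, name in enumerate(names):
        lines.append("\t".join([name] + [f"{matrix[i, j]:.4f}" for j in range(len(names))]))
    path.write_text("\n".join(lines) + "\n")
    return path
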