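"""Recording I/O and the preprocessing chain.

The chain is: zero-phase FIR band-pass (1-35 Hz) -> average re-reference ->
optional ICA-style artifact suppression -> segmentation into baseline-
corrected 1 s epochs with amplitude-based rejection.  The 1-35 Hz band-pass
already removes 50/60 Hz mains pickup, so no separate notch is applied.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve, firwin, welch

from .exceptions import ConfigurationError, DomainError, ParseError

logger = logging.getLogger(__name__)


@dataclass
class EEGRecording:
    """Continuous multi-channel EEG: channels x samples matrix in uV."""

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConfigurationError("recording data must be channels x samples")
        if self.data.shape[0] != len(self.channel_names):
            raise ConfigurationError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        if self.fs <= 0:
            raise ConfigurationError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ConfigurationError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        return EEGRecording(data, self.fs, self.channel_names)


@dataclass
class EpochSet:
    """Epochs x channels x samples array with per-epoch condition labels.

    ``starts`` records each surviving epoch's first-sample index in the
    source recording so connectivity extraction can slice phase series from
    the continuous record consistently with any epoch rejection.
    """

    data: np.ndarray
    fs: float
    epoch_ms: float
    labels: tuple[str, ...]
    channel_names: tuple[str, ...]
    starts: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ConfigurationError("epoch data must be epochs x channels x samples")
        expected = int(round(self.fs * self.epoch_ms / 1000.0))
        if self.data.shape[2] != expected:
            raise ConfigurationError(
                f"samples per epoch {self.data.shape[2]} != fs*duration {expected}"
            )
        if len(self.labels) != self.data.shape[0]:
            raise ConfigurationError("one label per epoch required")
        if self.starts and len(self.starts) != self.data.shape[0]:
            raise ConfigurationError("one start index per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def samples_per_epoch(self) -> int:
        return self.data.shape[2]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_recording(
    path: str | Path, format: str | None = None, fs: float = 256.0
) -> EEGRecording:
    """Read a recording from CSV (generator dialect: header of channel
    names, one row per sample) or EDF.

    CSV carries no sampling rate, so ``fs`` must be supplied (default 256
    Hz); for EDF the rate and channel names come from the file header.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "csv":
        import pandas as pd

        try:
            df = pd.read_csv(path)
        except Exception as exc:  # malformed file
            raise ParseError(f"could not parse CSV {path}: {exc}") from exc
        if df.shape[1] < 2:
            raise ParseError(f"{path}: need at least 2 channels, got {df.shape[1]}")
        if df.isna().any().any():
            raise ParseError(f"{path}: missing values / ragged rows")
        return EEGRecording(df.to_numpy().T, fs, tuple(df.columns))
    if format == "edf":
        import mne

        try:
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        except Exception as exc:
            raise ParseError(f"could not parse EDF {path}: {exc}") from exc
        data_uv = raw.get_data() * 1e6  # MNE returns Volts
        return EEGRecording(data_uv, float(raw.info["sfreq"]), tuple(raw.ch_names))
    raise ParseError(f"unknown format {format!r} (expected 'csv' or 'edf')")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def design_fir_bandpass(
    low: float, high: float, fs: float, transition: float = 1.0
) -> np.ndarray:
    """Windowed-sinc (Hamming) linear-phase band-pass taps.

    Order follows the standard Hamming transition-width rule
    N ~ 3.3 fs / transition; Hamming gives ~53 dB stop-band attenuation and
    ~0.02 dB pass-band ripple.
    """
    if not 0 < low < high < fs / 2:
        raise DomainError(
            f"band [{low}, {high}] must satisfy 0 < low < high < fs/2 = {fs / 2}"
        )
    numtaps = int(np.ceil(3.3 * fs / transition))
    if numtaps % 2 == 0:
        numtaps += 1
    return firwin(numtaps, [low, high], pass_zero=False, fs=fs, window="hamming")


def _zero_phase_filter(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR with zero phase via centred convolution.

    Edges are odd-reflection padded (as scipy's filtfilt does) to suppress
    boundary transients, then cropped back to the input length.
    """
    half = len(taps) // 2
    pad = min(half, data.shape[-1] - 1)
    left = 2 * data[..., :1] - data[..., pad:0:-1]
    right = 2 * data[..., -1:] - data[..., -2 : -pad - 2 : -1]
    padded = np.concatenate([left, data, right], axis=-1)
    out = fftconvolve(padded, taps[np.newaxis, :], mode="same", axes=-1)
    return out[..., pad : pad + data.shape[-1]]


def bandpass_filter(
    rec: EEGRecording, low: float = 1.0, high: float = 35.0, transition: float = 1.0
) -> EEGRecording:
    """Zero-phase FIR band-pass of every channel."""
    taps = design_fir_bandpass(low, high, rec.fs, transition)
    return rec.copy_with(_zero_phase_filter(rec.data, taps))


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous mean over channels from every channel."""
    if rec.n_channels < 2:
        raise DomainError("average reference needs at least 2 channels")
    return rec.copy_with(rec.data - rec.data.mean(axis=0, keepdims=True))


# ---------------------------------------------------------------------------
# ICA-style artifact suppression
# ---------------------------------------------------------------------------


def ica_artifact_removal(
    rec: EEGRecording,
    enabled: bool = True,
    low_cut: float = 4.0,
    high_cut: float = 30.0,
    power_fraction: float = 0.6,
    random_state: int = 0,
) -> EEGRecording:
    """Decompose the continuous record with FastICA and zero components
    dominated by ocular (< ``low_cut`` Hz) or myogenic (> ``high_cut`` Hz)
    power.

    A component is suppressed when more than ``power_fraction`` of its
    Welch-spectrum power lies in the artifact range.  Non-convergence falls
    back to the identity with a logged warning.  ``enabled=False`` is the
    identity.
    """
    if not enabled:
        return rec.copy_with(rec.data.copy())
    if rec.n_channels < 2:
        raise DomainError("ICA needs at least 2 channels")
    if rec.n_samples <= rec.n_channels:
        raise DomainError("ICA needs more samples than channels")
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    # average-referenced data is rank-deficient (channel mean is zero);
    # whitening with a full component set then breaks the reconstruction
    cov = (rec.data @ rec.data.T) / rec.n_samples
    rank = int(np.linalg.matrix_rank(cov, hermitian=True))
    ica = FastICA(
        n_components=min(rec.n_channels, rank),
        whiten="unit-variance",
        max_iter=2000,
        tol=1e-3,
        random_state=random_state,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        try:
            sources = ica.fit_transform(rec.data.T)  # samples x components
        except Exception as exc:
            logger.warning("FastICA failed (%s); returning input unchanged", exc)
            return rec.copy_with(rec.data.copy())
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            logger.warning("FastICA did not converge; returning input unchanged")
            return rec.copy_with(rec.data.copy())

    nper = min(rec.n_samples, int(4 * rec.fs))
    drop: list[int] = []
    for k in range(sources.shape[1]):
        f, pxx = welch(sources[:, k], fs=rec.fs, nperseg=nper)
        total = pxx.sum()
        if total <= 0:
            continue
        frac_low = pxx[f < low_cut].sum() / total
        frac_high = pxx[f > high_cut].sum() / total
        if frac_low > power_fraction or frac_high > power_fraction:
            drop.append(k)
    if drop:
        logger.info("ICA suppressing %d/%d components: %s", len(drop),
                    sources.shape[1], drop)
        sources[:, drop] = 0.0
    cleaned = ica.inverse_transform(sources).T
    return rec.copy_with(cleaned)


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------


def segment_epochs(
    rec: EEGRecording,
    windows: Sequence[tuple[str, float, float]],
    epoch_ms: float = 1000.0,
    reject_ptp_uv: float | None = 100.0,
) -> EpochSet:
    """Cut labelled condition windows into contiguous non-overlapping
    epochs, baseline-correct each epoch over its full length, and drop
    epochs whose peak-to-peak amplitude on any channel exceeds
    ``reject_ptp_uv`` (an automated stand-in for visual artifact checks).
    """
    spe = epoch_ms * rec.fs / 1000.0
    if abs(spe - round(spe)) > 1e-9:
        raise DomainError(
            f"epoch_ms={epoch_ms} at fs={rec.fs} is not an integer sample count"
        )
    spe = int(round(spe))
    epochs: list[np.ndarray] = []
    labels: list[str] = []
    starts: list[int] = []
    n_rejected = 0
    for cond, start_s, end_s in windows:
        if start_s < -1e-9 or end_s > rec.duration_s + 1e-6:
            raise DomainError(
                f"window [{start_s}, {end_s}] outside recording of "
                f"{rec.duration_s:.3f} s"
            )
        n_ep = int(np.floor((end_s - start_s) * rec.fs + 1e-9)) // spe
        if n_ep == 0:
            logger.warning(
                "window (%s, %.1f-%.1f s) shorter than one epoch; skipped",
                cond, start_s, end_s,
            )
            continue
        i0 = int(round(start_s * rec.fs))
        for k in range(n_ep):
            seg = rec.data[:, i0 + k * spe : i0 + (k + 1) * spe]
            seg = seg - seg.mean(axis=1, keepdims=True)  # full-epoch baseline
            if reject_ptp_uv is not None:
                ptp = (seg.max(axis=1) - seg.min(axis=1)).max()
                if ptp > reject_ptp_uv:
                    n_rejected += 1
                    continue
            epochs.append(seg)
            labels.append(cond)
            starts.append(i0 + k * spe)
    if n_rejected:
        logger.info("rejected %d epochs above %.1f uV peak-to-peak",
                    n_rejected, reject_ptp_uv)
    if not epochs:
        raise DomainError("no epochs survived segmentation")
    return EpochSet(
        np.stack(epochs), rec.fs, epoch_ms, tuple(labels),
        rec.channel_names, tuple(starts),
    )


def preprocess_recording(
    rec: EEGRecording,
    windows: Sequence[tuple[str, float, float]],
    low: float = 1.0,
    high: float = 35.0,
    ica: bool = False,
    epoch_ms: float = 1000.0,
    reject_ptp_uv: float | None = 100.0,
    random_state: int = 0,
) -> tuple[EEGRecording, EpochSet]:
    """Full chain: filter -> average reference -> (ICA) -> epochs.

    Returns the cleaned continuous recording (needed for band-wise
    connectivity extraction) together with the epoch set.
    """
    filtered = bandpass_filter(rec, low=low, high=high)
    referenced = average_reference(filtered)
    cleaned = ica_artifact_removal(referenced, enabled=ica, random_state=random_state)
    return cleaned, segment_epochs(cleaned, windows, epoch_ms, reject_ptp_uv)


def select_condition_windows(
    windows: Sequence[tuple[str, float, float]],
    rest_s: float = 20.0,
    stress_s: float = 20.0,
) -> list[tuple[str, float, float]]:
    """Pick the analysis windows from a full block schedule: the first
    ``rest_s`` seconds of the first rest block and the first ``stress_s``
    seconds of the last task block."""
    rests = [w for w in windows if w[0] == "rest"]
    tasks = [w for w in windows if w[0] == "stress"]
    if not rests or not tasks:
        raise DomainError("schedule must contain both rest and stress windows")
    r = rests[0]
    s = tasks[-1]
    if r[2] - r[1] < rest_s or s[2] - s[1] < stress_s:
        raise DomainError("selected blocks shorter than the requested windows")
    return [("rest", r[1], r[1] + rest_s), ("stress", s[1], s[1] + stress_s)]


# ---------------------------------------------------------------------------
# EpochSet persistence (flat numeric container + JSON sidecar)
# ---------------------------------------------------------------------------


def write_epochs(epochs: EpochSet, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.csv`` (epochs*channels rows of samples) and
    ``<prefix>.json`` (shape, fs, channels, labels, starts)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_suffix(".csv")
    flat = epochs.data.reshape(-1, epochs.samples_per_epoch)
    np.savetxt(csv_path, flat, delimiter=",", fmt="%.6f")
    meta = {
        "n_epochs": epochs.n_epochs,
        "n_channels": epochs.n_channels,
        "samples_per_epoch": epochs.samples_per_epoch,
        "fs": epochs.fs,
        "epoch_ms": epochs.epoch_ms,
        "channel_names": list(epochs.channel_names),
        "labels": list(epochs.labels),
        "starts": list(epochs.starts),
    }
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return csv_path, json_path


def read_epochs(prefix: str | Path) -> EpochSet:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    flat = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",")
    data = flat.reshape(
        meta["n_epochs"], meta["n_channels"], meta["samples_per_epoch"]
    )
    return EpochSet(
        data, meta["fs"], meta["epoch_ms"], tuple(meta["labels"]),
        tuple(meta["channel_names"]), tuple(meta["starts"]),
    )
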