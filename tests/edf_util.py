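"""Minimal synthetic EDF writer for exercising the EDF *reader*.

This is a test-only helper that emits a tiny, hand-assembled EDF file
(synthetic data, not derived from any recording system) so the mne-based
reader path can be tested without binary fixtures in the repository.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

PHYS_MIN, PHYS_MAX = -1000.0, 1000.0
DIG_MIN, DIG_MAX = -32768, 32767


def _pad(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    assert len(b) <= width, value
    return b + b" " * (width - len(b))


def write_minimal_edf(path: str | Path, data_uv: np.ndarray, fs: int,
                      channel_names=None) -> Path:
    """Write channels x samples (uV) as EDF with 1 s data records."""
    path = Path(path)
    n_ch, n_samp = data_uv.shape
    assert n_samp % fs == 0, "whole seconds only"
    n_records = n_samp // fs
    if channel_names is None:
        channel_names = [f"EEG{i}" for i in range(n_ch)]

    header = b""
    header += _pad("0", 8)
    header += _pad("X X X X", 80)          # patient
    header += _pad("Startdate X X X X", 80)  # recording
    header += _pad("01.01.01", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(256 * (n_ch + 1)), 8)
    header += _pad("", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)                  # record duration (s)
    header += _pad(str(n_ch), 4)
    for name in channel_names:
        header += _pad(name, 16)
    header += _pad("", 80) * n_ch            # transducer
    header += _pad("uV", 8) * n_ch
    header += _pad(str(PHYS_MIN), 8) * n_ch
    header += _pad(str(PHYS_MAX), 8) * n_ch
    header += _pad(str(DIG_MIN), 8) * n_ch
    header += _pad(str(DIG_MAX), 8) * n_ch
    header += _pad("", 80) * n_ch            # prefiltering
    header += _pad(str(fs), 8) * n_ch
    header += _pad("", 32) * n_ch

    scale = (DIG_MAX - DIG_MIN) / (PHYS_MAX - PHYS_MIN)
    digital = np.clip(
        np.round((data_uv - PHYS_MIN) * scale + DIG_MIN), DIG_MIN, DIG_MAX
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for ch in range(n_ch):
                fh.write(digital[ch, r * fs : (r + 1) * fs].tobytes())
    return path
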