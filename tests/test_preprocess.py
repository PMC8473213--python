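"""Preprocessing chain: I/O, filtering, re-referencing, artifact
suppression and epoching."""

import numpy as np
import pytest

import eegstress as es
from eegstress.exceptions import DomainError, ParseError
from eegstress.preprocess import (
    ica_artifact_removal,
    preprocess_recording,
    read_epochs,
    select_condition_windows,
    write_epochs,
)

from edf_util import write_minimal_edf

FS = 256.0


def make_rec(data, channels=None, fs=FS):
    data = np.atleast_2d(data)
    if channels is None:
        channels = tuple(f"C{i}" for i in range(data.shape[0]))
    return es.EEGRecording(data, fs, channels)


def band_power(x, fs, lo, hi):
    from scipy.signal import welch

    f, p = welch(x, fs=fs, nperseg=min(len(x), 1024))
    return p[(f >= lo) & (f <= hi)].sum()


class TestIO:
    def test_csv_shape_passthrough(self, tmp_path):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((7, 1000))
        rec = make_rec(data)
        es.simulate.write_session_csv(
            es.simulate.SubjectRecord(
                "S00", data, FS, rec.channel_names, [("rest", 0, 1000 / FS)],
                es.AmylaseSample(20.0, "baseline"), es.AmylaseSample(90.0, "post"),
                "stress", 0,
            ),
            tmp_path / "x.csv",
        )
        back = es.read_recording(tmp_path / "x.csv", fs=FS)
        assert back.data.shape == (7, 1000)
        assert np.allclose(back.data, data, atol=1e-5)

    def test_malformed_csv_rejected(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("a,b\n1,2\n3\n")
        with pytest.raises(ParseError):
            es.read_recording(bad, fs=FS)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(ParseError):
            es.read_recording(tmp_path / "nope.csv")

    def test_edf_header_drives_sampling_rate(self, tmp_path):
        """EDF at a non-default rate: fs and channel names come from the
        file header, and the samples survive the 16-bit round trip."""
        fs = 128
        t = np.arange(4 * fs) / fs
        data = np.vstack([40 * np.sin(2 * np.pi * 5 * t),
                          20 * np.cos(2 * np.pi * 9 * t)])
        path = write_minimal_edf(tmp_path / "mini.edf", data, fs,
                                 ["Fp1", "Fp2"])
        rec = es.read_recording(path)
        assert rec.fs == pytest.approx(128.0)
        assert rec.data.shape == (2, 4 * fs)
        assert list(rec.channel_names) == ["Fp1", "Fp2"]
        # 16-bit quantization at +-1000 uV range: ~0.03 uV steps
        assert np.allclose(rec.data, data, atol=0.1)


class TestBandpass:
    # the first/last half-kernel (~1.65 s) carries the edge transient of
    # any finite-length filtering; attenuation is measured in steady state
    STEADY = slice(int(4 * FS), -int(4 * FS))

    def test_stopband_50hz_attenuated(self):
        t = np.arange(int(16 * FS)) / FS
        x = np.sin(2 * np.pi * 50 * t)
        out = es.bandpass_filter(make_rec(np.vstack([x, x]))).data[0]
        ratio = np.sqrt((out[self.STEADY] ** 2).mean()) / np.sqrt(
            (x[self.STEADY] ** 2).mean()
        )
        assert ratio < 0.01

    def test_passband_10hz_preserved(self):
        t = np.arange(int(16 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t)
        out = es.bandpass_filter(make_rec(np.vstack([x, x]))).data[0]
        ratio = np.sqrt((out[self.STEADY] ** 2).mean()) / np.sqrt(
            (x[self.STEADY] ** 2).mean()
        )
        assert abs(ratio - 1) < 0.1

    def test_zero_in_zero_out(self):
        out = es.bandpass_filter(make_rec(np.zeros((2, 2048)))).data
        assert np.allclose(out, 0.0)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(DomainError):
            es.bandpass_filter(make_rec(np.zeros((2, 2048))), low=1, high=200)


class TestAverageReference:
    def test_channel_mean_vanishes(self, rng):
        rec = make_rec(rng.standard_normal((7, 512)))
        out = es.average_reference(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9

    def test_identical_channels_cancel(self):
        rec = make_rec(np.tile(np.sin(np.arange(512) / 10), (3, 1)))
        assert np.allclose(es.average_reference(rec).data, 0.0)

    def test_constant_channels_hand_computed(self):
        rec = make_rec(np.array([[1.0], [2.0], [3.0]]) * np.ones((3, 16)))
        out = es.average_reference(rec).data
        assert np.allclose(out[:, 0], [-1.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        rec = make_rec(rng.standard_normal((5, 256)))
        once = es.average_reference(rec)
        twice = es.average_reference(once)
        assert np.allclose(once.data, twice.data)

    def test_single_channel_rejected(self):
        with pytest.raises(DomainError):
            es.average_reference(make_rec(np.zeros((1, 256))))


def _blinky_recording(with_blinks: bool, seed: int = 0):
    """Alpha-dominant 7-channel fixture, optionally with strong 0.5 s
    blink bumps on Fp1/Fp2 (low delta so clean rhythms are preserved)."""
    amps = {
        "delta": 1.0, "theta": 2.0, "alpha": 8.0,
        "sigma": 2.0, "low_beta": 2.0, "high_beta": 1.5,
    }
    cfg = es.SynthConfig(
        n_subjects=1,
        seed=seed,
        band_amplitudes={"rest": amps, "stress": amps},
        blink_rate_per_min=20.0 if with_blinks else 0.0,
        blink_amplitude=150.0,
        noise_scale=2.0,
        line_noise_amplitude=0.0,
    )
    rec = es.generate_session(cfg, 0)
    raw = es.EEGRecording(rec.data, rec.fs, rec.channel_names)
    return es.average_reference(es.bandpass_filter(raw))


class TestICA:
    def test_disabled_is_identity(self, rng):
        rec = make_rec(rng.standard_normal((4, 2048)))
        out = ica_artifact_removal(rec, enabled=False)
        assert np.array_equal(out.data, rec.data)

    def test_blink_band_power_reduced(self):
        rec = _blinky_recording(with_blinks=True)
        cleaned = ica_artifact_removal(rec, enabled=True, random_state=0)
        i = rec.channel_names.index("Fp1")
        before = band_power(rec.data[i], rec.fs, 0.5, 3.0)
        after = band_power(cleaned.data[i], rec.fs, 0.5, 3.0)
        assert after < 0.5 * before

    def test_blink_free_recording_barely_changed(self):
        rec = _blinky_recording(with_blinks=False)
        cleaned = ica_artifact_removal(rec, enabled=True, random_state=0)
        p0 = (rec.data**2).mean(axis=1)
        p1 = (cleaned.data**2).mean(axis=1)
        assert np.abs(p1 / p0 - 1).max() <= 0.10


class TestEpoching:
    def test_default_layout_40x7x256(self, rng):
        rec = make_rec(rng.standard_normal((7, int(40 * FS))))
        windows = [("rest", 0.0, 20.0), ("stress", 20.0, 40.0)]
        epochs = es.segment_epochs(rec, windows, reject_ptp_uv=None)
        assert epochs.data.shape == (40, 7, 256)
        assert epochs.labels.count("rest") == 20
        assert epochs.labels.count("stress") == 20

    def test_baseline_removed_per_epoch_channel(self, rng):
        rec = make_rec(5.0 + rng.standard_normal((3, int(10 * FS))))
        epochs = es.segment_epochs(rec, [("rest", 0.0, 10.0)], reject_ptp_uv=None)
        assert np.abs(epochs.data.mean(axis=2)).max() < 1e-9

    def test_spiked_epoch_rejected(self, rng):
        data = rng.standard_normal((3, int(10 * FS)))
        data[1, 3 * 256 + 10] = 1000.0  # single epoch blown out
        rec = make_rec(data)
        epochs = es.segment_epochs(rec, [("rest", 0.0, 10.0)], reject_ptp_uv=100.0)
        assert epochs.n_epochs == 9
        assert 3 * 256 not in epochs.starts

    def test_short_window_contributes_nothing(self, rng):
        rec = make_rec(rng.standard_normal((2, int(2 * FS))))
        epochs = es.segment_epochs(
            rec, [("rest", 0.0, 1.0), ("stress", 1.0, 1.5)], reject_ptp_uv=None
        )
        assert epochs.n_epochs == 1

    def test_window_outside_recording_rejected(self, rng):
        rec = make_rec(rng.standard_normal((2, 256)))
        with pytest.raises(DomainError):
            es.segment_epochs(rec, [("rest", 0.0, 5.0)])

    def test_epoch_persistence_round_trip(self, rng, tmp_path):
        rec = make_rec(rng.standard_normal((3, int(4 * FS))))
        epochs = es.segment_epochs(
            rec, [("rest", 0.0, 2.0), ("stress", 2.0, 4.0)], reject_ptp_uv=None
        )
        write_epochs(epochs, tmp_path / "ep")
        back = read_epochs(tmp_path / "ep")
        assert back.labels == epochs.labels
        assert back.starts == epochs.starts
        assert np.allclose(back.data, epochs.data, atol=1e-5)


class TestChain:
    def test_window_selection_first_rest_last_task(self):
        windows = es.SynthConfig().condition_windows()
        sel = select_condition_windows(windows)
        assert sel == [("rest", 30.0, 50.0), ("stress", 200.0, 220.0)]

    def test_full_chain_yields_balanced_epochs(self):
        cfg = es.SynthConfig(n_subjects=1, seed=2)
        record = es.generate_session(cfg, 0)
        rec = es.EEGRecording(record.data, record.fs, record.channel_names)
        _, epochs = preprocess_recording(
            rec, select_condition_windows(record.condition_windows)
        )
        assert epochs.data.shape == (40, 7, 256)
        assert epochs.labels.count("stress") == 20
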