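import numpy as np
import pytest

import qeegkit as qk
from qeegkit.errors import DurationError, MontageError, ParameterError
from qeegkit.montage import DOUBLE_BANANA, TEN_TWENTY, normalize_label


def _rec(data, fs=512.0):
    return qk.Recording("s", fs, list(TEN_TWENTY), data)


def random_recording(n=2048, seed=0, fs=512.0):
    rng = np.random.default_rng(seed)
    return _rec(rng.standard_normal((19, n)), fs)


class TestReadWrite:
    def test_text_matrix_roundtrip(self, tmp_path):
        rec = random_recording(512)
        path = tmp_path / "rec.tsv"
        qk.write_text_matrix(rec, path)
        back = qk.read_recording(path)
        assert back.fs == 512.0
        assert back.electrodes == list(TEN_TWENTY)
        assert back.duration_s == 1.0
        np.testing.assert_allclose(back.data, rec.data, atol=1e-5)

    def test_missing_electrode_named(self, tmp_path):
        labels = [e for e in TEN_TWENTY if e != "O2"]
        path = tmp_path / "bad.tsv"
        with open(path, "w") as fh:
            fh.write("\t".join(labels) + "\n")
            for _ in range(32):
                fh.write("\t".join(["0.0"] * len(labels)) + "\n")
        with pytest.raises(MontageError, match="O2"):
            qk.read_recording(path)

    def test_edf_roundtrip_within_quantization(self, tmp_path):
        # dual route: in-package EDF writer vs mne's independent EDF reader
        rec = random_recording(1024, seed=3)
        path = tmp_path / "rec.edf"
        qk.write_edf(rec, path)
        back = qk.read_recording(path)
        assert back.electrodes == list(TEN_TWENTY)
        step = np.ptp(rec.data, axis=1) / 65535.0
        err = np.abs(back.data - rec.data).max(axis=1)
        assert np.all(err <= step + 1e-9)

    def test_modern_labels_accepted(self):
        assert normalize_label("T7") == "T3"
        assert normalize_label("EEG P8") == "T6"


class TestConcatSegments:
    def test_identity(self):
        rec = random_recording(120 * 512)
        out = qk.concat_segments(rec, [(0.0, 120.0)])
        np.testing.assert_array_equal(out.data, rec.data)
        assert out.segments == [(0, 120 * 512)]

    def test_two_chunks_flag_boundary(self):
        rec = random_recording(130 * 512)
        out = qk.concat_segments(rec, [(0.0, 60.0), (70.0, 130.0)])
        assert out.duration_s == 120.0
        assert out.segments == [(0, 60 * 512), (60 * 512, 120 * 512)]

    def test_below_minimum_raises(self):
        rec = random_recording(130 * 512)
        with pytest.raises(DurationError):
            qk.concat_segments(rec, [(0.0, 100.0)])
        out = qk.concat_segments(rec, [(0.0, 100.0)], allow_short=True)
        assert out.duration_s == 100.0

    def test_windows_respect_boundaries(self):
        # windows per spliced record = sum of per-chunk window counts
        rec = random_recording(130 * 512)
        out = qk.concat_segments(rec, [(0.0, 60.0), (70.0, 130.0)])
        wins = qk.segment_windows(out.segments, 512.0)
        per_chunk = len(qk.make_windows(60 * 512, 512.0))
        assert len(wins) == 2 * per_chunk
        for a, b in wins:
            assert (a < 60 * 512) == (b <= 60 * 512)


class TestBandpass:
    def test_dc_rejected(self):
        rec = _rec(np.full((19, 4096), 100.0))
        out = qk.bandpass(rec)
        assert np.abs(out.data[:, 1024:-1024]).max() < 1.0

    def test_passband_gain_unity(self):
        t = np.arange(8192) / 512.0
        rec = _rec(np.tile(np.sin(2 * np.pi * 10.0 * t), (19, 1)))
        out = qk.bandpass(rec)
        mid = out.data[0, 2048:-2048]
        gain = mid.std() / rec.data[0, 2048:-2048].std()
        assert 0.99 <= gain <= 1.01

    def test_stopband_attenuation(self):
        t = np.arange(8192) / 512.0
        rec = _rec(np.tile(np.sin(2 * np.pi * 50.0 * t), (19, 1)))
        out = qk.bandpass(rec)
        amp = np.abs(out.data[0, 2048:-2048]).max()
        assert 20 * np.log10(1.0 / amp) > 20.0

    def test_passband_idempotence(self):
        # content well inside the passband is untouched by a second pass
        rec = random_recording(20 * 512, seed=5)
        inband = qk.bandpass(rec, 2.0, 25.0)  # confine to the passband
        once = qk.bandpass(inband)
        twice = qk.bandpass(once)
        mid = slice(2048, -2048)
        ratio = twice.data[:, mid].std() / once.data[:, mid].std()
        assert abs(ratio - 1.0) < 0.02

    def test_invalid_corners(self):
        rec = random_recording(1024)
        with pytest.raises(ParameterError):
            qk.bandpass(rec, 30.0, 0.5)


class TestMontages:
    def test_identical_signals_zero_bipolar(self):
        rec = _rec(np.tile(np.sin(np.arange(512) / 10.0), (19, 1)))
        assert np.abs(qk.to_bipolar(rec).data).max() == 0.0

    def test_single_electrode_propagation(self):
        data = np.zeros((19, 64))
        data[TEN_TWENTY.index("Fp1")] = 1.0
        bip = qk.to_bipolar(_rec(data))
        for label, row in zip(bip.labels, bip.data):
            expected = 1.0 if label in ("Fp1-F3", "Fp1-F7") else 0.0
            assert np.all(row == expected), label

    def test_bipolar_equals_row_differences(self):
        rec = random_recording(256, seed=7)
        bip = qk.to_bipolar(rec)
        for (a, c), row in zip(bip.channels, bip.data):
            np.testing.assert_array_equal(
                row, rec.channel(a) - rec.channel(c))

    def test_avg_zero_sum_and_identical_zero(self):
        rec = random_recording(256, seed=8)
        avg = qk.to_avg(rec)
        np.testing.assert_allclose(avg.data.sum(axis=0), 0.0, atol=1e-9)
        same = _rec(np.tile(rec.data[0], (19, 1)))
        assert np.abs(qk.to_avg(same).data).max() < 1e-12

    def test_bipolar_reference_free(self):
        # differences are invariant to re-referencing: bipolar(avg(x)) ==
        # bipolar(x)
        rec = random_recording(256, seed=9)
        np.testing.assert_allclose(qk.to_bipolar(qk.to_avg(rec)).data,
                                   qk.to_bipolar(rec).data, atol=1e-10)

    def test_double_banana_channel_set(self):
        assert len(DOUBLE_BANANA) == 18
        assert ("Fz", "Cz") in DOUBLE_BANANA and ("Cz", "Pz") in DOUBLE_BANANA
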