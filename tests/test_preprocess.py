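"""Preprocessing: bandpass, resampling, segmentation, normalization, WAV I/O."""

import numpy as np
import pytest
from scipy import signal as sps

from pcgscreen.errors import (
    DegenerateSignalError,
    InvalidConfigError,
    InvalidInputError,
    RecordRejectedError,
)
from pcgscreen.io import (
    load_recording,
    read_manifest,
    read_wav,
    write_manifest,
    write_wav,
)
from pcgscreen.preprocess import (
    PCGRecord,
    RawRecording,
    bandpass_filter,
    extract_segment,
    preprocess_record,
    resample_to,
    zscore,
)


def tone(freq, duration=2.0, rate=44100.0, amplitude=1.0):
    t = np.arange(int(duration * rate)) / rate
    return amplitude * np.sin(2 * np.pi * freq * t)


def raw(samples, rate=44100.0, sid="s0", label="HC"):
    return RawRecording(samples=samples, rate=rate, subject_id=sid, label=label)


def rms(x):
    return float(np.sqrt(np.mean(np.asarray(x) ** 2)))


class TestBandpass:
    def test_in_band_tone_passes(self):
        rec = raw(tone(500.0))
        out = bandpass_filter(rec)
        assert rms(out.samples) == pytest.approx(rms(rec.samples), rel=0.05)
        assert out.samples.size == rec.samples.size and out.rate == rec.rate

    def test_stop_band_tone_rejected(self):
        rec = raw(tone(5.0))
        out = bandpass_filter(rec)
        assert rms(out.samples) < 0.10 * rms(rec.samples)

    def test_white_noise_out_of_band_attenuation(self):
        # Independent periodogram of the filtered output: PSD at 2 kHz must
        # sit >= 40 dB below PSD at 500 Hz.
        x = np.random.default_rng(0).standard_normal(44100 * 4)
        out = bandpass_filter(raw(x))
        f, p = sps.periodogram(out.samples, fs=44100.0)
        in_band = np.mean(p[(f > 450) & (f < 550)])
        out_band = np.mean(p[(f > 1950) & (f < 2050)])
        assert 10 * np.log10(out_band / in_band) < -40.0

    def test_edge_at_nyquist_rejected(self):
        with pytest.raises(InvalidConfigError):
            bandpass_filter(raw(tone(100.0, rate=2000.0), rate=2000.0), high=1000.0)

    def test_zero_phase_preserves_burst_position(self):
        # Zero-phase contract: a short in-band burst must not shift in time.
        rate = 44100.0
        x = np.zeros(int(rate))
        center = int(0.5 * rate)
        t = (np.arange(x.size) - center) / rate
        x += np.exp(-0.5 * (t / 0.01) ** 2) * np.sin(2 * np.pi * 200 * t)
        out = bandpass_filter(raw(x))
        assert abs(int(np.argmax(np.abs(out.samples))) - int(np.argmax(np.abs(x)))) < rate * 0.002


class TestResample:
    def test_length_arithmetic(self):
        rec = raw(np.random.default_rng(1).standard_normal(44100 * 60))
        out = resample_to(bandpass_filter(rec), 2000.0)
        assert out.samples.size == 120_000 and out.rate == 2000.0

    def test_tone_preserved(self):
        out = resample_to(bandpass_filter(raw(tone(100.0, duration=4.0))), 2000.0)
        f, p = sps.periodogram(out.samples, fs=2000.0)
        assert abs(f[np.argmax(p)] - 100.0) <= 2.0

    def test_chirp_ridge_matches(self):
        # STFT ridge tracking on input and output must agree within one bin.
        rate = 44100.0
        t = np.arange(int(rate * 8)) / rate
        x = sps.chirp(t, f0=20.0, f1=900.0, t1=8.0)
        out = resample_to(bandpass_filter(raw(x)), 2000.0)
        fo, to_, so = sps.stft(out.samples, fs=2000.0, nperseg=256)
        fi, ti, si = sps.stft(x, fs=rate, nperseg=int(256 * rate / 2000))
        ridge_out = fo[np.argmax(np.abs(so), axis=0)]
        ridge_in = fi[np.argmax(np.abs(si), axis=0)]
        # compare on the common interior time grid
        common = min(ridge_out.size, ridge_in.size) - 2
        df = fo[1] - fo[0]
        assert np.all(np.abs(ridge_out[1:common] - ridge_in[1:common]) <= df + 1e-9)

    def test_upsampling_refused_by_default(self):
        rec = raw(tone(100.0, rate=2000.0), rate=2000.0)
        with pytest.raises(InvalidConfigError):
            resample_to(rec, 8000.0)
        assert resample_to(rec, 8000.0, allow_upsample=True).rate == 8000.0


class TestSegmentAndZscore:
    def test_47s_record_trimmed_to_30s(self):
        rec = raw(np.random.default_rng(2).standard_normal(2000 * 47), rate=2000.0)
        out = extract_segment(rec)
        assert out.samples.size == 60_000

    def test_29s_record_rejected(self):
        rec = raw(np.random.default_rng(3).standard_normal(2000 * 29), rate=2000.0)
        with pytest.raises(RecordRejectedError):
            extract_segment(rec)

    def test_exact_30s_returned_trimmed(self):
        x = np.random.default_rng(4).standard_normal(60_000)
        out = extract_segment(raw(x, rate=2000.0))
        assert np.array_equal(out.samples, x)

    def test_constant_signal_rejected(self):
        with pytest.raises(DegenerateSignalError):
            zscore(raw(np.ones(1000), rate=2000.0))

    def test_zscore_definition_and_idempotence(self):
        x = np.random.default_rng(5).standard_normal(4000) * 7 + 3
        z1 = zscore(raw(x, rate=2000.0))
        assert abs(np.mean(z1.samples)) < 1e-8 and abs(np.std(z1.samples) - 1) < 1e-8
        z2 = zscore(raw(z1.samples, rate=2000.0))
        assert np.allclose(z1.samples, z2.samples, atol=1e-12)


class TestPipeline:
    def test_composition_and_determinism(self):
        x = np.random.default_rng(6).standard_normal(int(44100 * 60))
        rec = raw(x)
        a = preprocess_record(rec)
        b = preprocess_record(rec)
        assert a.is_canonical and a.samples.size == 60_000 and a.rate == 2000.0
        assert np.array_equal(a.samples, b.samples)

    def test_short_recording_rejected(self):
        rec = raw(np.random.default_rng(7).standard_normal(int(44100 * 20)))
        with pytest.raises(RecordRejectedError):
            preprocess_record(rec)

    def test_2khz_input_supported(self):
        rec = raw(np.random.default_rng(8).standard_normal(2000 * 31), rate=2000.0)
        assert preprocess_record(rec).is_canonical

    def test_energy_ordering_preserved_before_zscore(self):
        loud = bandpass_filter(raw(tone(200.0, amplitude=2.0)))
        quiet = bandpass_filter(raw(tone(200.0, amplitude=1.0)))
        assert rms(loud.samples) > rms(quiet.samples)

    def test_invariants_on_raw_recording(self):
        with pytest.raises(InvalidInputError):
            RawRecording(samples=np.array([1.0, np.nan]), rate=2000.0, subject_id="x", label="HC")
        with pytest.raises(InvalidInputError):
            RawRecording(samples=np.ones(10), rate=1000.0, subject_id="x", label="HC")
        with pytest.raises(InvalidInputError):
            PCGRecord(samples=np.random.default_rng(0).standard_normal(100) + 5.0,
                      rate=2000.0, subject_id="x", label="HC")


class TestWavIO:
    def test_float_roundtrip(self, tmp_path):
        x = np.random.default_rng(9).standard_normal(4000) * 0.1
        path = tmp_path / "a.wav"
        write_wav(path, x, 2000)
        y, rate = read_wav(path)
        assert rate == 2000 and np.allclose(x, y, atol=1e-6)

    def test_pcm16_scaled(self, tmp_path):
        from scipy.io import wavfile

        x = (np.sin(2 * np.pi * 100 * np.arange(2000) / 2000) * 32000).astype(np.int16)
        path = tmp_path / "b.wav"
        wavfile.write(path, 2000, x)
        y, _ = read_wav(path)
        assert np.max(np.abs(y)) <= 1.0 and np.max(np.abs(y)) > 0.9

    def test_pcm24_supported(self, tmp_path):
        import wave

        x = np.sin(2 * np.pi * 100 * np.arange(2000) / 2000)
        ints = (x * (2**23 - 1)).astype(np.int32)
        b = ints.astype("<i4").tobytes()
        frames = b"".join(b[i : i + 3] for i in range(0, len(b), 4))
        path = tmp_path / "c.wav"
        with wave.open(str(path), "wb") as w:
            w.setnchannels(1)
            w.setsampwidth(3)
            w.setframerate(2000)
            w.writeframes(frames)
        y, rate = read_wav(path)
        assert rate == 2000 and np.allclose(y, x, atol=1e-5)

    def test_stereo_rejected(self, tmp_path):
        from scipy.io import wavfile

        stereo = np.zeros((1000, 2), dtype=np.float32)
        path = tmp_path / "d.wav"
        wavfile.write(path, 2000, stereo)
        with pytest.raises(InvalidInputError):
            read_wav(path)

    def test_manifest_roundtrip(self, tmp_path):
        rows = [
            {"subject_id": "s1", "label": "RHD", "source": "synthetic", "path": "s1.wav"},
            {"subject_id": "s2", "label": "HC", "source": "synthetic", "path": "s2.wav"},
        ]
        path = tmp_path / "manifest.csv"
        write_manifest(path, rows)
        df = read_manifest(path)
        assert list(df.columns) == ["subject_id", "label", "source", "path"]
        assert df.shape == (2, 4)

    def test_load_recording(self, tmp_path):
        x = np.random.default_rng(10).standard_normal(4000) * 0.2
        path = tmp_path / "e.wav"
        write_wav(path, x, 2000)
        rec = load_recording(path, "s9", "HC", "synthetic")
        assert rec.subject_id == "s9" and rec.rate == 2000.0
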