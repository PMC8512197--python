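"""Mel-frequency cepstral coefficients (MFCC1-MFCC13) for heart sounds.

Framing defaults target a 2-kHz, 0-1-kHz-band signal: 128-ms frames resolve
the low-frequency murmur bands, and 26 triangular mel filters over 0-1000 Hz
keep at least two FFT bins under every filter. The 0th (energy) cepstral
coefficient is excluded -- loudness is covered by the acoustic group -- so
"MFCC1" here is the first non-energy coefficient. No pre-emphasis is
applied: that is a speech-specific high-frequency boost with no place in
low-frequency cardiac audio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, rfft

from ..errors import InvalidConfigError, InvalidInputError
from ..preprocess import PCGRecord
from .basic import PERCEPTUAL_NAMES


@dataclass(frozen=True)
class MFCCConfig:
    """Framing and filterbank parameters.

    ``frame_length``/``hop`` are in samples (256/128 = 128/64 ms at 2 kHz);
    ``fmax`` defaults to the Nyquist frequency of the record.
    """

    frame_length: int = 256
    hop: int = 128
    n_mel_filters: int = 26
    n_coefficients: int = 13
    log_floor: float = 1e-10
    fmin: float = 0.0
    fmax: float | None = None

    def validate(self, n_samples: int) -> None:
        if self.frame_length > n_samples:
            raise InvalidInputError(
                f"record of {n_samples} samples is shorter than one "
                f"{self.frame_length}-sample frame"
            )
        if self.hop > self.frame_length:
            raise InvalidConfigError("hop must not exceed frame_length")
        if self.n_mel_filters < self.n_coefficients:
            raise InvalidConfigError("need at least as many mel filters as coefficients")


@dataclass(frozen=True)
class PerceptualFeatures:
    """The 13 frame-averaged cepstral coefficients."""

    coefficients: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=np.float64)
        if c.shape != (13,) or not np.all(np.isfinite(c)):
            raise InvalidInputError("expected 13 finite MFCC values")
        object.__setattr__(self, "coefficients", c)

    def as_array(self) -> np.ndarray:
        return self.coefficients.copy()

    def as_dict(self) -> dict[str, float]:
        return dict(zip(PERCEPTUAL_NAMES, self.coefficients.tolist()))


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_filters: int, n_fft: int, rate: float, fmin: float, fmax: float
) -> np.ndarray:
    """Triangular mel filterbank, shape (n_filters, n_fft // 2 + 1).

    Filter apexes sit on a uniform mel grid between ``fmin`` and ``fmax``;
    triangles have unit height (no area normalization).
    """
    mel_points = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_filters + 2)
    hz_points = np.asarray(mel_to_hz(mel_points))
    bins = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_filters, bins.size))
    for i in range(n_filters):
        left, center, right = hz_points[i : i + 3]
        up = (bins - left) / max(center - left, 1e-12)
        down = (right - bins) / max(right - center, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mfcc_from_samples(
    samples: np.ndarray, rate: float, cfg: MFCCConfig | None = None
) -> np.ndarray:
    """Frame-averaged MFCC1..13 of an arbitrary signal (helper for tests)."""
    cfg = cfg or MFCCConfig()
    x = np.asarray(samples, dtype=np.float64)
    cfg.validate(x.size)
    fmax = cfg.fmax if cfg.fmax is not None else rate / 2.0

    n_frames = 1 + (x.size - cfg.frame_length) // cfg.hop
    idx = np.arange(cfg.frame_length)[None, :] + cfg.hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hamming(cfg.frame_length)
    spectra = np.abs(rfft(frames, axis=1))

    fb = mel_filterbank(cfg.n_mel_filters, cfg.frame_length, rate, cfg.fmin, fmax)
    energies = spectra @ fb.T  # (frames, filters), magnitude-domain energies
    log_energies = np.log(np.maximum(energies, cfg.log_floor))
    cepstra = dct(log_energies, type=2, norm="ortho", axis=1)
    return cepstra[:, 1 : cfg.n_coefficients + 1].mean(axis=0)


def mfcc_features(rec: PCGRecord, cfg: MFCCConfig | None = None) -> PerceptualFeatures:
    """Compute MFCC1..13 of a preprocessed record.

    Per frame: Hamming window, magnitude spectrum, triangular mel filterbank,
    natural log with floor, orthonormal DCT-II; coefficients 1..13 are then
    averaged over frames (the mean is order-free, so frame order is
    irrelevant).
    """
    return PerceptualFeatures(coefficients=mfcc_from_samples(rec.samples, rec.rate, cfg))
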