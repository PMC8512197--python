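"""Segmentation-free phonocardiogram preprocessing.

Turns an arbitrary heart-sound recording into the canonical form every
downstream feature operates on: bandpassed 20 Hz-1 kHz, resampled to 2 kHz,
a single 30-s window, z-scored to zero mean and unit standard deviation.
No attempt is made to locate S1/S2 or to denoise beyond the bandpass --
real-world noise is deliberately kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .errors import (
    DegenerateSignalError,
    InvalidConfigError,
    InvalidInputError,
    RecordRejectedError,
)

TARGET_RATE = 2000
SEGMENT_SECONDS = 30.0
BAND_LOW_HZ = 20.0
BAND_HIGH_HZ = 1000.0
FILTER_ORDER = 4

LABELS = ("RHD", "HC")


@dataclass(frozen=True)
class RawRecording:
    """A single-channel heart-sound recording tagged with subject metadata.

    ``samples`` are amplitudes in arbitrary units (absolute scale is removed
    later by z-scoring); ``rate`` is the sampling rate in Hz. Exactly one
    record per subject enters any experiment.
    """

    samples: np.ndarray
    rate: float
    subject_id: str
    label: str
    source: str = "unknown"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.rate < TARGET_RATE:
            raise InvalidInputError(
                f"sampling rate {self.rate} Hz below the minimum {TARGET_RATE} Hz"
            )
        if samples.ndim != 1 or samples.size == 0:
            raise InvalidInputError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise InvalidInputError("samples contain non-finite values")
        if self.label not in LABELS:
            raise InvalidInputError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.rate


@dataclass(frozen=True)
class PCGRecord:
    """A z-scored phonocardiogram at a fixed rate.

    The canonical record produced by :func:`preprocess_record` is 30 s at
    2 kHz (60 000 samples); ``is_canonical`` reports whether this instance
    has that shape. Mean and standard deviation are always 0 and 1 within
    1e-8 by construction.
    """

    samples: np.ndarray
    rate: float
    subject_id: str
    label: str
    source: str = "unknown"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise InvalidInputError("PCGRecord needs at least two samples")
        mu = float(np.mean(samples))
        sd = float(np.std(samples))
        if abs(mu) > 1e-8 or abs(sd - 1.0) > 1e-8:
            raise InvalidInputError(
                f"PCGRecord must be z-scored (mean {mu:.2e}, std {sd:.6f})"
            )
        if self.label not in LABELS:
            raise InvalidInputError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def is_canonical(self) -> bool:
        """True for the canonical 30-s, 2-kHz form (exactly 60 000 samples)."""
        return self.rate == TARGET_RATE and self.samples.size == int(
            round(SEGMENT_SECONDS * TARGET_RATE)
        )


def bandpass_filter(
    rec: RawRecording, low: float = BAND_LOW_HZ, high: float = BAND_HIGH_HZ
) -> RawRecording:
    """Zero-phase 4th-order Butterworth bandpass, applied forward-backward.

    The forward-backward application doubles the effective order and removes
    phase distortion, preserving murmur timing. Raises
    :class:`InvalidConfigError` when ``high`` reaches the Nyquist frequency.
    """
    nyquist = rec.rate / 2.0
    if not (0.0 < low < high):
        raise InvalidConfigError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= nyquist:
        raise InvalidConfigError(
            f"bandpass edge {high} Hz reaches the Nyquist frequency {nyquist} Hz"
        )
    sos = signal.butter(FILTER_ORDER, [low, high], btype="bandpass", fs=rec.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return replace(rec, samples=filtered)


def resample_to(
    rec: RawRecording, target_rate: float = TARGET_RATE, allow_upsample: bool = False
) -> RawRecording:
    """Polyphase rational resampling to ``target_rate``.

    The caller must have bandlimited the signal below ``target_rate / 2``
    (normally via :func:`bandpass_filter`). Output length is
    ``round(n * target_rate / rate)`` exactly.
    """
    if target_rate > rec.rate and not allow_upsample:
        raise InvalidConfigError(
            f"refusing to upsample {rec.rate} Hz to {target_rate} Hz"
        )
    if target_rate == rec.rate:
        return rec
    ratio = Fraction(target_rate).limit_denominator(10**6) / Fraction(
        rec.rate
    ).limit_denominator(10**6)
    out = signal.resample_poly(rec.samples, ratio.numerator, ratio.denominator)
    expected = int(round(rec.samples.size * target_rate / rec.rate))
    if out.size > expected:
        out = out[:expected]
    elif out.size < expected:  # pragma: no cover - resample_poly rounds up
        out = np.pad(out, (0, expected - out.size), mode="edge")
    return replace(rec, samples=out, rate=float(target_rate))


def extract_segment(
    rec: RawRecording, duration: float = SEGMENT_SECONDS, offset: float = 0.0
) -> RawRecording:
    """Take one ``duration``-second window starting at ``offset`` seconds.

    The default offset of zero makes the choice deterministic; recordings
    shorter than the window are rejected, mirroring the inclusion rule that
    a usable record must be at least 30 s long.
    """
    n = int(round(duration * rec.rate))
    start = int(round(offset * rec.rate))
    if start < 0:
        raise InvalidConfigError("offset must be non-negative")
    if rec.samples.size - start < n:
        raise RecordRejectedError(
            f"record {rec.subject_id!r} is {rec.duration:.2f} s; "
            f"need {duration} s from offset {offset} s"
        )
    return replace(rec, samples=rec.samples[start : start + n])


def zscore(rec: RawRecording) -> PCGRecord:
    """Normalize to zero mean and unit standard deviation."""
    x = rec.samples
    mu = float(np.mean(x))
    sd = float(np.std(x))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateSignalError(f"record {rec.subject_id!r} is constant (std = 0)")
    z = (x - mu) / sd
    # One corrective pass keeps the PCGRecord invariants inside 1e-8 even
    # for numerically awkward inputs (huge offsets, tiny variance).
    z = (z - np.mean(z)) / np.std(z)
    return PCGRecord(
        samples=z, rate=rec.rate, subject_id=rec.subject_id, label=rec.label, source=rec.source
    )


def preprocess_record(
    rec: RawRecording,
    low: float = BAND_LOW_HZ,
    high: float = BAND_HIGH_HZ,
    target_rate: float = TARGET_RATE,
    duration: float = SEGMENT_SECONDS,
    offset: float = 0.0,
) -> PCGRecord:
    """Full preprocessing chain: bandpass -> resample -> segment -> z-score.

    Deterministic; running it twice on the same input yields bit-identical
    output. Recordings already sampled at ``target_rate`` get the bandpass
    edge clipped just below Nyquist so that 2-kHz open-dataset records pass
    through the same chain.
    """
    effective_high = min(high, 0.99 * rec.rate / 2.0)
    out = bandpass_filter(rec, low, effective_high)
    out = resample_to(out, target_rate)
    out = extract_segment(out, duration, offset)
    return zscore(out)
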