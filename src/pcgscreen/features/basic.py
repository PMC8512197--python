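"""Time- and frequency-domain features, and the 31-element feature vector.

The representation of one 30-s record is a fixed, ordered vector of 31
scalars split over four groups: acoustic (4), frequency (5), time (9) and
perceptual (13 MFCCs). This module computes the time and frequency groups
and assembles the full vector; the other two groups live in
:mod:`pcgscreen.features.acoustic` and :mod:`pcgscreen.features.perceptual`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import signal

from ..errors import DegenerateSignalError, InvalidFeatureError
from ..preprocess import PCGRecord

if TYPE_CHECKING:  # pragma: no cover
    from .acoustic import AcousticFeatures
    from .perceptual import PerceptualFeatures

ACOUSTIC_NAMES = ("roughness", "loudness", "sharpness", "fluctuation_strength")
FREQUENCY_NAMES = (
    "spectral_entropy",
    "dominant_frequency_value",
    "dominant_frequency_magnitude",
    "dominant_frequency_ratio",
    "bandwidth",
)
TIME_NAMES = (
    "median",
    "mean_absolute_deviation",
    "q1",
    "q3",
    "iqr",
    "skewness",
    "kurtosis",
    "shannon_energy",
    "zero_crossing_rate",
)
PERCEPTUAL_NAMES = tuple(f"mfcc{i}" for i in range(1, 14))

#: Canonical column order of the feature table; part of the CSV contract.
FEATURE_NAMES: tuple[str, ...] = (
    ACOUSTIC_NAMES + FREQUENCY_NAMES + TIME_NAMES + PERCEPTUAL_NAMES
)


@dataclass(frozen=True)
class TimeFeatures:
    """Nine time-domain statistics of the z-scored signal.

    Kurtosis uses the non-excess (Pearson) convention, so a Gaussian scores
    3; Shannon energy is -(1/N) sum x^2 ln x^2 with 0 ln 0 := 0; the
    zero-crossing rate counts strict sign changes as a fraction of the N-1
    sample pairs.
    """

    median: float
    mean_absolute_deviation: float
    q1: float
    q3: float
    iqr: float
    skewness: float
    kurtosis: float
    shannon_energy: float
    zero_crossing_rate: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in TIME_NAMES], dtype=np.float64)


@dataclass(frozen=True)
class PSDEstimate:
    """One-sided Welch power spectral density on an ascending Hz grid."""

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=np.float64)
        p = np.asarray(self.power, dtype=np.float64)
        if f.shape != p.shape or f.ndim != 1:
            raise InvalidFeatureError("frequency grid and power must be 1-D, same length")
        if np.any(p < 0):
            raise InvalidFeatureError("spectral power must be non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "power", p)


@dataclass(frozen=True)
class FrequencyFeatures:
    """Five spectral-shape features computed from a PSD (DC bin excluded)."""

    spectral_entropy: float
    dominant_frequency_value: float
    dominant_frequency_magnitude: float
    dominant_frequency_ratio: float
    bandwidth: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FREQUENCY_NAMES], dtype=np.float64)


@dataclass(frozen=True)
class FeatureVector:
    """Ordered 31-value representation of one record.

    Order is the canonical :data:`FEATURE_NAMES`: acoustic (4), frequency
    (5), time (9), perceptual (13). All values are finite by construction.
    """

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.names),):
            raise InvalidFeatureError(
                f"expected {len(self.names)} values, got shape {values.shape}"
            )
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size:
            raise InvalidFeatureError(
                f"non-finite feature(s): {', '.join(self.names[i] for i in bad)}"
            )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def compute_time_features(rec: PCGRecord) -> TimeFeatures:
    """Compute the nine time-domain statistics on the z-scored samples.

    Quantiles use linear interpolation between order statistics; the mean
    absolute deviation is taken about the mean.
    """
    x = rec.samples
    n = x.size
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    mu = np.mean(x)
    mad = float(np.mean(np.abs(x - mu)))
    m2 = np.mean((x - mu) ** 2)
    m3 = np.mean((x - mu) ** 3)
    m4 = np.mean((x - mu) ** 4)
    skew = float(m3 / m2**1.5)
    kurt = float(m4 / m2**2)
    x2 = x * x
    shannon = float(-np.mean(np.where(x2 > 0, x2 * np.log(np.where(x2 > 0, x2, 1.0)), 0.0)))
    zcr = float(np.count_nonzero(x[:-1] * x[1:] < 0) / (n - 1))
    return TimeFeatures(
        median=float(med),
        mean_absolute_deviation=mad,
        q1=float(q1),
        q3=float(q3),
        iqr=float(q3 - q1),
        skewness=skew,
        kurtosis=kurt,
        shannon_energy=shannon,
        zero_crossing_rate=zcr,
    )


def estimate_psd(rec: PCGRecord, nperseg: int = 1024, overlap: float = 0.5) -> PSDEstimate:
    """Welch PSD with 1024-sample Hamming segments and 50% overlap.

    At 2 kHz this gives a ~1.95 Hz frequency resolution. The DC bin is kept
    on the grid but excluded by :func:`compute_frequency_features`.
    """
    nperseg = min(nperseg, rec.samples.size)
    freqs, power = signal.welch(
        rec.samples,
        fs=rec.rate,
        window="hamming",
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
    )
    return PSDEstimate(frequencies=freqs, power=power)


def compute_frequency_features(psd: PSDEstimate) -> FrequencyFeatures:
    """Five spectral-shape features from a normalized non-DC power distribution.

    The dominant-frequency ratio is the power fraction in a +/-5%
    neighborhood of the dominant bin (never narrower than one bin each
    side); bandwidth is the power-weighted spectral spread about the
    centroid. Ties for the dominant bin resolve to the lowest frequency.
    """
    keep = psd.frequencies > 0
    f = psd.frequencies[keep]
    p = psd.power[keep]
    total = p.sum()
    if f.size == 0 or total <= 0:
        raise DegenerateSignalError("spectrum carries no power outside DC")
    p = p / total
    entropy_n = float(
        -np.sum(np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)) / np.log(p.size)
    ) if p.size > 1 else 0.0
    idx = int(np.argmax(p))  # argmax takes the first maximum -> lowest frequency
    f_dom = float(f[idx])
    df = float(np.min(np.diff(f))) if f.size > 1 else 0.0
    half_width = max(0.05 * f_dom, df)
    neighborhood = np.abs(f - f_dom) <= half_width + 1e-12
    ratio = float(p[neighborhood].sum())
    centroid = float(np.sum(p * f))
    bw = float(np.sqrt(np.sum(p * (f - centroid) ** 2)))
    return FrequencyFeatures(
        spectral_entropy=entropy_n,
        dominant_frequency_value=f_dom,
        dominant_frequency_magnitude=float(p[idx]),
        dominant_frequency_ratio=ratio,
        bandwidth=bw,
    )


def assemble_feature_vector(
    ac: "AcousticFeatures",
    fr: FrequencyFeatures,
    ti: TimeFeatures,
    pe: "PerceptualFeatures",
) -> FeatureVector:
    """Concatenate the four groups in canonical order into one 31-vector.

    All groups must come from the same record; any non-finite component
    raises :class:`InvalidFeatureError` naming the offending feature.
    """
    values = np.concatenate(
        [ac.as_array(), fr.as_array(), ti.as_array(), pe.as_array()]
    )
    return FeatureVector(values=values)
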