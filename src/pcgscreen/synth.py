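"""Synthetic phonocardiogram generation.

Produces labeled heart-sound recordings with the structure the analysis
assumes: periodic S1/S2 transients (Gaussian-enveloped tone bursts near 60
and 90 Hz), optional systolic and/or diastolic murmurs for RHD-like
records (band-limited 150-400 Hz noise confined to the corresponding
interval of the cardiac cycle), cycle-length jitter, and additive noise --
either white or a babble-like band emulating people talking near the
stethoscope. Defaults describe a clearly audible murmur at 15 dB SNR, the
"separable" study condition; a "hard" preset (weak murmur, 0 dB SNR)
exists for robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .errors import InvalidConfigError
from .preprocess import RawRecording

MURMUR_TYPES = ("none", "systolic", "diastolic", "both")

#: Draw ranges of the per-subject parameters under the two study presets.
PRESETS: dict[str, dict[str, tuple[float, float]]] = {
    "separable": {"murmur_db": (-3.0, 3.0), "snr_db": (12.0, 18.0)},
    "hard": {"murmur_db": (-15.0, -6.0), "snr_db": (-3.0, 3.0)},
}


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic subject's recording.

    ``murmur_db`` is the murmur-to-S1 energy ratio in dB; ``jitter`` is the
    coefficient of variation of the cycle length. The label follows the
    murmur: any murmur means RHD, none means HC.
    """

    fs: float = 2000.0
    duration: float = 35.0
    heart_rate: float = 75.0
    s1_freq: float = 60.0
    s2_freq: float = 90.0
    s1_width_ms: float = 22.0
    s2_width_ms: float = 16.0
    murmur: str = "none"
    murmur_band: tuple[float, float] = (150.0, 400.0)
    murmur_db: float = 0.0
    snr_db: float = 15.0
    noise: str = "babble"
    jitter: float = 0.04
    seed: int = 0
    subject_id: str = "synthetic-0"

    def __post_init__(self) -> None:
        if self.fs < 2000:
            raise InvalidConfigError("fs must be >= 2000 Hz so preprocessing accepts the record")
        if self.duration < 30:
            raise InvalidConfigError("duration must be >= 30 s (the analysis window)")
        if self.murmur not in MURMUR_TYPES:
            raise InvalidConfigError(f"murmur must be one of {MURMUR_TYPES}")
        if self.noise not in ("white", "babble"):
            raise InvalidConfigError("noise must be 'white' or 'babble'")
        if not (0 <= self.jitter < 0.3):
            raise InvalidConfigError("jitter must be a small coefficient of variation")

    @property
    def label(self) -> str:
        return "HC" if self.murmur == "none" else "RHD"


def _tone_burst(t: np.ndarray, center: float, freq: float, sigma: float, phase: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2) * np.sin(2 * np.pi * freq * (t - center) + phase)


def _interval_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    band: tuple[float, float],
    start: float,
    stop: float,
) -> np.ndarray:
    """Band-limited noise windowed (Tukey edges) to [start, stop] seconds."""
    t = np.arange(n) / fs
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    noise = sps.sosfilt(sos, rng.standard_normal(n))
    i0, i1 = int(start * fs), int(stop * fs)
    window = np.zeros(n)
    if i1 > i0 + 8:
        window[i0:i1] = sps.windows.tukey(i1 - i0, alpha=0.3)
    return noise * window


def synth_cycle(spec: SynthSpec, rng: np.random.Generator | None = None,
                cycle_length: float | None = None) -> np.ndarray:
    """One heart cycle: S1, (murmur,) S2, (murmur,) at their phase positions.

    S1 sits at 5% of the cycle and S2 at 42% -- roughly a 300-ms systole at
    75 bpm. Murmur energy is set relative to S1 energy by ``murmur_db``.
    Raises if the S1/S2 envelopes would overlap (heart rate too high for
    the configured widths).
    """
    rng = rng or np.random.default_rng(spec.seed)
    T = cycle_length if cycle_length is not None else 60.0 / spec.heart_rate
    n = int(round(T * spec.fs))
    t = np.arange(n) / spec.fs
    s1_c, s2_c = 0.05 * T, 0.42 * T
    sig1 = spec.s1_width_ms / 1000.0
    sig2 = spec.s2_width_ms / 1000.0
    if s1_c + 3.5 * sig1 >= s2_c - 3.5 * sig2 or s2_c + 3.5 * sig2 >= T:
        raise InvalidConfigError(
            f"S1/S2 envelopes overlap at heart rate {60.0 / T:.0f} bpm "
            f"with widths {spec.s1_width_ms}/{spec.s2_width_ms} ms"
        )
    x = _tone_burst(t, s1_c, spec.s1_freq, sig1, rng.uniform(0, 2 * np.pi))
    x += 0.8 * _tone_burst(t, s2_c, spec.s2_freq, sig2, rng.uniform(0, 2 * np.pi))

    s1_energy = float(np.sum(_tone_burst(t, s1_c, spec.s1_freq, sig1, 0.0) ** 2))
    target = s1_energy * 10.0 ** (spec.murmur_db / 10.0)
    intervals = []
    if spec.murmur in ("systolic", "both"):
        intervals.append((s1_c + 3.0 * sig1, s2_c - 3.0 * sig2))
    if spec.murmur in ("diastolic", "both"):
        intervals.append((s2_c + 3.0 * sig2, T - 3.0 * sig1))
    for start, stop in intervals:
        m = _interval_noise(rng, n, spec.fs, spec.murmur_band, start, stop)
        energy = float(np.sum(m**2))
        if energy > 0:
            x += m * np.sqrt(target / energy)
    return x


def generate_record(spec: SynthSpec) -> RawRecording:
    """Concatenate jittered cycles to the requested duration and add noise.

    The label is derived from the murmur type; noise is scaled to the
    configured SNR against the clean signal power. Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = int(round(spec.duration * spec.fs))
    pieces, length = [], 0
    base_T = 60.0 / spec.heart_rate
    while length < n_total:
        T = base_T * float(np.clip(1.0 + spec.jitter * rng.standard_normal(), 0.7, 1.3))
        cycle = synth_cycle(spec, rng, cycle_length=T)
        pieces.append(cycle)
        length += cycle.size
    x = np.concatenate(pieces)[:n_total]

    p_signal = float(np.mean(x**2))
    if spec.noise == "white":
        noise = rng.standard_normal(n_total)
    else:
        # Babble: speech-band noise with a slow syllabic amplitude modulation.
        sos = sps.butter(4, (80.0, 600.0), btype="bandpass", fs=spec.fs, output="sos")
        noise = sps.sosfilt(sos, rng.standard_normal(n_total))
        t = np.arange(n_total) / spec.fs
        noise *= 1.0 + 0.5 * np.sin(2 * np.pi * 3.0 * t + rng.uniform(0, 2 * np.pi))
    p_noise = float(np.mean(noise**2))
    noise *= np.sqrt(p_signal / (p_noise * 10.0 ** (spec.snr_db / 10.0)))
    return RawRecording(
        samples=x + noise,
        rate=spec.fs,
        subject_id=spec.subject_id,
        label=spec.label,
        source="synthetic",
    )


def generate_dataset(
    n_rhd: int = 124,
    n_hc: int = 127,
    seed: int = 0,
    preset: str = "separable",
    fs: float = 2000.0,
    duration: float = 35.0,
) -> list[RawRecording]:
    """Generate a labeled cohort with per-subject parameter draws.

    Heart rate ~ U(60, 100) bpm; S1/S2 center frequencies jittered around
    60/90 Hz; murmur strength and SNR drawn from the preset's ranges; RHD
    murmur type is systolic/diastolic/both with probabilities 0.6/0.2/0.2
    (regurgitant murmurs being the most common RHD presentation). Subject
    identifiers are unique and generation is deterministic given ``seed``.
    """
    if n_rhd < 1 or n_hc < 1:
        raise InvalidConfigError("need at least one subject per class")
    if preset not in PRESETS:
        raise InvalidConfigError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    ranges = PRESETS[preset]
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_rhd + n_hc):
        is_rhd = i < n_rhd
        murmur = (
            str(rng.choice(["systolic", "diastolic", "both"], p=[0.6, 0.2, 0.2]))
            if is_rhd
            else "none"
        )
        spec = SynthSpec(
            fs=fs,
            duration=duration,
            heart_rate=float(rng.uniform(60, 100)),
            s1_freq=float(rng.uniform(55, 65)),
            s2_freq=float(rng.uniform(85, 95)),
            murmur=murmur,
            murmur_db=float(rng.uniform(*ranges["murmur_db"])),
            snr_db=float(rng.uniform(*ranges["snr_db"])),
            jitter=0.04,
            seed=int(rng.integers(0, 2**31 - 1)),
            subject_id=f"{'rhd' if is_rhd else 'hc'}-{(i if is_rhd else i - n_rhd):04d}",
        )
        records.append(generate_record(spec))
    return records
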