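"""WAV and manifest input/output.

Recordings travel as mono WAV files plus a plain-text manifest CSV with
columns ``subject_id,label,source,path``. Integer PCM (16/24/32-bit) is
scaled to [-1, 1] floats on read; absolute scale is irrelevant downstream
because every record is z-scored.
"""

from __future__ import annotations

import wave
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import DataError, InvalidInputError
from .preprocess import PCGRecord, RawRecording

MANIFEST_COLUMNS = ["subject_id", "label", "source", "path"]

_PCM_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31}


def _read_wav_24bit(path: Path) -> tuple[int, np.ndarray]:
    # scipy.io.wavfile cannot decode 24-bit PCM; unpack it via the stdlib.
    with wave.open(str(path), "rb") as w:
        if w.getsampwidth() != 3:
            raise InvalidInputError(f"unsupported WAV encoding in {path}")
        n_channels = w.getnchannels()
        rate = w.getframerate()
        raw = np.frombuffer(w.readframes(w.getnframes()), dtype=np.uint8)
    as32 = np.zeros((raw.size // 3, 4), dtype=np.uint8)
    as32[:, 1:] = raw.reshape(-1, 3)
    data = as32.view("<i4").ravel() >> 8
    if n_channels > 1:
        data = data.reshape(-1, n_channels)
    return rate, data.astype(np.float64) / 2**23


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a mono WAV file, returning float64 samples in [-1, 1] and the rate.

    Stereo files are rejected: auscultation is single-channel and silently
    mixing channels would hide a data problem.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
        data = np.asarray(data)
        if data.dtype in _PCM_SCALE:
            data = data.astype(np.float64) / _PCM_SCALE[data.dtype]
        else:
            data = data.astype(np.float64)
    except ValueError:
        rate, data = _read_wav_24bit(path)
    if data.ndim > 1:
        raise InvalidInputError(f"{path} has {data.shape[1]} channels; expected mono")
    return data, float(rate)


def write_wav(path: str | Path, samples: np.ndarray, rate: float) -> None:
    """Write float32 WAV."""
    wavfile.write(Path(path), int(rate), np.asarray(samples, dtype=np.float32))


def load_recording(
    path: str | Path, subject_id: str, label: str, source: str = "unknown"
) -> RawRecording:
    samples, rate = read_wav(path)
    return RawRecording(samples=samples, rate=rate, subject_id=subject_id, label=label, source=source)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest CSV and validate its header."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"manifest {path} is missing columns {missing}")
    return df[MANIFEST_COLUMNS]


def write_manifest(path: str | Path, rows: Iterable[dict]) -> pd.DataFrame:
    df = pd.DataFrame(list(rows), columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
    return df


def iter_manifest_recordings(
    manifest: pd.DataFrame, root: str | Path | None = None
) -> Iterable[RawRecording]:
    """Yield one RawRecording per manifest row; paths resolve against ``root``."""
    root = Path(root) if root is not None else None
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if root is not None and not p.is_absolute():
            p = root / p
        yield load_recording(p, row.subject_id, row.label, row.source)


def save_pcg_record(rec: PCGRecord, path: str | Path) -> None:
    """Serialize a preprocessed record as float32 WAV at its own rate."""
    write_wav(path, rec.samples, rec.rate)
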