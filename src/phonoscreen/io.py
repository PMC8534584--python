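"""Readers and writers: PCM WAV audio, feature matrices, manifests."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .core import InvalidAudioError, Phonation

#: metadata columns stored ahead of the feature columns in matrix CSVs
META_COLUMNS = ["file", "participant_id", "label", "age", "gender"]


def read_phonation(path: str | Path) -> Phonation:
    """Read a PCM RIFF WAV as a mono [-1, 1] float signal.

    Multi-channel input is downmixed to mono with a warning; non-PCM or
    corrupt files raise :class:`InvalidAudioError`.
    """
    try:
        fs, data = wavfile.read(str(path))
    except Exception as exc:  # scipy raises bare ValueError on corrupt files
        raise InvalidAudioError(f"cannot read {path}: {exc}") from exc
    if data.ndim == 2:
        warnings.warn(f"{path}: multi-channel audio downmixed to mono")
        data = data.mean(axis=1)
    if data.dtype == np.int16:
        x = data.astype(float) / 32768.0
    elif data.dtype == np.int32:
        x = data.astype(float) / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(float) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        x = data.astype(float)
    else:
        raise InvalidAudioError(f"{path}: unsupported sample format {data.dtype}")
    return Phonation(x, float(fs), {"file": str(path)})


def write_phonation(p: Phonation, path: str | Path) -> None:
    """Write a phonation as 16-bit PCM RIFF WAV."""
    x = np.clip(p.samples, -1.0, 1.0 - 1.0 / 32768)
    wavfile.write(str(path), int(round(p.fs)), (x * 32768.0).round().astype(np.int16))


def write_feature_matrix(values: np.ndarray, names: list[str],
                         metadata: pd.DataFrame, path: str | Path) -> None:
    """Write metadata + named feature columns as full-precision CSV."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != len(names):
        raise ValueError("feature matrix shape does not match the manifest")
    if len(metadata) != values.shape[0]:
        raise ValueError("metadata rows do not match the feature matrix")
    df = pd.concat(
        [metadata.reset_index(drop=True),
         pd.DataFrame(values, columns=names)], axis=1)
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_matrix(path: str | Path, names: list[str] | None = None
                        ) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Read a feature-matrix CSV; verify the manifest when one is given."""
    df = pd.read_csv(path, float_precision="round_trip")
    meta_cols = [c for c in META_COLUMNS if c in df.columns]
    feat_cols = [c for c in df.columns if c not in meta_cols]
    if names is not None and feat_cols != list(names):
        raise ValueError("feature columns do not match the expected manifest")
    return df[feat_cols].to_numpy(dtype=float), feat_cols, df[meta_cols]
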