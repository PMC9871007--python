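"""Mel-spectrograms and MFCC features.

40 mel-frequency cepstral coefficients are computed per short frame
with an FFT window of 660 samples, hop of 512 samples, and Hann
windowing. The 40 x n_frames coefficient matrix is aggregated to a
fixed-length vector (per-coefficient temporal mean and standard
deviation, 80 dimensions by default) — a compact descriptor suited to
small-sample SVM training.

The short-time transform uses centered frames with reflect padding, so
n_frames = floor(n_samples / hop) + 1. Mel filters are triangles on the
HTK mel scale (mel = 2595 log10(1 + f/700)), area-normalized; the
cepstrum is an orthonormal DCT-II of the dB-scaled mel power spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import dct, rfft
from scipy.signal import get_window

from pulmokit.preprocess import DenoiseConfig, FixedWindow, preprocess_clip

AMIN = 1e-10  # log floor: makes silent-input output deterministic

AGGREGATION_MODES = ("mean_std", "flatten", "mean_only")


@dataclass(frozen=True)
class FeatureConfig:
    n_mfcc: int = 40
    fft_length: int = 660
    hop_length: int = 512
    window_function: str = "hann"
    n_mels: int = 128
    center_padding: bool = True

    def __post_init__(self) -> None:
        if self.fft_length <= 0 or self.hop_length <= 0:
            raise ValueError("fft_length and hop_length must be positive")
        if self.n_mfcc <= 0 or self.n_mels <= 0:
            raise ValueError("n_mfcc and n_mels must be positive")
        if self.n_mfcc > self.n_mels:
            raise ValueError("n_mfcc must not exceed n_mels")


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(sample_rate: float, n_fft: int, n_mels: int) -> np.ndarray:
    """Area-normalized triangular mel filters, shape (n_mels, n_fft//2 + 1)."""
    f_max = sample_rate / 2.0
    mel_pts = np.linspace(0.0, hz_to_mel(f_max), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    fft_freqs = np.linspace(0.0, f_max, n_fft // 2 + 1)
    fb = np.zeros((n_mels, fft_freqs.size))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / (ctr - lo)
        down = (hi - fft_freqs) / (hi - ctr)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
        fb[i] *= 2.0 / (hi - lo)  # equal-area normalization
    return fb


def filterbank_center_frequencies(
    sample_rate: float, n_mels: int
) -> np.ndarray:
    """Center frequency (Hz) of each mel band."""
    mel_pts = np.linspace(0.0, hz_to_mel(sample_rate / 2.0), n_mels + 2)
    return mel_to_hz(mel_pts[1:-1])


def _frame(x: np.ndarray, config: FeatureConfig) -> np.ndarray:
    """Centered, reflect-padded framing: (n_frames, fft_length)."""
    n_fft, hop = config.fft_length, config.hop_length
    if config.center_padding:
        x = np.pad(x, n_fft // 2, mode="reflect")
    if x.size < n_fft:
        raise ValueError(f"signal too short for fft_length={n_fft}")
    return sliding_window_view(x, n_fft)[::hop]


def power_spectrogram(x: np.ndarray, config: FeatureConfig) -> np.ndarray:
    """|STFT|^2 with Hann windowing; shape (n_fft//2 + 1, n_frames)."""
    frames = _frame(np.asarray(x, dtype=np.float64), config)
    win = get_window(config.window_function, config.fft_length, fftbins=True)
    return np.abs(rfft(frames * win, axis=1)).T ** 2


def mel_spectrogram(window: FixedWindow, config: FeatureConfig | None = None) -> np.ndarray:
    """Mel-band power spectrogram of a fixed window, shape (n_mels, n_frames)."""
    if config is None:
        config = FeatureConfig()
    P = power_spectrogram(window.samples, config)
    fb = mel_filterbank(window.sample_rate, config.fft_length, config.n_mels)
    return fb @ P


@dataclass(frozen=True)
class MFCCMatrix:
    values: np.ndarray  # (n_mfcc, n_frames)
    config: FeatureConfig
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.values.shape[0] != self.config.n_mfcc:
            raise ValueError("row count must equal n_mfcc")


def mfcc(window: FixedWindow, config: FeatureConfig | None = None) -> MFCCMatrix:
    """Mel-frequency cepstral coefficients, shape (n_mfcc, n_frames)."""
    if config is None:
        config = FeatureConfig()
    S = mel_spectrogram(window, config)
    log_S = 10.0 * np.log10(np.maximum(S, AMIN))
    coeffs = dct(log_S, type=2, axis=0, norm="ortho")[: config.n_mfcc]
    return MFCCMatrix(values=coeffs, config=config, source_id=window.source_clip_id)


def n_frames_expected(n_samples: int, config: FeatureConfig) -> int:
    """Frame count under the centered-padding convention."""
    if config.center_padding:
        return n_samples // config.hop_length + 1
    return (n_samples - config.fft_length) // config.hop_length + 1


def aggregate(matrix: MFCCMatrix, mode: str = "mean_std") -> np.ndarray:
    """Collapse an MFCC matrix to a fixed-length feature vector.

    mean_std: per-coefficient temporal mean then per-coefficient
    temporal standard deviation, concatenated (2 * n_mfcc values).
    """
    if mode not in AGGREGATION_MODES:
        raise ValueError(f"unknown aggregation mode {mode!r}; use one of {AGGREGATION_MODES}")
    v = matrix.values
    if mode == "mean_std":
        return np.concatenate([v.mean(axis=1), v.std(axis=1)])
    if mode == "mean_only":
        return v.mean(axis=1)
    return v.reshape(-1)  # flatten, row-major


def featurize_windows(
    windows,
    config: FeatureConfig | None = None,
    mode: str = "mean_std",
) -> pd.DataFrame:
    """Feature table from FixedWindows: one row per window plus label column."""
    if config is None:
        config = FeatureConfig()
    rows, labels, ids = [], [], []
    for w in windows:
        rows.append(aggregate(mfcc(w, config), mode))
        labels.append(w.label)
        ids.append(w.source_clip_id)
    if rows:
        values = np.vstack(rows)
    else:
        dim = 2 * config.n_mfcc if mode == "mean_std" else config.n_mfcc
        values = np.empty((0, dim))
    df = pd.DataFrame(values, columns=[f"f{i:03d}" for i in range(values.shape[1])])
    df.insert(0, "clip_id", ids)
    df["label"] = labels
    return df


def featurize_corpus(
    manifest: pd.DataFrame,
    audio_dir: str | Path,
    feature_config: FeatureConfig | None = None,
    denoise_config: DenoiseConfig | None = None,
    mode: str = "mean_std",
) -> pd.DataFrame:
    """Full feature table for a WAV corpus: read, denoise, window, MFCC.

    Raises with the offending clip_id if any referenced WAV is unreadable.
    """
    from pulmokit import audio_io

    audio_dir = Path(audio_dir)
    windows = []
    for row in manifest.itertuples(index=False):
        try:
            clip = audio_io.read_wav(audio_dir / row.path)
        except (IOError, FileNotFoundError) as exc:
            raise IOError(f"cannot read audio for clip {row.clip_id!r}: {exc}") from exc
        clip = audio_io.resample_clip(clip)
        clip = clip.with_label(row.label)
        from dataclasses import replace

        clip = replace(clip, clip_id=row.clip_id)
        windows.append(preprocess_clip(clip, denoise_config))
    return featurize_windows(windows, feature_config, mode)


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a feature table into (X, labels) for model training."""
    cols = [c for c in table.columns if c.startswith("f") and c[1:].isdigit()]
    return table[cols].to_numpy(dtype=np.float64), table["label"].to_numpy()
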