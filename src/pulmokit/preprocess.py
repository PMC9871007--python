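"""Denoising and fixed-length windowing.

Clips are first denoised with BayesShrink soft-threshold wavelet
shrinkage (noise sigma estimated from the finest detail band as
median(|d|)/0.6745, per-subband threshold sigma_noise^2 / sigma_signal),
then converted to exactly-6-second windows: longer clips are cropped to
their first 6 s, shorter ones tiled whole until longer than 6 s and
cropped. 6 s spans 1-4 breaths across the pediatric-to-adult
respiratory-rate range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pywt
from skimage.restoration import denoise_wavelet

from pulmokit.synth import AudioClip

WINDOW_SECONDS = 6.0


@dataclass(frozen=True)
class DenoiseConfig:
    """BayesShrink configuration.

    decomposition_levels=None selects floor(log2(n)) - 6, capped to
    [1, 6] — enough levels to reach the sub-200 Hz bands where lung
    sound energy lives without over-decomposing short clips.
    """

    wavelet_name: str = "sym8"
    decomposition_levels: int | None = None
    threshold_mode: str = "soft"

    def __post_init__(self) -> None:
        if self.decomposition_levels is not None and self.decomposition_levels < 1:
            raise ValueError("decomposition_levels must be >= 1")
        if self.threshold_mode != "soft":
            raise ValueError("only soft thresholding is supported")


def _auto_levels(n: int) -> int:
    return int(np.clip(math.floor(math.log2(n)) - 6, 1, 6))


def denoise(x: np.ndarray, config: DenoiseConfig | None = None) -> np.ndarray:
    """BayesShrink soft-threshold wavelet denoising; length-preserving."""
    if config is None:
        config = DenoiseConfig()
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a non-empty 1-D array")
    levels = config.decomposition_levels
    if levels is None:
        levels = _auto_levels(x.size)
    max_levels = pywt.dwt_max_level(x.size, config.wavelet_name)
    if levels > max_levels:
        raise ValueError(
            f"signal of length {x.size} supports at most {max_levels} "
            f"{config.wavelet_name} levels, requested {levels}"
        )
    if not np.any(x):
        return np.zeros_like(x)
    return denoise_wavelet(
        x,
        wavelet=config.wavelet_name,
        method="BayesShrink",
        mode=config.threshold_mode,
        wavelet_levels=levels,
        rescale_sigma=True,
    )


def window_6s(x: np.ndarray, sample_rate: int) -> np.ndarray:
    """Duplicate-and-crop to an exactly 6-second window.

    Signals of at least 6 s are cropped to their first 6 s; shorter
    signals are concatenated with whole copies of themselves until
    longer than 6 s, then cropped.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a non-empty 1-D array")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    target = int(round(WINDOW_SECONDS * sample_rate))
    if x.size < target:
        reps = -(-target // x.size)  # ceil: whole copies until > target
        x = np.tile(x, reps)
    return x[:target].copy()


@dataclass(frozen=True)
class FixedWindow:
    """An exactly-6-second waveform ready for feature extraction."""

    samples: np.ndarray
    sample_rate: int
    source_clip_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        target = int(round(WINDOW_SECONDS * self.sample_rate))
        if samples.size != target:
            raise ValueError(
                f"FixedWindow requires exactly {target} samples at "
                f"{self.sample_rate} Hz, got {samples.size}"
            )


def preprocess_clip(
    clip: AudioClip, config: DenoiseConfig | None = None, normalize: bool = True
) -> FixedWindow:
    """Denoise the full clip, then window to 6 s; label and id propagate.

    Windows are peak-normalized by default so downstream features are
    invariant to recording gain.
    """
    y = denoise(clip.samples, config)
    w = window_6s(y, clip.sample_rate)
    if normalize:
        peak = np.max(np.abs(w))
        if peak > 0:
            w = w / peak
    return FixedWindow(
        samples=w,
        sample_rate=clip.sample_rate,
        source_clip_id=clip.clip_id,
        label=clip.label,
    )
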