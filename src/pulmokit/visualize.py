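"""Mel-spectrogram rendering and 2-D UMAP embeddings of feature vectors."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from pulmokit.features import (
    FeatureConfig,
    filterbank_center_frequencies,
    mel_spectrogram,
)
from pulmokit.preprocess import FixedWindow

DB_RANGE = 80.0  # dynamic-range floor for rendering


@dataclass(frozen=True)
class EmbeddingConfig:
    n_neighbors: int = 20
    min_dist: float = 0.3
    metric: str = "cosine"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if self.min_dist < 0:
            raise ValueError("min_dist must be >= 0")


@dataclass(frozen=True)
class Embedding2D:
    coordinates: np.ndarray  # (n, 2)
    labels: tuple
    config: EmbeddingConfig

    def __post_init__(self) -> None:
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValueError("coordinates must be n x 2")
        if len(self.labels) != self.coordinates.shape[0]:
            raise ValueError("labels must align with coordinate rows")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.coordinates[:, 0], "y": self.coordinates[:, 1], "label": self.labels}
        )


def mel_spectrogram_db(window: FixedWindow, config: FeatureConfig | None = None) -> np.ndarray:
    """Log-power mel spectrogram clipped to an 80 dB dynamic range."""
    if config is None:
        config = FeatureConfig()
    S = mel_spectrogram(window, config)
    S_db = 10.0 * np.log10(np.maximum(S, 1e-10))
    return np.maximum(S_db, S_db.max() - DB_RANGE)


def render_mel_spectrogram(
    window: FixedWindow,
    out_path: str | Path,
    config: FeatureConfig | None = None,
) -> Path:
    """Write a mel-spectrogram image (time in s, frequency in Hz on mel axis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if config is None:
        config = FeatureConfig()
    out_path = Path(out_path)
    S_db = mel_spectrogram_db(window, config)
    duration = window.samples.size / window.sample_rate
    centers = filterbank_center_frequencies(window.sample_rate, config.n_mels)

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(
        S_db,
        origin="lower",
        aspect="auto",
        extent=[0.0, duration, 0, config.n_mels],
        cmap="magma",
    )
    ticks = np.linspace(0, config.n_mels - 1, 6).astype(int)
    ax.set_yticks(ticks + 0.5)
    ax.set_yticklabels([f"{centers[t]:.0f}" for t in ticks])
    ax.set_xlabel("Time (s)")
    ax.set_ylabel("Frequency (Hz, mel scale)")
    title = window.label or window.source_clip_id or "mel-spectrogram"
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="dB")
    fig.tight_layout()
    try:
        fig.savefig(out_path)
    except OSError as exc:
        raise IOError(f"cannot write spectrogram image to {out_path}: {exc}") from exc
    finally:
        plt.close(fig)
    return out_path


def umap_embed(feature_table: pd.DataFrame, config: EmbeddingConfig | None = None) -> Embedding2D:
    """2-D UMAP embedding of the feature rows; row order is preserved.

    Seeded for reproducibility (which disables UMAP's parallel layout;
    testability outranks embedding aesthetics here).
    """
    if config is None:
        config = EmbeddingConfig()
    from pulmokit.features import feature_matrix

    X, labels = feature_matrix(feature_table)
    if X.shape[0] < config.n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors + 1 = {config.n_neighbors + 1} rows, got {X.shape[0]}"
        )
    import warnings

    import umap

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=config.n_neighbors,
            min_dist=config.min_dist,
            metric=config.metric,
            random_state=config.seed,
        )
        coords = reducer.fit_transform(X)
    return Embedding2D(np.asarray(coords, dtype=np.float64), tuple(labels), config)


def plot_embedding(embedding: Embedding2D, out_path: str | Path) -> Path:
    """Scatter plot of a 2-D embedding colored by class label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    df = embedding.to_frame()
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, group in df.groupby("label"):
        ax.scatter(group["x"], group["y"], s=12, label=str(label), alpha=0.8)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return out_path
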