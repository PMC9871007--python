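"""WAV and manifest I/O, plus ICBHI-2017-style annotation handling.

The ICBHI 2017 Challenge Respiratory Sound Database annotates each
recording with plain-text rows of (cycle start, cycle end, crackle
flag, wheeze flag); this module parses those rows and slices
recordings into per-cycle labeled clips for external validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from pulmokit.synth import LABELS, AudioClip

PIPELINE_SAMPLE_RATE = 44_100


@dataclass(frozen=True)
class ICBHICycle:
    cycle_start: float
    cycle_end: float
    crackle_flag: int
    wheeze_flag: int

    def __post_init__(self) -> None:
        if not self.cycle_start < self.cycle_end:
            raise ValueError(
                f"cycle_start must precede cycle_end, got [{self.cycle_start}, {self.cycle_end}]"
            )
        if self.crackle_flag not in (0, 1) or self.wheeze_flag not in (0, 1):
            raise ValueError("crackle/wheeze flags must be 0 or 1")


@dataclass(frozen=True)
class ICBHIAnnotation:
    """Per-recording breath-cycle annotation, rows sorted by cycle start."""

    cycles: tuple[ICBHICycle, ...]
    recording_id: str = ""

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.cycles, key=lambda c: c.cycle_start))
        object.__setattr__(self, "cycles", ordered)
        for prev, cur in zip(ordered, ordered[1:]):
            if cur.cycle_start < prev.cycle_end - 1e-9:
                raise ValueError(
                    f"overlapping cycles: [{prev.cycle_start}, {prev.cycle_end}] and "
                    f"[{cur.cycle_start}, {cur.cycle_end}]"
                )

    def __len__(self) -> int:
        return len(self.cycles)


def read_wav(path: str | Path) -> AudioClip:
    """Read a WAV file into an unlabeled :class:`AudioClip`.

    Integer PCM is scaled to [-1, 1]; stereo input is averaged to mono.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"WAV file not found: {path}")
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # corrupt container
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    data = np.asarray(data)
    dtype = data.dtype  # before downmix: averaging promotes to float
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        scale = float(max(abs(info.min), info.max))
        offset = 0.0
        if info.min == 0:  # unsigned PCM (e.g. uint8) is offset-binary
            offset = (info.max + 1) / 2.0
            scale = offset
        data = (data.astype(np.float64) - offset) / scale
    else:
        data = data.astype(np.float64)
    data = np.clip(data, -1.0, 1.0)
    return AudioClip(samples=data, sample_rate=int(rate), clip_id=path.stem)


def write_wav(
    path: str | Path,
    samples: np.ndarray,
    sample_rate: int,
    subtype: str = "pcm16",
) -> None:
    """Write float samples in [-1, 1] to a mono WAV file."""
    samples = np.asarray(samples, dtype=np.float64)
    if subtype == "pcm16":
        data = np.clip(np.round(samples * 32768.0), -32768, 32767).astype(np.int16)
    elif subtype == "float32":
        data = samples.astype(np.float32)
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")
    wavfile.write(Path(path), int(sample_rate), data)


def resample_clip(clip: AudioClip, target_rate: int = PIPELINE_SAMPLE_RATE) -> AudioClip:
    """Resample a clip to the pipeline rate (polyphase, rational ratio)."""
    if clip.sample_rate == target_rate:
        return clip
    from dataclasses import replace
    from math import gcd

    g = gcd(target_rate, clip.sample_rate)
    out = resample_poly(clip.samples, target_rate // g, clip.sample_rate // g)
    out = np.clip(out, -1.0, 1.0)
    return replace(clip, samples=out, sample_rate=target_rate)


def parse_icbhi_annotation(path: str | Path) -> ICBHIAnnotation:
    """Parse an ICBHI annotation file: 4 whitespace-delimited numeric columns.

    Columns are cycle start (s), cycle end (s), crackle flag, wheeze flag.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    cycles = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            try:
                start, end = float(fields[0]), float(fields[1])
                crk, whz = int(float(fields[2])), int(float(fields[3]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
            try:
                cycles.append(ICBHICycle(start, end, crk, whz))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return ICBHIAnnotation(tuple(cycles), recording_id=path.stem)


def icbhi_cycle_to_label(crackle_flag: int, wheeze_flag: int) -> str:
    """Map ICBHI per-cycle flags to a class label.

    (0,0) -> normal, (1,0) -> crackles, (0,1) -> wheezing, (1,1) -> "both"
    (cycles bearing both flags are excluded from the three-class tasks).
    """
    if crackle_flag not in (0, 1) or wheeze_flag not in (0, 1):
        raise ValueError(f"flags must be 0/1, got ({crackle_flag}, {wheeze_flag})")
    return {
        (0, 0): "normal",
        (1, 0): "crackles",
        (0, 1): "wheezing",
        (1, 1): "both",
    }[(crackle_flag, wheeze_flag)]


def extract_cycles(recording: AudioClip, ann: ICBHIAnnotation) -> list[AudioClip]:
    """Slice a recording into labeled per-cycle clips.

    Slices are half-open [start, end) with sample indices floor(t * sr),
    so adjacent cycles sharing a boundary never overlap. Cycles bearing
    both flags get label=None and are excluded from three-class tasks.
    """
    sr = recording.sample_rate
    n = recording.samples.size
    clips = []
    for i, cyc in enumerate(ann.cycles):
        i0, i1 = int(cyc.cycle_start * sr), int(cyc.cycle_end * sr)
        if i1 > n:
            raise ValueError(
                f"annotation row {i} ([{cyc.cycle_start}, {cyc.cycle_end}] s) "
                f"exceeds recording duration {n / sr:.3f} s"
            )
        label = icbhi_cycle_to_label(cyc.crackle_flag, cyc.wheeze_flag)
        clips.append(
            AudioClip(
                samples=recording.samples[i0:i1],
                sample_rate=sr,
                label=None if label == "both" else label,
                clip_id=f"{ann.recording_id or recording.clip_id}-cycle{i:03d}",
            )
        )
    return clips


def class_counts(labels) -> dict[str, int]:
    """Composition counts over {normal, crackles, wheezing, both}."""
    counts = {"normal": 0, "crackles": 0, "wheezing": 0, "both": 0}
    for lab in labels:
        counts[lab if lab is not None else "both"] += 1
    return counts


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a corpus manifest CSV; validates clip_id uniqueness and labels."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"clip_id", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    if df["clip_id"].duplicated().any():
        dupes = df.loc[df["clip_id"].duplicated(), "clip_id"].tolist()
        raise ValueError(f"manifest {path} has duplicate clip_ids: {dupes[:5]}")
    bad = set(df["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"manifest {path} has unknown labels: {sorted(bad)}")
    return df
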