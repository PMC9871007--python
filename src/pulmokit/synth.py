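"""Physics-informed synthesis of pediatric auscultation audio.

Generates labeled clips of normal (vesicular), crackle, and wheeze lung
sounds with the acoustic structure described in the respiratory-sound
literature:

* vesicular sound — non-musical low-pass-filtered noise whose spectral
  energy drops around 200 Hz, amplitude-modulated by the breath cycle
  (loudest during inspiration and early expiration);
* wheezes — sinusoidal (mildly harmonic, slowly drifting) oscillations
  with energy between 100 and 1000 Hz lasting longer than 80 ms;
* crackles — rapidly damped sinusoidal deflections, typically 650 Hz /
  5 ms for fine crackles and 350 Hz / 15 ms for coarse crackles;
* heart sounds — periodic S1/S2 pairs of low-frequency (20–100 Hz)
  damped oscillations, the dominant contaminant in pediatric chests.

Corpus-level distributions (clip length, respiratory rate, heart-sound
prevalence) default to the characteristics of a pediatric pulmonology
clinic population: mean clip length 4.1 s (sd 1.8), mean respiratory
rate 30.2/min (sd 13.4), heart sounds audible in 75% of clips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

LABELS = ("normal", "crackles", "wheezing")
CRACKLE_KINDS = ("fine_crackle", "coarse_crackle")

#: canonical (center frequency Hz, duration s) per crackle kind
CRACKLE_DEFAULTS = {"fine_crackle": (650.0, 0.005), "coarse_crackle": (350.0, 0.015)}

WHEEZE_MIN_DURATION = 0.080  # s; definitional lower bound
WHEEZE_FREQ_RANGE = (100.0, 1000.0)  # Hz; definitional band


@dataclass(frozen=True)
class BreathCycleSpec:
    """Breathing pattern of one clip.

    respiratory_rate is in breaths/min; one cycle lasts 60/rate seconds.
    inspiration_fraction is the inspiratory share of the cycle (0..1).
    cycle_count is the number of breath cycles the clip was labeled
    with (clinically clips contain one or two cycles).
    """

    respiratory_rate: float
    inspiration_fraction: float = 0.4
    cycle_count: int = 2

    def __post_init__(self) -> None:
        if self.respiratory_rate <= 0:
            raise ValueError(f"respiratory_rate must be > 0, got {self.respiratory_rate}")
        if not 0.0 < self.inspiration_fraction < 1.0:
            raise ValueError("inspiration_fraction must lie in (0, 1)")
        if self.cycle_count not in (1, 2):
            raise ValueError(f"cycle_count must be 1 or 2, got {self.cycle_count}")

    @property
    def cycle_duration(self) -> float:
        """Seconds per breath cycle."""
        return 60.0 / self.respiratory_rate


@dataclass(frozen=True)
class EventSpec:
    """A single adventitious sound event inside a clip.

    amplitude is expressed relative to the RMS of the vesicular base
    sound; onset is seconds from clip start.
    """

    kind: str
    center_frequency: float
    duration: float
    onset: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kind == "wheeze":
            lo, hi = WHEEZE_FREQ_RANGE
            if not lo <= self.center_frequency <= hi:
                raise ValueError(
                    f"wheeze center frequency must lie in [{lo:g}, {hi:g}] Hz, "
                    f"got {self.center_frequency:g}"
                )
            if self.duration <= WHEEZE_MIN_DURATION:
                raise ValueError(
                    f"wheeze duration must exceed {WHEEZE_MIN_DURATION * 1000:g} ms, "
                    f"got {self.duration * 1000:g} ms"
                )
        elif self.kind in CRACKLE_KINDS:
            if self.duration <= 0:
                raise ValueError("crackle duration must be positive")
            if self.center_frequency <= 0:
                raise ValueError("crackle center frequency must be positive")
        else:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.onset < 0:
            raise ValueError("onset must be non-negative")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    @classmethod
    def fine_crackle(cls, onset: float = 0.0, amplitude: float = 1.0) -> "EventSpec":
        f, d = CRACKLE_DEFAULTS["fine_crackle"]
        return cls("fine_crackle", f, d, onset, amplitude)

    @classmethod
    def coarse_crackle(cls, onset: float = 0.0, amplitude: float = 1.0) -> "EventSpec":
        f, d = CRACKLE_DEFAULTS["coarse_crackle"]
        return cls("coarse_crackle", f, d, onset, amplitude)


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults emulate a pediatric clinic corpus."""

    sample_rate: int = 44_100
    clip_length_mean: float = 4.1
    clip_length_sd: float = 1.8
    clip_length_bounds: tuple[float, float] = (1.5, 10.0)
    resp_rate_mean: float = 30.2
    resp_rate_sd: float = 13.4
    resp_rate_bounds: tuple[float, float] = (12.0, 80.0)
    inspiration_fraction_range: tuple[float, float] = (0.30, 0.45)
    heart_sound_probability: float = 0.75
    heart_rate_range: tuple[float, float] = (80.0, 160.0)
    class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    vesicular_corner_frequency: float = 200.0
    snr_range: tuple[float, float] = (15.0, 30.0)
    # event placement (not reported clinically; chosen for spectrogram realism)
    crackles_per_inspiration: tuple[int, int] = (3, 10)
    wheeze_count_range: tuple[int, int] = (1, 2)
    wheeze_phase_coverage: tuple[float, float] = (0.3, 0.9)
    wheeze_freq_range: tuple[float, float] = (200.0, 900.0)
    wheeze_amplitude_range: tuple[float, float] = (1.0, 2.5)
    crackle_amplitude_range: tuple[float, float] = (3.0, 6.0)
    heart_amplitude: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for name in ("clip_length_sd", "resp_rate_sd", "vesicular_corner_frequency"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if any(p < 0 for p in self.class_mix):
            raise ValueError("class_mix proportions must be non-negative")
        for name in ("clip_length_bounds", "resp_rate_bounds"):
            lo, hi = getattr(self, name)
            mean = getattr(self, name.replace("_bounds", "_mean"))
            if not lo < mean < hi:
                raise ValueError(f"{name} must contain the mean")
        if not 0.0 <= self.heart_sound_probability <= 1.0:
            raise ValueError("heart_sound_probability must lie in [0, 1]")


@dataclass(frozen=True)
class AudioClip:
    """A labeled mono waveform plus its generation/recording metadata."""

    samples: np.ndarray
    sample_rate: int
    label: str | None = None
    breath_spec: BreathCycleSpec | None = None
    events: tuple[EventSpec, ...] = ()
    heart_sound_present: bool = False
    clip_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if np.max(np.abs(samples)) > 1.0 + 1e-9:
            raise ValueError("samples must lie within [-1, 1]")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        # event metadata exists only for generated clips; recorded clips
        # carry labels without per-event annotations
        if self.events:
            if self.label == "normal":
                raise ValueError("normal clips must carry no adventitious events")
            if self.label == "crackles" and not all(
                e.kind in CRACKLE_KINDS for e in self.events
            ):
                raise ValueError("crackle clips may only carry crackle events")
            if self.label == "wheezing" and not any(
                e.kind == "wheeze" for e in self.events
            ):
                raise ValueError("wheezing clips must carry at least one wheeze event")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def with_label(self, label: str) -> "AudioClip":
        return replace(self, label=label)


# ---------------------------------------------------------------------------
# waveform primitives


def _n_samples(duration: float, sample_rate: float) -> int:
    return int(round(duration * sample_rate))


def breath_envelope(
    spec: BreathCycleSpec, duration: float, sample_rate: float
) -> np.ndarray:
    """Amplitude envelope of the breath cycle, values in [0, 1].

    The envelope rises through inspiration to a single per-cycle maximum
    at the inspiration/expiration boundary, decays through early
    expiration, and sits at a low floor in late expiration — matching
    the clinical picture of vesicular sound heard mainly during
    inspiration and early expiration.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    n = _n_samples(duration, sample_rate)
    t = np.arange(n) / sample_rate
    u = (t / spec.cycle_duration) % 1.0  # phase within cycle
    fi = spec.inspiration_fraction
    floor = 0.1
    env = np.empty(n)
    insp = u < fi
    env[insp] = floor + (1 - floor) * np.sin(0.5 * np.pi * u[insp] / fi)
    v = (u[~insp] - fi) / (1 - fi)  # expiratory phase in [0, 1)
    decay = np.clip(v / 0.6, 0.0, 1.0)  # decays over first 60% of expiration
    env[~insp] = floor + (1 - floor) * np.cos(0.5 * np.pi * decay)
    return env


def synth_vesicular(
    duration: float,
    config: SynthConfig,
    seed: int | np.random.SeedSequence = 0,
    breath_spec: BreathCycleSpec | None = None,
) -> np.ndarray:
    """Vesicular (normal) breath sound: low-pass noise under the breath envelope.

    Gaussian noise is shaped by a 2nd-order Butterworth low-pass whose
    -3 dB point sits at ``config.vesicular_corner_frequency`` and is then
    modulated by :func:`breath_envelope`.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if breath_spec is None:
        breath_spec = BreathCycleSpec(config.resp_rate_mean)
    rng = np.random.default_rng(seed)
    n = _n_samples(duration, config.sample_rate)
    noise = rng.standard_normal(n)
    sos = signal.butter(
        2, config.vesicular_corner_frequency, "lowpass", fs=config.sample_rate, output="sos"
    )
    shaped = signal.sosfilt(sos, noise)
    return shaped * breath_envelope(breath_spec, duration, config.sample_rate)


def synth_wheeze_event(
    spec: EventSpec,
    sample_rate: float,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """A wheeze: tonal segment with mild harmonics and slow frequency drift.

    The instantaneous frequency drifts smoothly within +/-5% of the
    center frequency; weak 2nd/3rd harmonics add the reedy timbre of a
    narrowed airway. Edges are tapered to avoid onset clicks.
    """
    if spec.kind != "wheeze":
        raise ValueError(f"expected a wheeze EventSpec, got kind={spec.kind!r}")
    rng = np.random.default_rng(seed)
    n = _n_samples(spec.duration, sample_rate)
    t = np.arange(n) / sample_rate
    drift_hz = rng.uniform(0.5, 2.0)  # slow modulation
    drift_depth = rng.uniform(0.0, 0.05)
    phase0 = rng.uniform(0, 2 * np.pi)
    f_inst = spec.center_frequency * (
        1.0 + drift_depth * np.sin(2 * np.pi * drift_hz * t + phase0)
    )
    phase = 2 * np.pi * np.cumsum(f_inst) / sample_rate
    wave = np.sin(phase) + 0.25 * np.sin(2 * phase) + 0.08 * np.sin(3 * phase)
    taper = signal.windows.tukey(n, alpha=0.2)
    wave *= taper
    return wave / np.max(np.abs(wave))


def synth_crackle_event(spec: EventSpec, sample_rate: float) -> np.ndarray:
    """A crackle: exponentially damped sinusoid A*exp(-t/tau)*sin(2*pi*f*t).

    tau = duration/3.1, so the envelope decays below 5% of its peak
    (exp(-3.1) ~= 4.5%) at ``spec.duration``.
    """
    if spec.kind not in CRACKLE_KINDS:
        raise ValueError(f"expected a crackle EventSpec, got kind={spec.kind!r}")
    tau = spec.duration / 3.1
    # render two durations so the tail decays smoothly to ~0.25% of peak
    n = max(_n_samples(2 * spec.duration, sample_rate), 8)
    t = np.arange(n) / sample_rate
    # unit analytic envelope (A=1): |wave| <= exp(-t/tau) by construction
    return np.exp(-t / tau) * np.sin(2 * np.pi * spec.center_frequency * t)


def synth_heart_sounds(
    duration: float,
    heart_rate: float,
    sample_rate: float,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Periodic S1/S2 heart-sound pairs of low-frequency damped oscillations.

    S1 (louder, ~45 Hz) falls at every multiple of the beat period;
    S2 (softer, ~55 Hz) follows at 30% of the period, approximating the
    systolic interval. All spectral content stays well below 150 Hz.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if heart_rate <= 0:
        raise ValueError(f"heart_rate must be positive, got {heart_rate}")
    rng = np.random.default_rng(seed)
    n = _n_samples(duration, sample_rate)
    out = np.zeros(n)
    period = 60.0 / heart_rate

    def add_burst(onset: float, freq: float, amp: float, tau: float) -> None:
        i0 = int(round(onset * sample_rate))
        if i0 >= n:
            return
        m = min(_n_samples(6 * tau, sample_rate), n - i0)
        t = np.arange(m) / sample_rate
        out[i0 : i0 + m] += amp * np.exp(-t / tau) * np.sin(2 * np.pi * freq * t)

    k = 0
    while k * period < duration:
        jitter = rng.uniform(0.9, 1.1)
        add_burst(k * period, 45.0, 1.0 * jitter, 0.030)
        add_burst(k * period + 0.3 * period, 55.0, 0.45 * jitter, 0.022)
        k += 1
    peak = np.max(np.abs(out))
    return out / peak if peak > 0 else out


# ---------------------------------------------------------------------------
# clip composition


def _matched_truncnorm(
    mean: float, sd: float, bounds: tuple[float, float]
) -> stats.rv_continuous:
    """Truncated normal on ``bounds`` whose *truncated* mean equals ``mean``.

    Truncating N(mean, sd) to an asymmetric interval shifts its mean, so
    the location parameter is solved (moment matching) to keep the
    corpus-level sample mean on target.
    """
    lo, hi = bounds

    def tn_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    loc = optimize.brentq(lambda m: tn_mean(m) - mean, lo - 5 * sd, hi + 5 * sd)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm(a, b, loc=loc, scale=sd)


def _inspiratory_segments(
    breath_spec: BreathCycleSpec, duration: float
) -> list[tuple[float, float]]:
    """(start, end) of every inspiratory segment intersecting [0, duration]."""
    T = breath_spec.cycle_duration
    segs = []
    k = 0
    while k * T < duration:
        start, end = k * T, min(k * T + breath_spec.inspiration_fraction * T, duration)
        if end - start > 1e-6:
            segs.append((start, end))
        k += 1
    return segs


def _expiratory_segments(
    breath_spec: BreathCycleSpec, duration: float
) -> list[tuple[float, float]]:
    T = breath_spec.cycle_duration
    segs = []
    k = 0
    while k * T < duration:
        start = k * T + breath_spec.inspiration_fraction * T
        end = min((k + 1) * T, duration)
        if end - start > 1e-6:
            segs.append((start, end))
        k += 1
    return segs


def _draw_crackle_events(
    rng: np.random.Generator, config: SynthConfig, breath_spec: BreathCycleSpec, duration: float
) -> list[EventSpec]:
    events: list[EventSpec] = []
    insp = _inspiratory_segments(breath_spec, duration)
    exp = _expiratory_segments(breath_spec, duration)
    lo, hi = config.crackles_per_inspiration
    for seg in insp:
        n_crk = int(rng.integers(lo, hi + 1))
        for _ in range(n_crk):
            kind = "fine_crackle" if rng.random() < 0.5 else "coarse_crackle"
            f0, d0 = CRACKLE_DEFAULTS[kind]
            # mostly inspiratory; occasionally spills into early expiration
            if rng.random() < 0.9 or not exp:
                a, b = seg
            else:
                a, b = exp[int(rng.integers(len(exp)))]
                b = a + 0.4 * (b - a)
            dur = d0 * rng.uniform(0.8, 1.2)
            onset = rng.uniform(a, max(a, b - 2 * dur))
            events.append(
                EventSpec(
                    kind,
                    f0 * rng.uniform(0.9, 1.1),
                    dur,
                    onset,
                    rng.uniform(*config.crackle_amplitude_range),
                )
            )
    return events


def _draw_wheeze_events(
    rng: np.random.Generator, config: SynthConfig, breath_spec: BreathCycleSpec, duration: float
) -> list[EventSpec]:
    events: list[EventSpec] = []
    phases = _inspiratory_segments(breath_spec, duration) + _expiratory_segments(
        breath_spec, duration
    )
    phases = [p for p in phases if p[1] - p[0] > 0.12]
    lo, hi = config.wheeze_count_range
    n_whz = int(rng.integers(lo, hi + 1))
    for _ in range(max(n_whz, 1)):
        a, b = phases[int(rng.integers(len(phases)))]
        coverage = rng.uniform(*config.wheeze_phase_coverage)
        # floor at 100 ms keeps every wheeze above the 80 ms definition
        # even in the shortest physiologic breath phases
        dur = min(max(coverage * (b - a), 0.100), b - a)
        onset = rng.uniform(a, b - dur)
        events.append(
            EventSpec(
                "wheeze",
                rng.uniform(*config.wheeze_freq_range),
                dur,
                onset,
                rng.uniform(*config.wheeze_amplitude_range),
            )
        )
    return events


def synth_clip(label: str, config: SynthConfig | None = None, seed: int = 0) -> AudioClip:
    """Synthesize one labeled auscultation clip.

    Clip length and respiratory rate are drawn from moment-matched
    truncated normals; the vesicular base is overlaid with
    class-conditional events (crackles predominantly inspiratory,
    wheezes in inspiratory and/or expiratory phases), heart sounds with
    probability ``heart_sound_probability``, and ambient white noise at
    an SNR drawn from ``snr_range``. Output is peak-normalized to 0.9.
    Fully deterministic given (label, config, seed).
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    if config is None:
        config = SynthConfig()
    ss = np.random.SeedSequence(seed)
    ss_draw, ss_ves, ss_evt, ss_heart = ss.spawn(4)
    rng = np.random.default_rng(ss_draw)

    duration = float(
        _matched_truncnorm(
            config.clip_length_mean, config.clip_length_sd, config.clip_length_bounds
        ).rvs(random_state=rng)
    )
    resp_rate = float(
        _matched_truncnorm(
            config.resp_rate_mean, config.resp_rate_sd, config.resp_rate_bounds
        ).rvs(random_state=rng)
    )
    insp_frac = rng.uniform(*config.inspiration_fraction_range)
    cycle_count = int(np.clip(round(duration * resp_rate / 60.0), 1, 2))
    breath_spec = BreathCycleSpec(resp_rate, insp_frac, cycle_count)

    x = synth_vesicular(duration, config, ss_ves, breath_spec)
    ves_rms = float(np.sqrt(np.mean(x**2)))
    n = x.size

    rng_evt = np.random.default_rng(ss_evt)
    if label == "crackles":
        events = _draw_crackle_events(rng_evt, config, breath_spec, duration)
    elif label == "wheezing":
        events = _draw_wheeze_events(rng_evt, config, breath_spec, duration)
    else:
        events = []

    for ev in events:
        if ev.kind == "wheeze":
            seg = synth_wheeze_event(ev, config.sample_rate, rng_evt.integers(2**31))
        else:
            seg = synth_crackle_event(ev, config.sample_rate)
        i0 = int(round(ev.onset * config.sample_rate))
        m = min(seg.size, n - i0)
        if m > 0:
            x[i0 : i0 + m] += ev.amplitude * ves_rms * seg[:m]

    heart_present = rng.random() < config.heart_sound_probability
    if heart_present:
        heart_rate = rng.uniform(*config.heart_rate_range)
        x += config.heart_amplitude * ves_rms * synth_heart_sounds(
            duration, heart_rate, config.sample_rate, ss_heart
        )

    snr_db = rng.uniform(*config.snr_range)
    sig_rms = float(np.sqrt(np.mean(x**2)))
    noise_rms = sig_rms * 10.0 ** (-snr_db / 20.0)
    x += noise_rms * rng.standard_normal(n)

    x *= 0.9 / np.max(np.abs(x))
    return AudioClip(
        samples=x,
        sample_rate=config.sample_rate,
        label=label,
        breath_spec=breath_spec,
        events=tuple(events),
        heart_sound_present=heart_present,
        clip_id=f"syn-{label}-{seed}",
    )


MANIFEST_COLUMNS = [
    "clip_id",
    "path",
    "label",
    "length_s",
    "respiratory_rate",
    "cycle_count",
    "heart_sound_present",
    "seed",
]


def generate_corpus(
    config: SynthConfig | None = None,
    n: int = 100,
    out_dir: str | None = None,
    write_audio: bool = True,
    label_counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Generate ``n`` labeled clips and their CSV manifest.

    Labels are drawn from ``config.class_mix`` (or fixed per-class
    counts via ``label_counts``, shuffled); each clip gets its own child
    seed (recorded in the manifest, so any clip is reproducible in
    isolation). With ``out_dir`` set, clips are written as 16-bit PCM
    WAV plus ``manifest.csv``; with ``write_audio=False`` only the
    manifest rows are produced (the parameter draws are identical either
    way). Returns the manifest as a DataFrame.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if config is None:
        config = SynthConfig()
    from pulmokit import audio_io  # deferred: avoid import cycle

    root = np.random.default_rng(config.seed)
    if label_counts is not None:
        if sum(label_counts.values()) != n:
            raise ValueError("label_counts must sum to n")
        if set(label_counts) - set(LABELS):
            raise ValueError(f"label_counts keys must be among {LABELS}")
        label_idx = np.repeat(
            [LABELS.index(lab) for lab in LABELS if lab in label_counts],
            [label_counts[lab] for lab in LABELS if lab in label_counts],
        )
        root.shuffle(label_idx)
    else:
        label_idx = root.choice(len(LABELS), size=n, p=np.asarray(config.class_mix))
    clip_seeds = root.integers(0, 2**31 - 1, size=n)

    out_path = None
    if out_dir is not None:
        from pathlib import Path

        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)

    rows = []
    for i in range(n):
        label = LABELS[label_idx[i]]
        seed_i = int(clip_seeds[i])
        clip = synth_clip(label, config, seed_i)
        clip_id = f"clip{i:05d}-{label}"
        wav_name = f"{clip_id}.wav"
        if out_path is not None and write_audio:
            audio_io.write_wav(out_path / wav_name, clip.samples, clip.sample_rate)
        rows.append(
            {
                "clip_id": clip_id,
                "path": wav_name,
                "label": label,
                "length_s": clip.duration,
                "respiratory_rate": clip.breath_spec.respiratory_rate,
                "cycle_count": clip.breath_spec.cycle_count,
                "heart_sound_present": clip.heart_sound_present,
                "seed": seed_i,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return manifest
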