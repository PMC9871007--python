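"""Generator tests: acoustic structure of events, corpus statistics, determinism."""

import numpy as np
import pytest
from scipy import signal

from pulmokit import synth
from pulmokit.synth import (
    AudioClip,
    BreathCycleSpec,
    EventSpec,
    SynthConfig,
    breath_envelope,
    generate_corpus,
    synth_clip,
    synth_crackle_event,
    synth_heart_sounds,
    synth_vesicular,
    synth_wheeze_event,
)

SR = 44_100


def spectral_peak_hz(x, sr=SR, pad_to=None):
    spec = np.abs(np.fft.rfft(x, pad_to or x.size))
    freqs = np.fft.rfftfreq(pad_to or x.size, 1 / sr)
    return freqs[np.argmax(spec)]


class TestBreathEnvelope:
    def test_two_cycles_two_maxima(self):
        spec = BreathCycleSpec(30, 0.4, 2)
        env = breath_envelope(spec, 4.0, SR)
        assert env.size == 4 * SR
        assert env.min() >= 0.0 and env.max() <= 1.0
        peaks, _ = signal.find_peaks(env, prominence=0.5)
        assert len(peaks) == 2  # one maximum per 2-s cycle

    def test_one_cycle_per_second_at_60(self):
        env = breath_envelope(BreathCycleSpec(60, 0.4, 1), 1.0, SR)
        peaks, _ = signal.find_peaks(env, prominence=0.5)
        assert len(peaks) == 1

    def test_inspiration_louder_than_late_expiration(self):
        spec = BreathCycleSpec(30, 0.4, 2)
        env = breath_envelope(spec, 4.0, SR)
        T = spec.cycle_duration
        t = np.arange(env.size) / SR
        u = (t / T) % 1.0
        insp = env[u < spec.inspiration_fraction]
        late = env[u > spec.inspiration_fraction + 0.5 * (1 - spec.inspiration_fraction)]
        assert insp.mean() / late.mean() > 1.0

    @pytest.mark.parametrize("duration", [0.0, -1.0])
    def test_invalid_duration(self, duration):
        with pytest.raises(ValueError):
            breath_envelope(BreathCycleSpec(30), duration, SR)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            BreathCycleSpec(0.0)


class TestVesicular:
    def test_corner_frequency_near_200hz(self, default_config):
        from acceptance_measures import vesicular_corner_hz

        corner = vesicular_corner_hz(default_config, seed=1)
        assert 160 <= corner <= 240  # 200 Hz +/- 20%

    def test_deterministic(self, default_config):
        a = synth_vesicular(2.0, default_config, seed=5)
        b = synth_vesicular(2.0, default_config, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_zero_duration_rejected(self, default_config):
        with pytest.raises(ValueError):
            synth_vesicular(0.0, default_config, seed=0)


class TestWheezeEvent:
    def test_spectral_peak_at_center_frequency(self):
        spec = EventSpec("wheeze", 400.0, 0.2)
        w = synth_wheeze_event(spec, SR, seed=3)
        peak = spectral_peak_hz(w, pad_to=SR)
        assert abs(peak - 400.0) <= 40.0
        assert 100.0 <= peak <= 1000.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="80"):
            EventSpec("wheeze", 400.0, 0.05)

    def test_frequency_outside_band_rejected(self):
        with pytest.raises(ValueError):
            EventSpec("wheeze", 50.0, 0.2)
        with pytest.raises(ValueError):
            EventSpec("wheeze", 1500.0, 0.2)


class TestCrackleEvent:
    @pytest.mark.parametrize(
        "kind,freq,dur",
        [("fine_crackle", 650.0, 0.005), ("coarse_crackle", 350.0, 0.015)],
    )
    def test_peak_and_decay(self, kind, freq, dur):
        spec = EventSpec(kind, freq, dur)
        w = synth_crackle_event(spec, SR)
        peak = spectral_peak_hz(w, pad_to=SR)
        assert abs(peak - freq) <= 0.1 * freq
        # unit analytic envelope: |x| falls below 5% of its t=0 peak (1.0)
        # at the nominal duration
        assert np.abs(w[int(np.ceil(dur * SR)):]).max() < 0.05

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            EventSpec("fine_crackle", 650.0, 0.0)


class TestHeartSounds:
    def test_s1_count_at_120bpm(self):
        h = synth_heart_sounds(6.0, 120.0, SR, seed=0)
        env = np.abs(signal.hilbert(h))
        env = np.convolve(env, np.ones(441) / 441, mode="same")
        s1, _ = signal.find_peaks(env, height=0.55 * env.max(), distance=int(0.35 * SR))
        assert len(s1) == 12  # 120 bpm x 6 s / 60

    def test_low_frequency_content(self):
        h = synth_heart_sounds(6.0, 100.0, SR, seed=1)
        freqs = np.fft.rfftfreq(h.size, 1 / SR)
        power = np.abs(np.fft.rfft(h)) ** 2
        centroid = (freqs * power).sum() / power.sum()
        assert centroid < 150.0

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            synth_heart_sounds(6.0, 0.0, SR, seed=0)


class TestSynthClip:
    def test_normal_clip_has_no_events(self, default_config):
        clip = synth_clip("normal", default_config, seed=1)
        assert clip.events == ()
        assert clip.label == "normal"

    def test_wheeze_durations_exceed_80ms(self, default_config):
        for seed in range(5):
            clip = synth_clip("wheezing", default_config, seed=seed)
            assert all(e.duration > 0.080 for e in clip.events)
            assert any(e.kind == "wheeze" for e in clip.events)

    def test_crackle_clip_event_kinds(self, default_config):
        clip = synth_clip("crackles", default_config, seed=2)
        assert clip.events and all(
            e.kind in ("fine_crackle", "coarse_crackle") for e in clip.events
        )

    def test_deterministic(self, default_config):
        a = synth_clip("crackles", default_config, seed=9)
        b = synth_clip("crackles", default_config, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert a.events == b.events

    def test_amplitude_bounded(self, default_config):
        clip = synth_clip("wheezing", default_config, seed=4)
        assert np.max(np.abs(clip.samples)) <= 1.0
        assert np.all(np.isfinite(clip.samples))

    def test_unknown_label_rejected(self, default_config):
        with pytest.raises(ValueError):
            synth_clip("murmur", default_config, seed=0)

    def test_label_invariants_enforced(self):
        crackle = EventSpec.fine_crackle(onset=0.0)
        with pytest.raises(ValueError):  # wheezing clip with only crackle events
            AudioClip(np.zeros(100) + 0.1, SR, label="wheezing", events=(crackle,))
        with pytest.raises(ValueError):  # normal clip carrying events
            AudioClip(np.zeros(100) + 0.1, SR, label="normal", events=(crackle,))


class TestCorpus:
    def test_manifest_schema_and_stats(self, default_config, tmp_path):
        manifest = generate_corpus(default_config, n=20, out_dir=tmp_path)
        assert list(manifest.columns) == synth.MANIFEST_COLUMNS
        assert (tmp_path / "manifest.csv").exists()
        assert len(list(tmp_path.glob("*.wav"))) == 20
        assert manifest["clip_id"].is_unique
        assert set(manifest["label"]) <= set(synth.LABELS)

    def test_zero_clips_rejected(self, default_config):
        with pytest.raises(ValueError):
            generate_corpus(default_config, n=0)

    def test_label_counts_exact(self, default_config):
        manifest = generate_corpus(
            default_config, n=9, write_audio=False,
            label_counts={"normal": 2, "crackles": 3, "wheezing": 4},
        )
        counts = manifest["label"].value_counts()
        assert counts["normal"] == 2 and counts["crackles"] == 3 and counts["wheezing"] == 4

    def test_byte_identical_wav_output(self, default_config, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_corpus(default_config, n=3, out_dir=a)
        generate_corpus(default_config, n=3, out_dir=b)
        for fa in sorted(a.glob("*")):
            assert fa.read_bytes() == (b / fa.name).read_bytes()

    def test_manifest_identical_without_audio(self, default_config, tmp_path):
        with_audio = generate_corpus(default_config, n=5, out_dir=tmp_path)
        without = generate_corpus(default_config, n=5, write_audio=False)
        assert with_audio.equals(without)


class TestClassSeparability:
    def test_wheezing_band_power_exceeds_normal(self, default_config):
        def band_power(clip):
            f, P = signal.welch(clip.samples, SR, nperseg=4096)
            return P[(f >= 300) & (f <= 1000)].sum()

        wheeze = [synth_clip("wheezing", default_config, s) for s in range(25)]
        normal = [synth_clip("normal", default_config, 100 + s) for s in range(25)]
        assert np.mean([band_power(c) for c in wheeze]) > np.mean(
            [band_power(c) for c in normal]
        )

    def test_crackle_clips_contain_bursts(self, default_config):
        from scipy.ndimage import median_filter

        win = int(0.050 * SR)
        for seed in range(5):
            clip = synth_clip("crackles", default_config, seed=seed)
            env = np.abs(clip.samples)
            background = median_filter(env, size=win)
            ratio = env / np.maximum(background, 1e-12)
            assert ratio.max() > 3.0
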