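import numpy as np
import pytest

from pulmokit import cli, features, synth


@pytest.fixture(scope="session")
def default_config():
    return synth.SynthConfig()


@pytest.fixture(scope="session")
def pipeline_config():
    return cli.PipelineConfig(seed=0)


def _featurized_corpus(corpus_seed: int):
    """300-clip balanced corpus run through denoise/window/MFCC."""
    cfg = cli.PipelineConfig(seed=0)
    scfg = synth.SynthConfig(seed=corpus_seed)
    manifest = synth.generate_corpus(
        scfg,
        n=300,
        write_audio=False,
        label_counts={"normal": 100, "crackles": 100, "wheezing": 100},
    )
    import dataclasses

    table = cli.featurize_manifest(manifest, dataclasses.replace(cfg, synth_config=scfg))
    return features.feature_matrix(table)


_CORPUS_CACHE: dict[int, tuple] = {}


@pytest.fixture(scope="session")
def featurized_corpora():
    """(X, labels) for three independently seeded 300-clip corpora."""

    def get(seed: int):
        if seed not in _CORPUS_CACHE:
            _CORPUS_CACHE[seed] = _featurized_corpus(seed)
        return _CORPUS_CACHE[seed]

    return get


@pytest.fixture(scope="session")
def small_window_pair():
    """One wheezing and one normal 6-s FixedWindow (no denoising)."""
    from pulmokit import preprocess

    cfg = synth.SynthConfig()
    out = {}
    for label, seed in (("wheezing", 42), ("normal", 43)):
        clip = synth.synth_clip(label, cfg, seed)
        w = preprocess.window_6s(clip.samples, clip.sample_rate)
        out[label] = preprocess.FixedWindow(w, clip.sample_rate, clip.clip_id, label)
    return out
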