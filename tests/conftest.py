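import numpy as np
import pytest

from pansharp import (SceneConfig, paint_truth_scene, degrade_to_pair,
                      upsample_ms, MultispectralImage, PanchromaticImage,
                      WV2_BAND_CATALOG)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230917)


def _scene(archetype, ms_size=32, seed=7, noise_sd=0.01):
    cfg = SceneConfig(archetype=archetype, ms_size=ms_size, ratio=4,
                      seed=seed, noise_sd=noise_sd)
    truth = paint_truth_scene(cfg)
    ms, pan = degrade_to_pair(truth, cfg)
    return cfg, truth, ms, pan


@pytest.fixture(scope="session")
def shrubland_scene():
    """(config, truth, ms, pan) for a small heterogeneous shrubland scene."""
    return _scene("shrubland")


@pytest.fixture(scope="session")
def coastal_scene():
    return _scene("coastal")


@pytest.fixture(scope="session")
def mixed_scene():
    return _scene("mixed")


@pytest.fixture(scope="session")
def shrubland_up(shrubland_scene):
    """Shrubland MS bicubically expanded to the PAN grid."""
    _, _, ms, pan = shrubland_scene
    return upsample_ms(ms, pan.ratio)


@pytest.fixture()
def constant_pair():
    """Per-band-constant MS (PAN grid) with a matching constant PAN: the
    zero-detail configuration in which fusion must be the identity."""
    vals = np.array([0.1, 0.2, 0.3, 0.15, 0.25, 0.3, 0.4, 0.35])
    ms_up = MultispectralImage(np.broadcast_to(vals, (64, 64, 8)).copy(),
                               list(WV2_BAND_CATALOG))
    pan = PanchromaticImage(np.full((64, 64), 0.25), ratio=4)
    return ms_up, pan
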