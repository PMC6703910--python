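"""Shared fixtures: synthetic sessions and textures, generated once."""

from types import SimpleNamespace

import numpy as np
import pytest
from scipy import ndimage

from gammastruct import focus, gammafit, spectral, synth
from gammastruct.preprocess import bipolar_derive, extract_epochs


def make_texture(seed: int, n: int = 256) -> np.ndarray:
    """Band-limited random texture in [0, 1] with fixed contrast."""
    rng = np.random.default_rng(seed)
    t = ndimage.gaussian_filter(rng.standard_normal((n, n)), 1.0)
    t = 0.5 + 0.15 * (t - t.mean()) / t.std()
    return np.clip(t, 0.0, 1.0)


def run_session(cfg: synth.SessionConfig) -> SimpleNamespace:
    """Generate a session and push it through the spectral pipeline."""
    images, truth = synth.generate_images(cfg)
    raw, trials, truth = synth.generate_session(cfg, images, truth)
    epochs = extract_epochs(bipolar_derive(raw), trials)
    stim = spectral.compute_power(epochs, "stimulation")
    base = spectral.compute_power(epochs, "baseline")
    pc, img_ids = spectral.percent_change(stim, base, per_image=True)
    bandpower, _ = spectral.band_power_change(stim, base)
    rdf = np.array([focus.compute_rdf(img) for img in images])
    return SimpleNamespace(cfg=cfg, images=images, truth=truth, raw=raw,
                           trials=trials, epochs=epochs, stim=stim, base=base,
                           pc=pc, img_ids=img_ids, bandpower=bandpower, rdf=rdf)


@pytest.fixture(scope="session")
def session():
    """The default calibrated synthetic session (positive control)."""
    return run_session(synth.SessionConfig(seed=1))


@pytest.fixture(scope="session")
def narrowband_values(session):
    values, _, _ = gammafit.narrowband_metric(session.stim, session.base)
    return values


@pytest.fixture(scope="session")
def patch_rdf(session):
    """19x19 patch RDF maps (default operator) for the session's images."""
    return np.stack([focus.patchwise_rdf(img) for img in session.images])


def null_config(seed: int) -> synth.SessionConfig:
    """Reduced zero-coupling session used for negative controls."""
    return synth.SessionConfig(seed=seed, coupling_gain=0.0,
                               image_size_px=128, presentations_per_image=3)


@pytest.fixture(scope="session")
def null_session():
    """A zero-coupling session: gamma amplitude independent of the images."""
    return run_session(null_config(seed=5))


@pytest.fixture
def texture():
    return make_texture(7)
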