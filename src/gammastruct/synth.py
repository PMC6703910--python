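"""Synthetic stimulus images and matched multichannel LFP sessions.

The generator emulates a natural-image ECoG experiment with a known,
configurable coupling between image structure and gamma-band activity:

- images are band-limited textures whose local sharpness follows a smooth
  spatial "structure field", with an overall per-image structure level, so
  both the global RDF and the patch-local RDF vary across images and
  locations;
- the recording is a continuous multichannel signal built from a large
  common-reference artifact (shared across channels, removed by bipolar
  derivation), per-channel 1/f^n background noise, a 60-Hz line component,
  and during each 1-s stimulus presentation a broadband power increase
  plus a narrowband gamma oscillation (constant envelope with slow random
  frequency jitter around ``gamma_freq_hz``, giving a spectral bump a few
  Hz wide) whose amplitude on each bipolar site is a monotone function of
  the RDF of the image inside that site's simulated receptive-field disc.

Site-specific oscillations are injected through telescoping channel sums
(channel c carries the oscillations of sites c..last), so the bipolar
difference of neighboring channels recovers exactly the intended per-site
component.  Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import rankdata

from .focus import DEFAULT_OPERATOR
from .operators import apply_operator
from .preprocess import RawRecording

__all__ = ["SessionConfig", "GroundTruth", "generate_images",
           "generate_session", "render_from_field"]


def _default_rf_centers(n_electrodes: int) -> np.ndarray:
    """Electrode RF centers along a simulated eccentricity axis.

    The last electrode sits parafoveally (near the image center) and
    eccentricity grows toward the first electrode, mimicking an electrode
    strip running away from the occipital pole.
    """
    xs = np.linspace(0.12, 0.52, n_electrodes)
    ys = np.full(n_electrodes, 0.5)
    return np.column_stack([xs, ys])


@dataclass
class SessionConfig:
    """Parameters of the synthetic experiment.

    Amplitudes are in the arbitrary units of the channel background noise
    (RMS 1).  ``gamma_base_amp`` is the gamma RMS injected for the image
    with the least structure inside a site's RF; ``coupling_gain`` scales
    the additional amplitude earned by climbing the local-RDF ranking, so
    a site's gamma RMS is ``gamma_base_amp * (1 + coupling_gain * u)`` with
    u in [0, 1] the normalized local RDF rank.  Defaults are calibrated so
    the mean gamma-band (30-80 Hz) percent change spans roughly 100-300%
    from the lowest to the highest RDF octile.
    """

    n_images: int = 72
    presentations_per_image: int = 6
    image_size_px: int = 256
    n_electrodes: int = 6
    rf_centers: np.ndarray | None = None  # (n_electrodes, 2) in [0, 1]^2
    rf_radius: float = 0.12
    gamma_freq_hz: float = 55.0
    gamma_bandwidth_hz: float = 5.0
    gamma_base_amp: float = 0.095
    coupling_gain: float = 1.44
    broadband_gain: float = 0.25
    noise_exponent: float = 2.0
    common_ref_amp: float = 5.0
    #: residual 60-Hz line after the acquisition-stage notch filter the
    #: emulated recording chain applies; per-channel amplitudes differ so a
    #: small line component survives the bipolar derivation
    line_amp: float = 0.2
    sample_rate_hz: float = 1000.0
    stim_duration_s: float = 1.0
    isi_range_s: tuple[float, float] = (0.6, 1.4)
    seed: int = 0

    def __post_init__(self):
        if self.n_images <= 1:
            raise ValueError("need at least 2 images")
        if self.image_size_px < 20:
            raise ValueError("image size must be at least 20 px")
        if self.n_electrodes < 2:
            raise ValueError("need at least 2 electrodes")
        if self.rf_centers is None:
            self.rf_centers = _default_rf_centers(self.n_electrodes)
        self.rf_centers = np.asarray(self.rf_centers, dtype=np.float64)
        if self.rf_centers.shape != (self.n_electrodes, 2):
            raise ValueError("rf_centers must be (n_electrodes, 2)")
        if np.any(self.rf_centers < 0) or np.any(self.rf_centers > 1):
            raise ValueError("rf_centers must lie in [0, 1]^2")
        if self.sample_rate_hz < 400.0:
            raise ValueError("sample rate must be at least 2 x 200 Hz")
        if self.isi_range_s[0] > self.isi_range_s[1] or self.isi_range_s[0] < 0.5:
            raise ValueError("invalid inter-stimulus interval range")

    @property
    def n_sites(self) -> int:
        return self.n_electrodes - 1

    def site_rf_centers(self) -> np.ndarray:
        """RF disc center of each bipolar site: midpoint of its electrodes."""
        return 0.5 * (self.rf_centers[:-1] + self.rf_centers[1:])


@dataclass
class GroundTruth:
    """What the generator actually injected (enables recovery tests)."""

    structure_levels: np.ndarray  # (n_images,) global structure level
    structure_fields: np.ndarray  # (n_images, H, W) in [0, 1]
    site_rf_centers: np.ndarray = field(default=None)  # (n_sites, 2)
    rf_radius: float = 0.0
    local_rdf: np.ndarray = field(default=None)  # (n_sites, n_images)
    gamma_amplitude: np.ndarray = field(default=None)  # (n_sites, n_images)
    trial_gamma_amplitude: np.ndarray = field(default=None)  # (n_trials, n_sites)
    trial_broadband_scale: np.ndarray = field(default=None)  # (n_trials,)


def render_from_field(texture: np.ndarray, structure_field: np.ndarray,
                      blur_sigma: float = 4.0) -> np.ndarray:
    """Blend a texture with its blurred version according to a field in [0,1].

    Where the field is 1 the sharp texture survives; where it is 0 only the
    Gaussian-blurred version remains.
    """
    blurred = ndimage.gaussian_filter(texture, blur_sigma, mode="reflect")
    img = structure_field * texture + (1.0 - structure_field) * blurred
    return np.clip(img, 0.0, 1.0)


def generate_images(config: SessionConfig, seed: int | None = None):
    """Generate the stimulus set; returns ``(images, GroundTruth)``.

    Each image is a band-limited texture sharp where a smooth random
    structure field is high and blurred where it is low; per-image global
    structure levels are evenly spread over the set so the image ranking by
    structure is well defined.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([seed, 1])
    n, edge = config.n_images, config.image_size_px

    levels = rng.permutation(np.linspace(0.3, 1.0, n))
    images = np.empty((n, edge, edge))
    fields = np.empty((n, edge, edge))
    for i in range(n):
        raw = ndimage.gaussian_filter(rng.standard_normal((edge, edge)),
                                      edge / 12.0, mode="reflect")
        lo, hi = raw.min(), raw.max()
        smooth = (raw - lo) / (hi - lo) if hi > lo else np.zeros_like(raw)
        # squaring makes sharp regions patchy, so patch-local structure is
        # dominated by location-specific variation rather than the global
        # per-image level (images differ in where, not only how much)
        fields[i] = levels[i] * smooth ** 2

        t = ndimage.gaussian_filter(rng.standard_normal((edge, edge)), 1.0,
                                    mode="reflect")
        t = 0.5 + 0.15 * (t - t.mean()) / t.std()
        images[i] = render_from_field(np.clip(t, 0.0, 1.0), fields[i])
    return images, GroundTruth(structure_levels=levels, structure_fields=fields)


def _local_rdf(images: np.ndarray, center_frac: np.ndarray, radius_frac: float,
               operator_id: str = DEFAULT_OPERATOR) -> np.ndarray:
    """RDF of each image restricted to one RF disc's bounding square."""
    edge = images.shape[-1]
    half = max(int(round(radius_frac * edge)), 8)
    cx = int(round(center_frac[0] * edge))
    cy = int(round(center_frac[1] * edge))
    x0 = min(max(cx - half, 0), edge - 2 * half)
    y0 = min(max(cy - half, 0), edge - 2 * half)
    return np.array([apply_operator(img[y0:y0 + 2 * half, x0:x0 + 2 * half],
                                    operator_id) for img in images])


def _pink_noise(n: int, exponent: float, rate_hz: float,
                rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise, RMS 1, flat below 1 Hz to keep power finite."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    shaping = np.ones_like(freqs)
    nz = freqs >= 1.0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    spec = (rng.standard_normal(freqs.size)
            + 1j * rng.standard_normal(freqs.size)) * shaping
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _narrowband_burst(n: int, rate_hz: float, center_hz: float,
                      bandwidth_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS narrowband oscillation with small cycle-to-cycle phase jitter.

    A constant-envelope oscillation whose instantaneous frequency wanders
    slowly around ``center_hz`` (slow Gaussian frequency modulation with a
    standard deviation of ``bandwidth_hz / 2``), producing a spectral bump
    a few Hz wide while keeping the injected power per trial essentially
    deterministic — unlike bandpass-filtered noise, whose trial power is
    Rayleigh-distributed.
    """
    sigma_t = rate_hz / (2.0 * np.pi * bandwidth_hz)  # slow modulation
    df = ndimage.gaussian_filter1d(rng.standard_normal(n), sigma_t,
                                   mode="reflect")
    sd = df.std()
    if sd > 0:
        df *= (bandwidth_hz / 2.0) / sd
    phase = 2.0 * np.pi * (center_hz * np.arange(n) / rate_hz
                           + np.cumsum(df) / rate_hz)
    return np.sqrt(2.0) * np.cos(phase + rng.uniform(0, 2 * np.pi))


def _envelope(n: int, rate_hz: float, ramp_s: float = 0.1) -> np.ndarray:
    nr = min(int(round(ramp_s * rate_hz)), n // 2)
    env = np.ones(n)
    if nr > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(nr) / nr))
        env[:nr] = ramp
        env[-nr:] = ramp[::-1]
    return env


def generate_session(config: SessionConfig, images: np.ndarray,
                     truth: GroundTruth, seed: int | None = None):
    """Simulate the continuous recording; returns ``(raw, trials, truth)``.

    ``trials`` is a DataFrame with columns ``onset_sample`` and
    ``image_id``; every image id appears exactly
    ``presentations_per_image`` times.  ``truth`` is updated in place with
    the per-site RF discs and the injected amplitudes.
    """
    if len(images) != config.n_images:
        raise ValueError("image set does not match the config")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([seed, 2])
    rate = config.sample_rate_hz
    n_ch = config.n_electrodes
    n_sites = config.n_sites
    n_trials = config.n_images * config.presentations_per_image

    # trial sequence and timing
    image_seq = rng.permutation(np.repeat(np.arange(config.n_images),
                                          config.presentations_per_image))
    isi = rng.uniform(*config.isi_range_s, size=n_trials)
    onsets_s = 2.0 + np.concatenate(
        [[0.0], np.cumsum(config.stim_duration_s + isi[:-1])])
    onsets = np.round(onsets_s * rate).astype(int)
    n_stim = int(round(config.stim_duration_s * rate))
    n_total = int(onsets[-1] + n_stim + round(1.0 * rate))

    # per-site coupling: local RDF rank inside the RF disc -> gamma RMS
    site_centers = config.site_rf_centers()
    local = np.stack([_local_rdf(images, c, config.rf_radius)
                      for c in site_centers])
    denom = max(config.n_images - 1, 1)
    u = (np.apply_along_axis(rankdata, 1, local) - 1.0) / denom
    amp = config.gamma_base_amp * (1.0 + config.coupling_gain * u)

    # background: common reference + per-channel 1/f^n + 60-Hz line
    data = np.empty((n_ch, n_total))
    ref = config.common_ref_amp * _pink_noise(n_total, config.noise_exponent,
                                              rate, rng)
    t = np.arange(n_total) / rate
    phase = rng.uniform(0, 2 * np.pi)
    for c in range(n_ch):
        chan = _pink_noise(n_total, config.noise_exponent, rate, rng)
        line = config.line_amp * (0.6 + 0.8 * rng.uniform()) \
            * np.sin(2 * np.pi * 60.0 * t + phase)
        data[c] = ref + chan + line

    # stimulus-driven site components, injected via telescoping sums
    env = _envelope(n_stim, rate)
    trial_amp = np.empty((n_trials, n_sites))
    bb_scale = np.full(n_trials, config.broadband_gain)
    site_sig = np.zeros((n_sites, n_total))
    for ti, (onset, img) in enumerate(zip(onsets, image_seq)):
        sl = slice(onset, onset + n_stim)
        for k in range(n_sites):
            a = amp[k, img]
            burst = a * _narrowband_burst(n_stim, rate, config.gamma_freq_hz,
                                          config.gamma_bandwidth_hz, rng) * env
            # broadband increase: independent white-noise realization per site
            site_sig[k, sl] += burst + bb_scale[ti] * rng.standard_normal(n_stim) * env
            trial_amp[ti, k] = a

    for c in range(n_ch - 1):
        data[c] += site_sig[c:].sum(axis=0)

    raw = RawRecording(data, rate, [str(i + 1) for i in range(n_ch)])
    trials = pd.DataFrame({"onset_sample": onsets, "image_id": image_seq})

    truth.site_rf_centers = site_centers
    truth.rf_radius = config.rf_radius
    truth.local_rdf = local
    truth.gamma_amplitude = amp
    truth.trial_gamma_amplitude = trial_amp
    truth.trial_broadband_scale = bb_scale
    return raw, trials, truth
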