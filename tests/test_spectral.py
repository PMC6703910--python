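"""Hann-taper spectra, percent change, band power, COG frequency."""

import numpy as np
import pytest
from scipy.signal import windows

from gammastruct import spectral
from gammastruct.inference import spearman
from gammastruct.preprocess import EpochSet
from gammastruct.spectral import FREQS_HZ, PowerSpectra


def make_epochs(baseline, stimulation, image_ids=None, rate=1000.0):
    baseline = np.asarray(baseline)
    if image_ids is None:
        image_ids = np.arange(baseline.shape[0])
    return EpochSet(baseline=baseline, stimulation=np.asarray(stimulation),
                    image_ids=np.asarray(image_ids), rate_hz=rate,
                    site_labels=[str(i) for i in range(baseline.shape[1])])


def test_sinusoid_peaks_at_its_frequency():
    t = np.arange(500) / 1000.0
    x = np.sin(2 * np.pi * 50.0 * t)[None, None, :]
    ps = spectral.compute_power(make_epochs(x, x), "stimulation")
    assert ps.freqs[np.argmax(ps.power[0, 0])] == 50.0


def test_zero_signal_zero_power():
    z = np.zeros((3, 2, 500))
    ps = spectral.compute_power(make_epochs(z, z), "baseline")
    assert np.all(ps.power == 0.0)
    assert ps.power.shape == (2, 3, 99)


def test_incompatible_epoch_length_rejected():
    z = np.zeros((1, 1, 400))
    with pytest.raises(ValueError, match="2-Hz"):
        spectral.compute_power(make_epochs(z, z))


def test_white_noise_spectrum_flat_in_gamma_band():
    """Trial-averaged white-noise power is flat within 10% over 30-80 Hz."""
    rng = np.random.default_rng(0)
    x = rng.normal(size=(2000, 1, 500))
    ps = spectral.compute_power(make_epochs(x, x), "stimulation")
    avg = ps.power[0].mean(axis=0)
    band = avg[(FREQS_HZ >= 30) & (FREQS_HZ <= 80)]
    assert band.max() < 1.1 * band.mean()
    assert band.min() > 0.9 * band.mean()


def test_parseval_identity():
    """Integrated one-sided PSD equals tapered-signal power exactly."""
    rng = np.random.default_rng(1)
    x = rng.normal(size=500)
    power, freqs = spectral._taper_power(x, 1000.0)
    w = windows.hann(500, sym=False)
    df = freqs[1] - freqs[0]
    lhs = power.sum() * df
    rhs = np.sum((w * x) ** 2) / np.sum(w ** 2)
    assert lhs == pytest.approx(rhs, rel=1e-12)
    # and approximates the raw signal variance (flat spectrum, loose bound)
    assert lhs == pytest.approx(x.var(), rel=0.2)


class TestPercentChange:
    def _spectra(self, base_val, stim_val):
        base = PowerSpectra(np.full((1, 4, 99), base_val), FREQS_HZ.copy(),
                            np.arange(4), "baseline")
        stim = PowerSpectra(np.full((1, 4, 99), stim_val), FREQS_HZ.copy(),
                            np.arange(4), "stimulation")
        return stim, base

    def test_equal_power_gives_zero(self):
        pc, _ = spectral.percent_change(*self._spectra(2.0, 2.0))
        assert np.allclose(pc, 0.0)

    def test_doubling_gives_100_percent(self):
        pc, _ = spectral.percent_change(*self._spectra(1.0, 2.0))
        assert np.allclose(pc, 100.0)

    def test_gamma_only_increase(self):
        stim, base = self._spectra(1.0, 1.0)
        m = (FREQS_HZ >= 30) & (FREQS_HZ <= 80)
        stim.power[..., m] = 11.0
        pc, _ = spectral.percent_change(stim, base)
        assert np.allclose(pc[..., m], 1000.0)
        assert np.allclose(pc[..., ~m], 0.0)

    def test_zero_baseline_rejected(self):
        stim, base = self._spectra(0.0, 1.0)
        with pytest.raises(ValueError, match="zero baseline"):
            spectral.percent_change(stim, base)

    def test_baseline_vs_own_average_is_centered(self, session):
        """Baseline epochs against their own average have mean ~0 per bin."""
        pc, _ = spectral.percent_change(session.base, session.base)
        mean = pc.mean(axis=1)
        sem = pc.std(axis=1, ddof=1) / np.sqrt(pc.shape[1])
        assert np.all(np.abs(mean) < 3 * sem + 1e-9)


class TestBandPowerChange:
    def test_flat_change_recovered(self):
        base = PowerSpectra(np.ones((2, 6, 99)), FREQS_HZ.copy(),
                            np.repeat([0, 1], 3), "baseline")
        stim = PowerSpectra(np.full((2, 6, 99), 2.0), FREQS_HZ.copy(),
                            np.repeat([0, 1], 3), "stimulation")
        vals, ids = spectral.band_power_change(stim, base)
        assert np.allclose(vals, 100.0)
        assert ids.tolist() == [0, 1]

    def test_zero_change(self):
        base = PowerSpectra(np.ones((1, 2, 99)), FREQS_HZ.copy(),
                            np.array([0, 0]), "baseline")
        stim = PowerSpectra(np.ones((1, 2, 99)), FREQS_HZ.copy(),
                            np.array([0, 0]), "stimulation")
        vals, _ = spectral.band_power_change(stim, base)
        assert np.allclose(vals, 0.0)

    def test_band_outside_grid_rejected(self):
        base = PowerSpectra(np.ones((1, 2, 99)), FREQS_HZ.copy(),
                            np.array([0, 0]), "baseline")
        with pytest.raises(ValueError, match="band"):
            spectral.band_power_change(base, base, band=(300, 400))

    def test_ground_truth_recovery(self, session):
        """Band power change tracks the injected gamma amplitude."""
        r = [spearman(session.bandpower[s], session.truth.gamma_amplitude[s])
             for s in range(session.bandpower.shape[0])]
        assert np.mean(r) > 0.9
        assert min(r) > 0.8


class TestCogFrequency:
    def test_single_line(self):
        v = np.zeros(99)
        v[FREQS_HZ == 50] = 3.0
        assert spectral.cog_frequency(v) == 50.0

    def test_symmetric_pair(self):
        v = np.zeros(99)
        v[FREQS_HZ == 40] = 2.0
        v[FREQS_HZ == 60] = 2.0
        assert spectral.cog_frequency(v) == 50.0

    def test_all_zero_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            spectral.cog_frequency(np.zeros(99))

    def test_injected_gamma_frequency_recovered(self, session):
        """COG of the induced change sits within 3 Hz of the 55-Hz gamma."""
        pooled = session.pc.mean(axis=(0, 1))
        assert spectral.cog_frequency(pooled) == pytest.approx(55.0, abs=3.0)


class TestTimeResolved:
    def test_nonoverlapping_window_count(self, session):
        times, freqs, vals = spectral.time_resolved_power(
            _subset_sites(session), session.trials.iloc[:20],
            window_s=0.25, step_s=0.25, t_range_s=(-0.5, 1.0))
        assert len(times) == 6  # floor(1.5 / 0.25)
        assert vals.shape[1] == len(times)

    def test_gamma_sustained_during_stimulation(self, session):
        times, freqs, vals = spectral.time_resolved_power(
            _subset_sites(session), session.trials.iloc[:60])
        gm = (freqs >= 40) & (freqs <= 70)
        gamma = vals[:, :, gm].mean(axis=(0, 2))
        during = gamma[(times >= 0.35) & (times <= 0.75)]
        before = gamma[times < -0.1]
        assert during.min() > 50.0
        assert np.abs(before).max() < 50.0


def _subset_sites(session):
    from gammastruct.preprocess import bipolar_derive
    return bipolar_derive(session.raw)
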