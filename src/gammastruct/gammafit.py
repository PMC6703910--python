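"""Decomposition of log-power spectra into broadband power law + gamma bump.

The model, in log10 coordinates (x = log10 frequency):

    P(x) = beta_broadband - n * x + beta_narrowband * G(x | mu, sigma)
    G(x | mu, sigma) = exp(-(x - mu)^2 / (2 sigma^2))

with the bump width fixed at 10**sigma = 1.1, the center constrained to
35 Hz < 10**mu < 80 Hz, and the power-law slope ``n`` fixed per site from
the trial-averaged baseline spectrum.  ``beta_narrowband`` (log10-power
units, constrained nonnegative) is the narrowband-gamma metric: it
separates a spectrally peaked oscillation from broadband power increases.

Fits use the average log10 spectrum from 35 to 200 Hz, excluding the 60-Hz
line band and its harmonics (58-62, 118-122, 178-182 Hz).  The model is
linear in the betas given mu, so for each candidate mu on a fine grid the
betas are solved in closed form; the best mu is then refined locally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "SIGMA_LOG10",
    "FIT_RANGE_HZ",
    "LINE_EXCLUSION_BANDS_HZ",
    "MU_BOUNDS_HZ",
    "SpectralDecomposition",
    "fit_range_mask",
    "fit_baseline_slope",
    "fit_decomposition",
    "narrowband_metric",
]

SIGMA_LOG10 = float(np.log10(1.1))
FIT_RANGE_HZ = (35.0, 200.0)
MU_BOUNDS_HZ = (35.0, 80.0)
LINE_EXCLUSION_BANDS_HZ = ((58.0, 62.0), (118.0, 122.0), (178.0, 182.0))
_MU_GRID_STEP = 0.001  # log10 units; bump sigma ~0.0414 demands a fine grid


@dataclass
class SpectralDecomposition:
    """Fitted parameters of the broadband + narrowband-gamma model."""

    beta_broadband: float
    beta_narrowband: float
    n: float
    mu: float  # log10 center frequency
    sigma: float
    rss: float

    @property
    def peak_freq_hz(self) -> float:
        return 10.0 ** self.mu


def fit_range_mask(freqs: np.ndarray) -> np.ndarray:
    """Frequency bins used for fitting: 35-200 Hz minus line bands."""
    freqs = np.asarray(freqs)
    m = (freqs >= FIT_RANGE_HZ[0]) & (freqs <= FIT_RANGE_HZ[1])
    for lo, hi in LINE_EXCLUSION_BANDS_HZ:
        m &= ~((freqs >= lo) & (freqs <= hi))
    return m


def fit_baseline_slope(baseline_avg_power: np.ndarray,
                       freqs: np.ndarray) -> float:
    """Power-law slope magnitude ``n`` from the average baseline spectrum.

    Least-squares line in (log10 f, log10 P) over the fit range; the
    returned ``n`` is the magnitude of the descending slope, so a 1/f^2
    spectrum gives n = 2 and a white spectrum gives n = 0.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    p = np.asarray(baseline_avg_power, dtype=np.float64)
    m = fit_range_mask(freqs)
    if np.any(p[m] <= 0) or not np.all(np.isfinite(p[m])):
        raise ValueError("baseline power must be positive over the fit range")
    slope, _ = np.polyfit(np.log10(freqs[m]), np.log10(p[m]), 1)
    return float(-slope)


def _solve_betas(target: np.ndarray, g: np.ndarray):
    """Closed-form least squares for (beta_bb, beta_nb), beta_nb >= 0.

    ``target`` is log10 power with the fixed power-law trend added back
    (y + n x); the model is target = beta_bb + beta_nb * g.
    """
    npts = target.size
    sg, sg2 = g.sum(), (g * g).sum()
    st, sgt = target.sum(), (g * target).sum()
    det = npts * sg2 - sg * sg
    if det <= 1e-15:
        b_bb, b_nb = st / npts, 0.0
    else:
        b_nb = (npts * sgt - sg * st) / det
        b_bb = (st - b_nb * sg) / npts
    if b_nb < 0.0:
        b_nb = 0.0
        b_bb = st / npts
    resid = target - b_bb - b_nb * g
    return b_bb, b_nb, float(resid @ resid)


def fit_decomposition(avg_log_power: np.ndarray, freqs: np.ndarray,
                      n: float) -> SpectralDecomposition:
    """Fit the bump model to an average log10 power spectrum with fixed n.

    Minimizes squared error of log10 power over the fit range (line bands
    excluded).  For each candidate mu on a 0.001-step log10 grid inside
    (log10 35, log10 80) the betas are solved in closed form; the best grid
    point is refined with a bounded scalar search.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    y = np.asarray(avg_log_power, dtype=np.float64)
    m = fit_range_mask(freqs)
    if not m.any():
        raise ValueError("empty fit range")
    x = np.log10(freqs[m])
    t = y[m] + n * x
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite log spectrum over the fit range")

    lo, hi = np.log10(MU_BOUNDS_HZ[0]), np.log10(MU_BOUNDS_HZ[1])
    grid = np.arange(lo + _MU_GRID_STEP, hi, _MU_GRID_STEP)

    # vectorized grid search over candidate bump centers
    gmat = np.exp(-((x[None, :] - grid[:, None]) ** 2) / (2 * SIGMA_LOG10 ** 2))
    npts = x.size
    sg = gmat.sum(axis=1)
    sg2 = (gmat * gmat).sum(axis=1)
    st = t.sum()
    sgt = gmat @ t
    det = npts * sg2 - sg * sg
    with np.errstate(divide="ignore", invalid="ignore"):
        b_nb = np.where(det > 1e-15, (npts * sgt - sg * st) / det, 0.0)
    b_nb = np.clip(b_nb, 0.0, None)
    b_bb = (st - b_nb * sg) / npts
    rss = ((t[None, :] - b_bb[:, None] - b_nb[:, None] * gmat) ** 2).sum(axis=1)
    best = int(np.argmin(rss))

    def objective(mu):
        g = np.exp(-((x - mu) ** 2) / (2 * SIGMA_LOG10 ** 2))
        return _solve_betas(t, g)[2]

    span = 2 * _MU_GRID_STEP
    res = minimize_scalar(objective, bounds=(max(lo + 1e-9, grid[best] - span),
                                             min(hi - 1e-9, grid[best] + span)),
                          method="bounded",
                          options={"xatol": 1e-7})
    mu = float(res.x)
    g = np.exp(-((x - mu) ** 2) / (2 * SIGMA_LOG10 ** 2))
    b_bb_f, b_nb_f, rss_f = _solve_betas(t, g)
    if rss_f > rss[best]:  # keep the grid optimum if refinement regressed
        mu = float(grid[best])
        g = np.exp(-((x - mu) ** 2) / (2 * SIGMA_LOG10 ** 2))
        b_bb_f, b_nb_f, rss_f = _solve_betas(t, g)
    return SpectralDecomposition(float(b_bb_f), float(b_nb_f), float(n),
                                 mu, SIGMA_LOG10, rss_f)


def model_spectrum(freqs: np.ndarray, beta_bb: float, n: float,
                   beta_nb: float, mu: float,
                   sigma: float = SIGMA_LOG10) -> np.ndarray:
    """Log10 power predicted by the decomposition model (test utility)."""
    x = np.log10(np.asarray(freqs, dtype=np.float64))
    g = np.exp(-((x - mu) ** 2) / (2 * sigma ** 2))
    return beta_bb - n * x + beta_nb * g


def narrowband_metric(stim: "PowerSpectra", baseline: "PowerSpectra"):
    """Per-image narrowband-gamma amplitude (beta_narrowband) per site.

    For each site, the power-law slope n is fixed from the trial-averaged
    baseline spectrum; for each image, the stimulation epochs' log10
    spectra are averaged and the bump model fitted.  Returns
    ``(values, image_ids, decompositions)`` with values of shape
    (n_sites, n_images).
    """
    from .spectral import baseline_average  # local import avoids a cycle

    freqs = stim.freqs
    ids = np.asarray(stim.image_ids)
    uniq = np.unique(ids)
    base_avg = baseline_average(baseline)
    n_sites = stim.power.shape[0]
    values = np.empty((n_sites, uniq.size))
    decomps: list[list[SpectralDecomposition]] = []
    for s in range(n_sites):
        n_slope = fit_baseline_slope(base_avg[s], freqs)
        row = []
        for j, img in enumerate(uniq):
            logspec = np.log10(stim.power[s, ids == img, :]).mean(axis=0)
            d = fit_decomposition(logspec, freqs, n_slope)
            values[s, j] = d.beta_narrowband
            row.append(d)
        decomps.append(row)
    return values, uniq, decomps
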