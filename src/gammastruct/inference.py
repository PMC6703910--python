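"""Correlation of gamma metrics with image structure, with randomization
inference.

Spearman rank correlations relate per-image RDF scores to per-image,
per-site gamma measures: globally, per frequency bin (correlation spectra),
and per image patch (receptive-field-like maps).  Family-wise error across
frequencies/patches and sites is controlled with a min/max-statistic
randomization test: per permutation of the RDF ranks only the global
maximum and minimum of the statistic map are kept, and the 99th percentile
of maxima / 1st percentile of minima serve as two-sided p = 0.02
significance thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .spectral import GAMMA_BAND_HZ, band_mask

__all__ = [
    "spearman",
    "spearman_pvalue",
    "average_rank_metric",
    "gamma_metrics_table",
    "correlate_rdf_gamma",
    "correlation_spectra",
    "RandomizationResult",
    "maxstat_randomization",
    "maxstat_spearman",
    "rf_correlation_maps",
    "bin_by_rdf",
]


def _ranks_std(v: np.ndarray) -> np.ndarray:
    """Average ranks standardized to zero mean and unit norm (per column)."""
    r = np.apply_along_axis(rankdata, 0, v) if v.ndim > 1 else rankdata(v)
    r = r - r.mean(axis=0)
    norm = np.sqrt((r * r).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(norm > 0, r / norm, np.nan)


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D arrays with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    xs, ys = _ranks_std(x), _ranks_std(y)
    if np.any(np.isnan(xs)) or np.any(np.isnan(ys)):
        raise ValueError("Spearman correlation undefined for constant input")
    return float(xs @ ys)


def spearman_pvalue(r: float, n: int, x=None, y=None) -> float:
    """Two-sided p-value for a Spearman correlation.

    Exact permutation distribution for n <= 10 (enumeration is cheap there),
    otherwise the large-sample t approximation with n - 2 degrees of
    freedom.
    """
    if n <= 10:
        from itertools import permutations
        if x is None or y is None:
            raise ValueError("exact p-value needs the data for n <= 10")
        xs, ys = _ranks_std(np.asarray(x, float)), _ranks_std(np.asarray(y, float))
        count = 0
        total = 0
        for perm in permutations(range(n)):
            total += 1
            if abs(xs[list(perm)] @ ys) >= abs(r) - 1e-12:
                count += 1
        return count / total
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def average_rank_metric(narrowband: np.ndarray, bandpower: np.ndarray) -> np.ndarray:
    """Per-site mean of the two gamma metrics' within-site image ranks.

    Scale-free combination of the narrowband-fit and band-power metrics;
    with Spearman correlations downstream only the ranking matters.
    """
    narrowband = np.atleast_2d(narrowband)
    bandpower = np.atleast_2d(bandpower)
    rh = np.apply_along_axis(rankdata, 1, narrowband)
    rb = np.apply_along_axis(rankdata, 1, bandpower)
    return (rh + rb) / 2.0


def gamma_metrics_table(narrowband: np.ndarray, bandpower: np.ndarray,
                        image_ids, site_labels) -> pd.DataFrame:
    """Long-format per-image, per-site table of the three gamma metrics."""
    avg = average_rank_metric(narrowband, bandpower)
    rows = []
    for s, lab in enumerate(site_labels):
        for j, img in enumerate(image_ids):
            rows.append((lab, img, narrowband[s, j], bandpower[s, j], avg[s, j]))
    return pd.DataFrame(rows, columns=["site", "image_id", "narrowband",
                                       "bandpower", "average"])


def correlate_rdf_gamma(rdf_scores: np.ndarray, narrowband: np.ndarray,
                        bandpower: np.ndarray, metric: str = "average"):
    """Spearman R (and two-sided p) between RDF and a gamma metric, per site.

    ``metric`` is one of ``narrowband``, ``bandpower`` or ``average`` (mean of the
    two metrics' within-site ranks).  Returns ``(R, p)`` arrays of length
    n_sites.
    """
    rdf_scores = np.asarray(rdf_scores, dtype=np.float64)
    if metric == "narrowband":
        vals = np.atleast_2d(narrowband)
    elif metric == "bandpower":
        vals = np.atleast_2d(bandpower)
    elif metric == "average":
        vals = average_rank_metric(narrowband, bandpower)
    else:
        raise ValueError("metric must be 'narrowband', 'bandpower' or 'average'")
    if vals.shape[1] != rdf_scores.size:
        raise ValueError("image sets of RDF scores and gamma metrics differ")
    r = np.array([spearman(rdf_scores, vals[s]) for s in range(vals.shape[0])])
    p = np.array([spearman_pvalue(r[s], rdf_scores.size, rdf_scores, vals[s])
                  for s in range(vals.shape[0])])
    return r, p


def correlation_spectra(rdf_scores: np.ndarray, pc_per_image: np.ndarray) -> np.ndarray:
    """Spearman R between RDF and percent-change power, per site and frequency.

    ``pc_per_image`` has shape (n_sites, n_images, n_freqs); returns
    (n_sites, n_freqs).
    """
    xs = _ranks_std(np.asarray(rdf_scores, float))
    n_sites, n_images, n_freqs = pc_per_image.shape
    ys = _ranks_std(pc_per_image.transpose(1, 0, 2).reshape(n_images, -1))
    return (xs @ ys).reshape(n_sites, n_freqs)


@dataclass
class RandomizationResult:
    """Min/max-statistic randomization distributions and thresholds."""

    maxima: np.ndarray
    minima: np.ndarray
    upper: float  # 99th percentile of maxima
    lower: float  # 1st percentile of minima

    @property
    def n_randomizations(self) -> int:
        return self.maxima.size

    def significant(self, values: np.ndarray) -> np.ndarray:
        """Boolean mask of values outside the two-sided thresholds."""
        values = np.asarray(values)
        return (values > self.upper) | (values < self.lower)


def _thresholds(maxima: np.ndarray, minima: np.ndarray,
                percentile: float = 99.0) -> tuple[float, float]:
    return (float(np.percentile(maxima, percentile)),
            float(np.percentile(minima, 100.0 - percentile)))


def maxstat_randomization(statistic_fn, labels_to_permute, n_rand: int = 1000,
                          seed=None) -> RandomizationResult:
    """Generic min/max-statistic randomization test.

    ``statistic_fn`` maps a permuted copy of ``labels_to_permute`` to the
    full statistic array (e.g. site x frequency); per randomization only
    its global maximum and minimum are recorded.  The 99th percentile of
    maxima and the 1st percentile of minima bound a two-sided family-wise
    p = 0.02 test.
    """
    if n_rand < 100:
        warnings.warn(f"n_rand={n_rand} is small; thresholds will be noisy",
                      stacklevel=2)
    labels = np.asarray(labels_to_permute)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_rand)
    minima = np.empty(n_rand)
    for i in range(n_rand):
        stat = np.asarray(statistic_fn(rng.permutation(labels)))
        maxima[i] = stat.max()
        minima[i] = stat.min()
    upper, lower = _thresholds(maxima, minima)
    return RandomizationResult(maxima, minima, upper, lower)


def maxstat_spearman(rdf_scores: np.ndarray, values: np.ndarray,
                     n_rand: int = 1000, seed=None):
    """Vectorized max-statistic test for Spearman correlation maps.

    ``values`` has shape (n_images, K) for K statistic cells (e.g. sites x
    frequencies or sites x patches flattened).  Returns
    ``(observed, RandomizationResult)`` where observed has shape (K,).
    """
    xs = _ranks_std(np.asarray(rdf_scores, float))
    ys = _ranks_std(np.asarray(values, float))
    observed = xs @ ys
    rng = np.random.default_rng(seed)
    n = xs.size
    perms = np.stack([xs[rng.permutation(n)] for _ in range(n_rand)])
    r_perm = perms @ ys  # (n_rand, K)
    maxima = r_perm.max(axis=1)
    minima = r_perm.min(axis=1)
    upper, lower = _thresholds(maxima, minima)
    return observed, RandomizationResult(maxima, minima, upper, lower)


def rf_correlation_maps(patch_rdf: np.ndarray, bandpower: np.ndarray,
                        n_rand: int = 1000, seed=None):
    """Patch-wise RDF-gamma correlation maps with max-statistic masking.

    ``patch_rdf``: (n_images, gh, gw) patch RDF scores;
    ``bandpower``: (n_sites, n_images) gamma metric.  For each patch and site
    the Spearman correlation across images is computed; significance is
    controlled across all patches and sites jointly by randomizing the
    gamma metric's image assignment.  Returns ``(maps, masks, result)``
    with maps and masks of shape (n_sites, gh, gw).
    """
    patch_rdf = np.asarray(patch_rdf, dtype=np.float64)
    bandpower = np.atleast_2d(np.asarray(bandpower, dtype=np.float64))
    n_images, gh, gw = patch_rdf.shape
    n_sites = bandpower.shape[0]
    if bandpower.shape[1] != n_images:
        raise ValueError("image counts of patch maps and gamma metric differ")

    # statistic cells: sites x patches; permute the per-image gamma values
    ys = _ranks_std(patch_rdf.reshape(n_images, gh * gw))
    xs = _ranks_std(bandpower.T)  # (n_images, n_sites)
    observed = np.einsum("is,ik->sk", xs, ys)  # (n_sites, patches)

    rng = np.random.default_rng(seed)
    maxima = np.empty(n_rand)
    minima = np.empty(n_rand)
    for i in range(n_rand):
        perm = rng.permutation(n_images)
        r = np.einsum("is,ik->sk", xs[perm], ys)
        maxima[i] = r.max()
        minima[i] = r.min()
    upper, lower = _thresholds(maxima, minima)
    result = RandomizationResult(maxima, minima, upper, lower)
    maps = observed.reshape(n_sites, gh, gw)
    masks = result.significant(maps)
    return maps, masks, result


def bin_by_rdf(rdf_scores: np.ndarray, pc_per_image: np.ndarray,
               freqs: np.ndarray, n_bins: int = 8,
               band: tuple[float, float] = GAMMA_BAND_HZ):
    """Gamma change and peak frequency across RDF-sorted image bins.

    Images are sorted by RDF (ties broken by image index) and split into
    ``n_bins`` contiguous bins; per bin, the percent-change spectrum is
    averaged over the bin's images and all sites, then reduced to the mean
    gamma-band (30-80 Hz) change and the center-of-gravity gamma frequency.
    Returns a DataFrame with columns bin, gamma_change_pct, cog_freq_hz,
    n_images.
    """
    from .spectral import cog_frequency

    rdf_scores = np.asarray(rdf_scores, dtype=np.float64)
    n_images = rdf_scores.size
    if n_images < n_bins:
        raise ValueError("fewer images than bins")
    order = np.lexsort((np.arange(n_images), rdf_scores))
    bounds = np.linspace(0, n_images, n_bins + 1).round().astype(int)
    m = band_mask(np.asarray(freqs), band)
    rows = []
    for b in range(n_bins):
        sel = order[bounds[b]:bounds[b + 1]]
        spec = pc_per_image[:, sel, :].mean(axis=(0, 1))  # pooled over sites
        gamma = float(spec[m].mean())
        cog = float(cog_frequency(spec, freqs, band))
        rows.append((b + 1, gamma, cog, sel.size))
    return pd.DataFrame(rows, columns=["bin", "gamma_change_pct",
                                       "cog_freq_hz", "n_images"])
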