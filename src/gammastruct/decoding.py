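"""Pairwise image decoding from spectral power with a linear SVM.

For every unordered pair of images and every 20-Hz frequency window (11
bins on the 2-Hz grid), a linear maximum-margin classifier is trained on
the stimulation-epoch spectral power of all but one presentation
(presentation counts matched between the two images by seeded random
subselection) and classifies the held-out presentation; accuracy is
averaged over hold-outs and pairs.  Windows slide over 4-200 Hz; site
features can be concatenated.

The inner solver is a batched dual coordinate-descent linear SVM
(L1-loss dual with an augmented bias feature, C = 1, the LinearSVC
formulation), vectorized over thousands of 10-sample problems at once;
sklearn's SVM serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "enumerate_pairs",
    "window_bins",
    "window_centers",
    "PairProblems",
    "build_problems",
    "svm_batch_correct",
    "loo_pair_accuracy",
    "decoding_spectrum",
    "concatenate_sites",
    "select_best_sites",
    "decode_significance",
]

WINDOW_HALF_WIDTH_HZ = 10.0  # 20-Hz windows -> 11 bins at 2-Hz steps
SVM_C = 1.0


def enumerate_pairs(image_ids) -> list[tuple]:
    """All unordered pairs of image ids, each exactly once."""
    ids = list(image_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 images")
    return list(combinations(ids, 2))


def window_centers(freqs: np.ndarray) -> np.ndarray:
    """All window center frequencies for which 11 bins fit inside the grid."""
    freqs = np.asarray(freqs)
    lo, hi = freqs.min() + WINDOW_HALF_WIDTH_HZ, freqs.max() - WINDOW_HALF_WIDTH_HZ
    return freqs[(freqs >= lo) & (freqs <= hi)]


def window_bins(freqs: np.ndarray, center_hz: float) -> np.ndarray:
    """Indices of the 11 bins of the 20-Hz window centered at ``center_hz``."""
    freqs = np.asarray(freqs)
    sel = np.flatnonzero(np.abs(freqs - center_hz) <= WINDOW_HALF_WIDTH_HZ + 1e-9)
    if sel.size != 11:
        raise ValueError(
            f"window centered at {center_hz} Hz has {sel.size} bins, not 11")
    return sel


# -- problem construction -----------------------------------------------------

@dataclass
class PairProblems:
    """One batch of equally-sized LOO training problems.

    ``train_idx``: (B, n_train) trial indices; ``train_y``: (B, n_train)
    labels in {-1, +1}; ``hold_idx``/``hold_y``: held-out trial and label;
    ``pair_index``: (B,) index into the pair list.
    """

    train_idx: np.ndarray
    train_y: np.ndarray
    hold_idx: np.ndarray
    hold_y: np.ndarray
    pair_index: np.ndarray


def build_problems(trial_image_ids, pairs=None, seed: int = 0) -> list[PairProblems]:
    """Enumerate every (pair, hold-out) problem with matched subselection.

    The subselection of training presentations is seeded per (pair,
    hold-out) from the master seed — keyed by the unordered pair and the
    held-out trial's index, so it is identical across frequency windows and
    recording sites (concatenated-site features stay aligned) and invariant
    under swapping the two images' roles.  Problems are grouped by
    training-set size.
    """
    ids = np.asarray(trial_image_ids)
    if pairs is None:
        pairs = enumerate_pairs(np.unique(ids))
    trials_of = {img: np.flatnonzero(ids == img) for img in np.unique(ids)}
    key_of = {img: k for k, img in enumerate(sorted(trials_of))}

    groups: dict[int, list] = {}
    for pi, (a, b) in enumerate(pairs):
        ta, tb = trials_of[a], trials_of[b]
        if ta.size < 2 or tb.size < 2:
            raise ValueError(f"images {a!r}/{b!r} need >= 2 presentations")
        pair_key = sorted((key_of[a], key_of[b]))
        holds = [(h, +1) for h in ta] + [(h, -1) for h in tb]
        for h, ysign in holds:
            rng = np.random.default_rng([seed, *pair_key, int(h)])
            rem_a = ta[ta != h]
            rem_b = tb[tb != h]
            m = min(rem_a.size, rem_b.size)
            # draw in canonical image order so the subselection (and hence
            # the problem) is invariant under swapping the pair's roles
            first_is_a = key_of[a] <= key_of[b]
            sel_1 = np.sort(rng.choice(rem_a if first_is_a else rem_b,
                                       size=m, replace=False))
            sel_2 = np.sort(rng.choice(rem_b if first_is_a else rem_a,
                                       size=m, replace=False))
            sel_a, sel_b = (sel_1, sel_2) if first_is_a else (sel_2, sel_1)
            tr = np.concatenate([sel_a, sel_b])
            y = np.concatenate([np.ones(m), -np.ones(m)])
            groups.setdefault(2 * m, []).append((tr, y, h, ysign, pi))

    out = []
    for size, rows in sorted(groups.items()):
        out.append(PairProblems(
            train_idx=np.array([r[0] for r in rows]),
            train_y=np.array([r[1] for r in rows]),
            hold_idx=np.array([r[2] for r in rows]),
            hold_y=np.array([r[3] for r in rows], dtype=np.float64),
            pair_index=np.array([r[4] for r in rows]),
        ))
    return out


# -- batched linear SVM -------------------------------------------------------

def _dual_cd_weights(X: np.ndarray, y: np.ndarray, C: float = SVM_C,
                     max_sweeps: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Batched L1-loss dual coordinate descent for linear SVMs.

    ``X``: (B, n, d) training features (bias feature included);
    ``y``: (B, n) labels in {-1, +1}.  Returns weights (B, d).
    """
    B, n, _ = X.shape
    Q = np.einsum("bik,bjk->bij", X, X) * (y[:, :, None] * y[:, None, :])
    diag = np.einsum("bii->bi", Q).copy()
    diag[diag <= 0] = 1.0
    alpha = np.zeros((B, n))
    for _ in range(max_sweeps):
        delta_max = 0.0
        for i in range(n):
            g = np.einsum("bj,bj->b", Q[:, i, :], alpha) - 1.0
            new = np.clip(alpha[:, i] - g / diag[:, i], 0.0, C)
            delta = new - alpha[:, i]
            alpha[:, i] = new
            delta_max = max(delta_max, float(np.abs(delta).max()))
        if delta_max < tol:
            break
    return np.einsum("bi,bid->bd", alpha * y, X)


def svm_batch_correct(X: np.ndarray, y: np.ndarray, Xh: np.ndarray,
                      yh: np.ndarray) -> np.ndarray:
    """Train one linear SVM per problem and score the held-out sample.

    Features are centered by the training fold's mean (but deliberately not
    variance-standardized: for narrowband power features the per-bin
    variance itself carries class information, and equalizing it would give
    pure-noise bins the same a-priori weight as signal bins) and augmented
    with a constant bias feature.  Returns per-problem credit in
    {0, 0.5, 1}; a zero decision value (e.g. identical feature sets for
    both classes) counts as 0.5 by symmetric tie-breaking.
    """
    mu = X.mean(axis=1, keepdims=True)
    Xs = X - mu
    Xhs = Xh - mu[:, 0, :]
    ones = np.ones((*Xs.shape[:2], 1))
    w = _dual_cd_weights(np.concatenate([Xs, ones], axis=2), y)
    dec = np.einsum("bd,bd->b", w[:, :-1], Xhs) + w[:, -1]
    credit = np.where(np.abs(dec) < 1e-12, 0.5,
                      (np.sign(dec) == np.sign(yh)).astype(np.float64))
    return credit


def _accuracy(features: np.ndarray, problems: list[PairProblems]) -> float:
    """Mean LOO accuracy over all problems; ``features`` is (n_trials, d)."""
    total, count = 0.0, 0
    for grp in problems:
        credit = svm_batch_correct(features[grp.train_idx], grp.train_y,
                                   features[grp.hold_idx], grp.hold_y)
        total += credit.sum()
        count += credit.size
    return total / count


def loo_pair_accuracy(features_a: np.ndarray, features_b: np.ndarray,
                      seed: int = 0) -> float:
    """Leave-one-presentation-out accuracy for a single image pair.

    ``features_a``/``features_b``: (n_presentations, d) feature vectors of
    the two images.
    """
    if len(features_a) < 2 or len(features_b) < 2:
        raise ValueError("need at least 2 presentations per image")
    feats = np.vstack([features_a, features_b])
    ids = np.array([0] * len(features_a) + [1] * len(features_b))
    problems = build_problems(ids, pairs=[(0, 1)], seed=seed)
    return _accuracy(feats, problems)


def _site_features(power: np.ndarray, bins: np.ndarray, sites) -> np.ndarray:
    """Concatenated spectral-power features (n_trials, 11 * n_sites)."""
    return np.concatenate([power[s][:, bins] for s in sites], axis=1)


def decoding_spectrum(stim_power: np.ndarray, freqs: np.ndarray,
                      trial_image_ids, centers=None, seed: int = 0,
                      site_groups=None, problems=None) -> pd.DataFrame:
    """Mean pairwise LOO accuracy per site (group) and frequency window.

    ``stim_power``: (n_sites, n_trials, n_freqs) stimulation-epoch power.
    ``site_groups``: list of (label, tuple-of-site-indices); defaults to
    each site alone.  Returns a DataFrame (site, center_freq, accuracy).
    """
    stim_power = np.asarray(stim_power)
    freqs = np.asarray(freqs)
    if centers is None:
        centers = window_centers(freqs)
    if site_groups is None:
        site_groups = [(str(s), (s,)) for s in range(stim_power.shape[0])]
    if problems is None:
        problems = build_problems(trial_image_ids, seed=seed)

    rows = []
    for c in centers:
        bins = window_bins(freqs, c)
        for label, sites in site_groups:
            feats = _site_features(stim_power, bins, sites)
            rows.append((label, float(c), _accuracy(feats, problems)))
    return pd.DataFrame(rows, columns=["site", "center_freq", "accuracy"])


def concatenate_sites(stim_power: np.ndarray, freqs: np.ndarray,
                      center_hz: float, site_ids) -> np.ndarray:
    """Per-trial feature vectors of several sites joined (11 bins each)."""
    if len(site_ids) < 1:
        raise ValueError("need at least one site")
    bins = window_bins(np.asarray(freqs), center_hz)
    return _site_features(np.asarray(stim_power), bins, site_ids)


def select_best_sites(spectrum: pd.DataFrame, n: int = 3) -> list[int]:
    """Sites with the highest peak accuracy over windows (ties: lower id)."""
    peaks = spectrum.groupby("site")["accuracy"].max()
    order = sorted(peaks.index, key=lambda s: (-peaks[s], int(s)))
    return [int(s) for s in order[:n]]


def decode_significance(stim_power: np.ndarray, freqs: np.ndarray,
                        trial_image_ids, centers=None, n_rand: int = 100,
                        seed: int = 0, site_groups=None) -> tuple[float, np.ndarray]:
    """Label-permutation significance threshold for decoding spectra.

    Per randomization the trial image labels are permuted, the decoding
    spectra recomputed, and the global maximum accuracy across frequencies
    and sites recorded; the threshold is the largest of the ``n_rand``
    maxima.
    """
    if n_rand < 10:
        raise ValueError("n_rand must be at least 10")
    ids = np.asarray(trial_image_ids)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_rand)
    for i in range(n_rand):
        perm_ids = ids[rng.permutation(ids.size)]
        spec = decoding_spectrum(stim_power, freqs, perm_ids, centers=centers,
                                 seed=seed + i + 1, site_groups=site_groups)
        maxima[i] = spec["accuracy"].max()
    return float(maxima.max()), maxima
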