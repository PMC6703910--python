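# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, what the synthetic generator emulates, and
the numerical decisions taken where the design was genuinely open.

## Signal model and preprocessing

Recordings are multichannel field potentials from an ordered chain of
electrodes over retinotopic visual cortex, sharing a common recording
reference. Preprocessing follows the standard intracranial chain:

- **Low-pass + downsample.** A zero-phase FIR low-pass (401 taps,
  Hamming-windowed design, cutoff 250 Hz, applied forward and backward)
  followed by rational-rate polyphase resampling to 1 kHz. Zero-phase
  filtering was chosen so epoch boundaries are not phase-shifted; the
  pass band below 0.8×cutoff is preserved within 1% and a 400-Hz tone is
  attenuated below 5% residual amplitude.
- **Bipolar derivation.** Site *k* = channel *k* − channel *k*+1 along
  the chain; *n* electrodes give *n*−1 sites. Any common component (the
  reference, shared artifacts) cancels identically; all downstream power
  analyses are invariant to the sign convention.
- **Epochs.** Per trial, a baseline window [−0.5, 0) s and a stimulation
  window [0.3, 0.8) s relative to stimulus onset, half-open so sample
  counts are exact (500 samples at 1 kHz). The first 0.3 s after onset
  are skipped to avoid the onset transient. Trials whose windows fall
  outside the recording are excluded with a logged warning.
- **Line noise.** No notch filter is applied in software; the 58–62 Hz
  band is annotated and excluded from the spectral-decomposition fit
  (below), on the assumption that the acquisition chain already notched
  the line during recording.

## Spectral estimation and gamma metrics

Each 0.5-s epoch is multiplied by a single periodic Hann taper and
Fourier transformed once — no multitaper, no zero padding — which yields
a native 2-Hz grid; power is kept on 4–200 Hz (99 bins) as a one-sided
PSD (`2|X|²/(fs·Σw²)`), so the integral over frequency equals the tapered
signal's power exactly (tested as a Parseval identity). Stimulus-induced
change is expressed per site and frequency as
`100 · (P_stim − P̄_base)/P̄_base`, with `P̄_base` the average over *all*
baseline epochs of that site.

Two per-image gamma metrics are computed, and a third formed from them:

1. **Band-power metric.** Stimulation power integrated over 30–80 Hz per
   epoch, as percent change against the band-integrated average baseline,
   averaged over the image's presentations. Band integration happens
   before the percent change so the metric is a single number per epoch.
2. **Narrowband-fit metric.** The average log10 spectrum of the image's
   stimulation epochs is decomposed over 35–200 Hz (excluding 58–62,
   118–122 and 178–182 Hz) into a broadband power law and a Gaussian bump
   in log-frequency:

       P(x) = β_bb − n·x + β_nb · exp(−(x−μ)² / 2σ²),  x = log10 f

   with the bump width fixed at 10^σ = 1.1 and the center constrained to
   35 < 10^μ < 80 Hz. The slope *n* is fixed per site by a least-squares
   line through the trial-averaged baseline spectrum in log–log
   coordinates over the same range. Given μ the model is linear in the
   βs, so the fit profiles μ: a grid search at 0.001 log10-unit spacing
   (the bump σ ≈ 0.0414 demands that resolution) with closed-form normal
   equations at each candidate, followed by bounded local refinement.
   β_nb is clipped at zero — it quantifies a narrowband *increase* — and
   is the metric. Fits on spectra generated exactly from the model
   recover β_nb to 1e−6 and 10^μ to 0.1 Hz. Absolute stimulation spectra
   are used (not baseline-normalized ones); the baseline enters only
   through the fixed slope.
3. **Average metric.** Per site, the mean of the two metrics' image
   ranks. Rank-averaging was chosen because the two metrics live on
   different scales (percent vs log10 power) and every downstream
   correlation is a Spearman correlation, for which only ranks matter.

The gamma peak frequency of a (pooled) percent-change spectrum is its
center of gravity over 30–80 Hz, Σf·p / Σp, with negative values clipped
to zero. (A weighted mean divided by Σf instead of Σp does not return a
frequency and is not used.)

## Image structure: RDF operators

The relative degree of focus of a luminance image in [0, 1] is computed
with 26 operators spanning the families used in shape-from-focus work:
gradient-based (Brenner, squared/thresholded gradient, energy of
gradient, Tenengrad and its variance, Gaussian derivative), Laplacian-
based (energy, modified, variance, diagonal), statistics-based (variance,
local variance, normalized variance, absolute central moment), DCT-based
(AC energy and AC/DC energy ratio on 8×8 blocks), wavelet-based (sum,
variance, detail/approximation ratio at one db6 level), and miscellaneous
(contrast, curvature, Helmli mean-ratio, steerable filters, spatial
frequency, Vollath autocorrelation). Where an operator produces a
pixel-level focus map it is pooled by the mean over the evaluated region;
operators classically defined as a region statistic (e.g. gray-level
variance) return it directly. Open hyper-parameters were fixed at
standard values: 3×3 local windows (5×5 for the Helmli measure), 8×8 DCT
blocks, one db6 wavelet level, replicate boundaries. Two stability
choices: the Helmli luminance ratio floors its inputs at 0.05 (otherwise
near-black pixels make the measure heavy-tailed), and the curvature
measure fits a local quadratic surface and pools only the non-constant
coefficients, so a constant image scores exactly zero.

Global RDF is the operator applied to the central 80% of the image (10%
trimmed from each edge against boundary effects). Patch-wise RDF covers
the full image with a 19×19 grid of square patches, each 0.1 of the edge
length, stepped by 0.05 — patches are not re-cropped. Every operator
decreases strictly under progressive Gaussian blur (σ = 0…8 px) and
changes by less than 5% under a 2-px circular shift; these are tested
invariants. The default operator throughout the headline analyses is DCT
energy.

## Statistical inference

All associations are Spearman rank correlations (Pearson on average
ranks; ties get average ranks). Two-sided p-values for single
correlations use the exact permutation distribution for n ≤ 10 and the
t approximation with n−2 degrees of freedom otherwise.

Multiple comparisons across frequencies (or patches) and sites are
controlled with a min/max-statistic randomization test: the per-image RDF
ranks are permuted (1000 times by default); after each permutation the
full statistic map is recomputed and only its global maximum and minimum
are stored; the 99th percentile of maxima and 1st percentile of minima
serve as two-sided family-wise p = 0.02 thresholds. The implementation is
vectorized (permutation matrix × rank matrix); a generic callback variant
exists for arbitrary statistics and is tested to agree with the fast
path. Calibration is itself a tested property: over 500 independent null
simulations (72 images, 5 sites × 99 frequencies), the fraction with any
supra-threshold value is statistically consistent with 0.02.

**RF maps.** For each site, patch RDF is correlated with the site's
band-power metric across images, per patch; the max-statistic correction
runs jointly over all patches and sites. On synthetic sessions the
supra-threshold region overlaps the generator's true RF disc (Jaccard
against the set of patches whose window intersects the disc), and
zero-coupling sessions yield fully masked maps at the nominal rate.

**8-bin analysis.** Images are sorted by global RDF (ties broken by image
index) and split into 8 contiguous bins of 9; per bin the percent-change
spectrum is averaged over the bin's images and all sites, then reduced to
the mean 30–80 Hz change and the center-of-gravity frequency.

## Pairwise decoding

For every unordered image pair (72 images → 2556 pairs) and every 20-Hz
window (11 bins on the 2-Hz grid; centers 14–190 Hz), each presentation
of either image is held out in turn, presentation counts of the remaining
trials are matched by random subselection, a linear SVM (C = 1) is
trained, and the held-out spectrum is classified; accuracy averages over
hold-outs and pairs. The subselection is seeded per (unordered pair,
held-out trial), making it identical across windows and sites — so
concatenated-site features stay aligned — and invariant under swapping
the pair's roles.

Features are the stimulation-epoch spectral power values of the window's
bins, centered by the training fold's mean but deliberately *not*
variance-standardized: for narrowband oscillatory power, the per-bin
variance across trials is itself class information, and scaling every
bin to unit variance hands pure-noise bins the same a-priori weight as
signal bins (measured on the calibrated synthetic session, per-bin
standardization costs about five points of concatenated accuracy). A
zero decision value is scored as half-correct, which makes chance exact
for degenerate inputs.

Because the procedure trains on the order of 10^5–10^6 ten-sample
problems, the solver is a batched dual coordinate-descent linear SVM
(the L1-loss dual with an augmented bias feature — the LinearSVC
formulation), vectorized over thousands of problems at once; its
predictions agree with sklearn's LinearSVC on randomly generated problems
(tested), and sklearn remains the independent cross-check rather than the
production path purely for speed. Site concatenation joins the per-trial
window features of the three sites with the highest own peak accuracy.
Significance uses the same max-statistic logic with trial-label
permutations; because decoding is expensive, 100 randomizations and the
distribution's maximum are the default.

## The synthetic generator

The generator stands in for a natural-image ECoG session and defines the
package's study conditions: 72 unique images, 6 presentations each (432
trials), 1-s stimuli with 0.6–1.4 s inter-stimulus intervals, 6
electrodes → 5 bipolar sites, 1 kHz sampling (a 3.05 kHz mode exists to
exercise the filter chain).

**Images** (256×256, representing 10°×10° of visual field) are
band-limited textures blended with their Gaussian-blurred version
according to a smooth random structure field, so they are sharp where the
field is high. The field is `level · s²`, where `s` is a smoothed random
surface (correlation length ≈ edge/12) and the per-image `level` is
spread evenly over 0.3–1.0. Squaring `s` makes sharp regions patchy:
images differ mainly in *where* they carry structure, not only in how
much, which is what gives patch-wise RF mapping something to localize.
The global level still orders mean structure, so the image ranking by
global RDF is well defined (rank correlation with the generating levels
> 0.9).

**Recording.** Each channel carries a shared common-reference artifact
(pink noise, 5× the channel noise RMS — removed exactly by the bipolar
derivation), independent 1/f² background noise (RMS 1, the unit of all
amplitudes), and a small-amplitude 60-Hz line (default 0.2) representing
the residual left by an acquisition-stage notch filter; per-channel line
amplitudes differ so a trace survives bipolar derivation. During each
stimulus, every site receives an independent broadband (white) increase
and a narrowband gamma burst. Site-specific components are injected via
telescoping channel sums (channel *c* carries sites *c*… last), so the
bipolar difference recovers exactly the intended per-site signal.

**Gamma bursts** are constant-envelope oscillations (100-ms cosine
ramps) whose instantaneous frequency wanders slowly around 55 Hz with a
2.5-Hz standard deviation — a spectral bump a few Hz wide with small
cycle-to-cycle phase jitter. This was chosen over bandpass-filtered
noise deliberately: filtered noise has Rayleigh-distributed epoch power
(CV ≈ 45%), which is not "small jitter" and swamps the image-to-image
amplitude differences the decoding analyses exist to detect; with a
constant envelope, the injected power per trial is essentially
deterministic and the remaining trial noise is the physically
unavoidable beating between signal and background.

**Coupling.** Per site, the RDF (default operator) of each image inside
the site's RF disc — discs of radius 0.12 centered between the two
electrodes' visual-field positions, laid out along an eccentricity axis
(last site parafoveal) — is rank-transformed to u ∈ [0, 1], and the
burst RMS is `gamma_base_amp · (1 + coupling_gain · u)`. The defaults
(0.095, 1.44) were calibrated once, analytically from the measured
baseline band power of the default session, so that the mean gamma-band
percent change spans roughly 100–300% from the lowest to the highest
RDF octile; they are part of the study conditions, not free knobs.
Ground truth (structure fields, RF discs, per-trial injected amplitudes)
is returned for recovery tests.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: eye movements and fixation instability,
attention and arousal fluctuations, evoked onset transients, cross-site
correlated noise beyond the common reference, gamma frequency shifts with
stimulus drive (the injected frequency is fixed; the small negative
octile trend in the recovered center-of-gravity frequency reflects
spectral asymmetry of the percent-change normalization, not an injected
effect), non-stationary line noise, and of course real image statistics —
the textures share none of the object structure of natural photographs.
Positive results on the generator demonstrate that the analysis chain
recovers a known coupling at realistic SNR; they do not by themselves
validate claims about cortex.

## Numerical choices and degenerate inputs

- Spearman on constant input raises rather than returning NaN.
- Percent change requires strictly positive baseline power per bin.
- The decomposition keeps the grid optimum if local refinement fails to
  improve it; an all-excluded fit range is an error.
- `rank_images` uses average ranks for ties (required for Spearman
  consistency); bin assignment breaks RDF ties by image index.
- Decoding problems are grouped by training-set size so batches stay
  rectangular when presentation counts vary (5–7 presentations are
  supported; the default is 6).
- All randomness flows from explicit seeds: the session config seed, the
  analysis seed (randomization tests), and the decoding master seed.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run at the study's native scale
where that is cheap (full 432-trial sessions, all 2556 pairs, 1000
permutations) and at reduced scale where the full grid adds nothing to
the check: decoding spectra are evaluated on a representative subset of
window centers (a coarse scan spanning low, gamma and high frequencies
for site selection, then gamma-band centers for the concatenated
readout), and the zero-coupling negative controls use 50 reduced sessions
(128-px images, 3 presentations) since the null calibration is
scale-free. The family-wise error calibration uses 500 null datasets at
the full 5 × 99 statistic size with 1000 permutations each.
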