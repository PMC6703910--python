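# gammastruct

Links image-computable metrics of natural-image structure to visually
induced gamma-band activity in intracranial (ECoG-style) field-potential
recordings.

Visual cortex responds to structured stimuli with narrowband gamma
oscillations (30–80 Hz), but many natural images seem to induce little or
no gamma. This package implements the analysis chain needed to test a
quantitative resolution of that puzzle: that the *graded* amount of sharp
structure in an image — measured with relative-degree-of-focus (RDF)
operators from machine vision — predicts the graded strength of the gamma
response. It is aimed at electrophysiologists and computational
neuroscientists who want to relate image content to spectral responses,
and it ships a fully seeded synthetic image + LFP generator so every
analysis runs end to end with no data download.

## What is inside

- **`synth`** — stimulus images with a controllable spatial "structure
  field" and a matched multichannel recording: common-reference artifact,
  1/f^n background, 60-Hz line residual, stimulus-driven broadband
  increase, and a narrowband gamma oscillation whose amplitude on each
  bipolar site follows the RDF of the image inside that site's simulated
  receptive-field (RF) disc. Ground truth is returned for recovery tests.
- **`operators` / `focus`** — 26 focus-measure operators (gradient-,
  Laplacian-, statistics-, DCT- and wavelet-based), global RDF on the
  central 80% of the image, and patch-wise RDF on a 19×19 grid (patches
  0.1 of the edge, stepped by 0.05).
- **`preprocess`** — zero-phase low-pass filtering and downsampling,
  bipolar derivation (site *k* = channel *k* − channel *k*+1), and
  extraction of baseline ([−0.5, 0) s) and stimulation ([0.3, 0.8) s)
  epochs.
- **`spectral`** — single Hann-taper power on the 4–200 Hz, 2-Hz grid;
  percent power change against the trial-averaged baseline; the
  band-power gamma metric (30–80 Hz change per image); center-of-gravity
  gamma frequency; time-resolved power.
- **`gammafit`** — decomposition of the average log10 spectrum into a
  broadband power law and a narrowband Gaussian bump in log-frequency,

  `P(x) = β_bb − n·x + β_nb · exp(−(x−μ)²/2σ²)`,  `x = log10 f`,

  with 10^σ = 1.1, 35 < 10^μ < 80 Hz and the slope *n* fixed per site
  from the baseline spectrum; β_nb is the narrowband gamma metric.
- **`inference`** — Spearman correlation of RDF with the gamma metrics
  (per site, per frequency, per patch), min/max-statistic randomization
  correction (family-wise two-sided p = 0.02 across frequencies/patches
  and sites), RF correlation maps with significance masks, and the 8-bin
  RDF analysis.
- **`decoding`** — leave-one-presentation-out pairwise image
  classification with a linear SVM on 20-Hz spectral windows (11 bins),
  with presentation counts matched by seeded subselection, site
  concatenation, and label-permutation significance. The inner solver is
  a batched dual coordinate-descent linear SVM vectorized over thousands
  of small training problems.
- **`pipeline` / CLI** — one-config orchestration:
  `gammastruct run --config cfg.yaml`, plus `gammastruct synth`,
  `gammastruct rdf`, `gammastruct decode`, `gammastruct validate`.

## Worked example

```python
import numpy as np
from gammastruct import (SessionConfig, generate_images, generate_session,
                         bipolar_derive, extract_epochs, compute_power,
                         percent_change, band_power_change, narrowband_metric,
                         compute_rdf, correlate_rdf_gamma, bin_by_rdf)

cfg = SessionConfig(seed=1)                      # 72 images x 6 presentations
images, truth = generate_images(cfg)
raw, trials, truth = generate_session(cfg, images, truth)

epochs = extract_epochs(bipolar_derive(raw), trials)
stim = compute_power(epochs, "stimulation")
base = compute_power(epochs, "baseline")
pc, image_ids = percent_change(stim, base, per_image=True)

bandpower, _ = band_power_change(stim, base)     # 30-80 Hz % change per image
narrowband, _, _ = narrowband_metric(stim, base) # Gaussian-bump amplitude
rdf = np.array([compute_rdf(img) for img in images])  # DCT energy

for metric, values in [("bandpower", bandpower), ("narrowband", narrowband)]:
    r, p = correlate_rdf_gamma(rdf, narrowband, bandpower, metric)
    print(f"{metric:>10}: R per site = {np.round(r, 2)}")

bins = bin_by_rdf(rdf, pc, stim.freqs)
print("gamma change per RDF octile (%):",
      np.round(bins['gamma_change_pct'].to_numpy()).astype(int))
```

prints

```
 bandpower: R per site = [0.66 0.7  0.68 0.65 0.7 ]
narrowband: R per site = [0.59 0.69 0.6  0.53 0.67]
gamma change per RDF octile (%): [110 140 165 195 204 201 239 296]
```

Each R is the Spearman rank correlation, across the 72 images, between
the image's global RDF (DCT energy) and one recording site's gamma
response — positive at every site for both metrics, because the generator
injects gamma whose amplitude follows local image structure. The octile
row shows the induced gamma-band power change growing monotonically from
roughly 100% to 300% as image structure increases.

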