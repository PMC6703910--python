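"""Reading and writing of images, sessions, and result tables.

A synthetic (or external) session is stored as a documented plain
container:

- ``signals.npy``   -- float array, channels x samples
- ``meta.json``     -- sample rate, channel labels
- ``trials.csv``    -- one row per presentation: onset_sample, image_id
- ``ground_truth.json`` / ``structure_fields.npy`` -- generator ground
  truth (only for synthetic sessions)

Images are 8-bit grayscale PNG files named ``img_<id>.png``.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .preprocess import RawRecording
from .synth import GroundTruth

__all__ = ["save_images", "load_images", "save_session", "load_session",
           "save_ground_truth", "load_ground_truth"]


def save_images(out_dir, images) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(images):
        arr = np.clip(np.asarray(img) * 255.0, 0, 255).round().astype(np.uint8)
        p = out_dir / f"img_{i:03d}.png"
        iio.imwrite(p, arr)
        paths.append(p)
    return paths


def load_images(img_dir) -> np.ndarray:
    paths = sorted(Path(img_dir).glob("img_*.png"))
    if not paths:
        raise FileNotFoundError(f"no img_*.png files in {img_dir}")
    return np.stack([np.asarray(iio.imread(p), dtype=np.float64) / 255.0
                     for p in paths])


def save_session(out_dir, raw: RawRecording, trials: pd.DataFrame,
                 truth: GroundTruth | None = None) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.save(out_dir / "signals.npy", raw.data)
    (out_dir / "meta.json").write_text(json.dumps({
        "rate_hz": raw.rate_hz,
        "channel_labels": raw.channel_labels,
    }, indent=2))
    trials.to_csv(out_dir / "trials.csv", index=False)
    if truth is not None:
        save_ground_truth(out_dir, truth)


def load_session(session_dir) -> tuple[RawRecording, pd.DataFrame]:
    session_dir = Path(session_dir)
    meta = json.loads((session_dir / "meta.json").read_text())
    data = np.load(session_dir / "signals.npy")
    trials = pd.read_csv(session_dir / "trials.csv")
    return RawRecording(data, meta["rate_hz"], meta["channel_labels"]), trials


def save_ground_truth(out_dir, truth: GroundTruth) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = {"structure_levels": truth.structure_levels.tolist(),
           "rf_radius": truth.rf_radius}
    for name in ("site_rf_centers", "local_rdf", "gamma_amplitude",
                 "trial_gamma_amplitude", "trial_broadband_scale"):
        arr = getattr(truth, name)
        doc[name] = None if arr is None else np.asarray(arr).tolist()
    (out_dir / "ground_truth.json").write_text(json.dumps(doc))
    np.save(out_dir / "structure_fields.npy", truth.structure_fields)


def load_ground_truth(session_dir) -> GroundTruth:
    session_dir = Path(session_dir)
    doc = json.loads((session_dir / "ground_truth.json").read_text())
    fields = np.load(session_dir / "structure_fields.npy")
    kwargs = {k: (None if doc[k] is None else np.asarray(doc[k]))
              for k in ("site_rf_centers", "local_rdf", "gamma_amplitude",
                        "trial_gamma_amplitude", "trial_broadband_scale")}
    return GroundTruth(structure_levels=np.asarray(doc["structure_levels"]),
                       structure_fields=fields,
                       rf_radius=doc["rf_radius"], **kwargs)
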