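"""End-to-end orchestration: synthesis -> preprocessing -> spectra ->
gamma metrics -> RDF -> inference -> decoding, from one configuration.

Every stage writes flat CSV/JSON outputs into the run directory; the
machine-readable ``summary.json`` echoes the configuration, its hash, and
the headline numbers (correlations, thresholds, decoding peaks).  Any
stage failure halts the run with a stage-tagged error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decoding as dec
from . import focus, gammafit, inference, io as gio, spectral, synth
from .preprocess import bipolar_derive, extract_epochs, lowpass_downsample
from .synth import SessionConfig

__all__ = ["RunConfig", "load_config", "validate_config", "run_all"]

logger = logging.getLogger(__name__)

_VALID_MODES = ("synthetic", "external-data")


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    out_dir: str = "results"
    mode: str = "synthetic"
    session: SessionConfig = dc_field(default_factory=SessionConfig)
    session_dir: str | None = None  # external-data mode
    images_dir: str | None = None
    operator: str = focus.DEFAULT_OPERATOR
    gamma_band: tuple[float, float] = spectral.GAMMA_BAND_HZ
    n_rand: int = 1000
    n_bins: int = 8
    analysis_seed: int = 0
    run_decoding: bool = True
    decoding_centers: list[float] | None = None  # None -> full window grid
    n_rand_decode: int = 0  # label-permutation threshold; 0 skips it

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["session"]["rf_centers"] = np.asarray(
            self.session.rf_centers).tolist()
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    errors = validate_config(doc)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(f"- {e}" for e in errors))
    session = SessionConfig(**doc.pop("session", {}))
    return RunConfig(session=session, **doc)


def validate_config(doc: dict) -> list[str]:
    """Report unknown keys, out-of-range values and missing files."""
    errors = []
    known = {f.name for f in dataclasses.fields(RunConfig)}
    session_known = {f.name for f in dataclasses.fields(SessionConfig)}
    for key in doc:
        if key not in known:
            errors.append(f"unknown key: {key}")
    for key in doc.get("session", {}) or {}:
        if key not in session_known:
            errors.append(f"unknown session key: {key}")
    mode = doc.get("mode", "synthetic")
    if mode not in _VALID_MODES:
        errors.append(f"mode must be one of {_VALID_MODES}")
    band = doc.get("gamma_band")
    if band is not None and (len(band) != 2 or band[1] <= band[0]):
        errors.append("gamma_band upper edge must exceed the lower edge")
    op = doc.get("operator")
    if op is not None and op not in focus.operator_ids():
        errors.append(
            f"unknown operator {op!r}; valid ids: {', '.join(focus.operator_ids())}")
    if mode == "external-data":
        for key in ("session_dir", "images_dir"):
            p = doc.get(key)
            if p is None:
                errors.append(f"external-data mode requires {key}")
            elif not Path(p).exists():
                errors.append(f"{key} does not exist: {p}")
    if doc.get("n_rand", 1000) < 1:
        errors.append("n_rand must be positive")
    try:
        SessionConfig(**(doc.get("session", {}) or {}))
    except (TypeError, ValueError) as exc:
        errors.append(f"session: {exc}")
    return errors


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"[{stage}] {exc}")
        self.stage = stage


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return inner
    return wrap


@_stage("session")
def _get_session(config: RunConfig, out: Path):
    if config.mode == "synthetic":
        images, truth = synth.generate_images(config.session)
        raw, trials, truth = synth.generate_session(config.session, images, truth)
        return images, raw, trials, truth
    if config.session_dir is None or config.images_dir is None:
        raise ValueError("external-data mode requires session_dir and images_dir")
    raw, trials = gio.load_session(config.session_dir)
    images = gio.load_images(config.images_dir)
    return images, raw, trials, None


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write the result bundle; returns the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    summary: dict = {"config_hash": chash, "config": config.to_dict()}

    images, raw, trials, truth = _get_session(config, out)

    @_stage("preprocess")
    def _preprocess():
        rec = raw
        if rec.rate_hz != 1000.0:
            rec = lowpass_downsample(rec, 250.0, 1000.0)
        sites = bipolar_derive(rec)
        return sites, extract_epochs(sites, trials)

    sites, epochs = _preprocess()
    summary["n_sites"] = epochs.n_sites
    summary["n_trials"] = epochs.n_trials

    @_stage("spectral")
    def _spectra():
        stim = spectral.compute_power(epochs, "stimulation")
        base = spectral.compute_power(epochs, "baseline")
        pc, img_ids = spectral.percent_change(stim, base, per_image=True)
        bandpower, _ = spectral.band_power_change(stim, base, config.gamma_band)
        return stim, base, pc, img_ids, bandpower

    stim, base, pc, img_ids, bandpower = _spectra()

    @_stage("gamma_fit")
    def _narrowband():
        values, ids, _ = gammafit.narrowband_metric(stim, base)
        return values

    narrowband = _narrowband()

    @_stage("focus_metrics")
    def _rdf():
        table = focus.rdf_table(images, image_ids=range(len(images)))
        scores = np.array([focus.compute_rdf(img, config.operator)
                           for img in images])
        patch = np.stack([focus.patchwise_rdf(img, config.operator)
                          for img in images])
        return table, scores, patch

    rdf_all, rdf_scores, patch_rdf = _rdf()
    rdf_all.to_csv(out / "rdf_table.csv", index=False)

    @_stage("inference")
    def _inference():
        res: dict = {}
        metrics = inference.gamma_metrics_table(
            narrowband, bandpower, img_ids, epochs.site_labels)
        metrics.to_csv(out / "gamma_metrics.csv", index=False)
        for metric in ("narrowband", "bandpower", "average"):
            r, p = inference.correlate_rdf_gamma(rdf_scores[img_ids], narrowband,
                                                 bandpower, metric)
            res[f"corr_{metric}"] = {"R": r.tolist(), "P": p.tolist()}
        n_sites, n_images, n_freqs = pc.shape
        obs, rand = inference.maxstat_spearman(
            rdf_scores[img_ids], pc.transpose(1, 0, 2).reshape(n_images, -1),
            n_rand=config.n_rand, seed=config.analysis_seed)
        spec_r = obs.reshape(n_sites, n_freqs)
        pd.DataFrame(spec_r, columns=stim.freqs).assign(
            site=epochs.site_labels).to_csv(out / "correlation_spectra.csv",
                                            index=False)
        res["corr_spectrum_thresholds"] = {"upper": rand.upper,
                                           "lower": rand.lower}
        maps, masks, rf_rand = inference.rf_correlation_maps(
            patch_rdf[img_ids], bandpower, n_rand=config.n_rand,
            seed=config.analysis_seed + 1)
        gh, gw = maps.shape[1:]
        sidx, rows, cols = np.meshgrid(np.arange(maps.shape[0]),
                                       np.arange(gh), np.arange(gw),
                                       indexing="ij")
        pd.DataFrame({"site": sidx.ravel(), "row": rows.ravel(),
                      "col": cols.ravel(), "R": maps.ravel(),
                      "significant": masks.ravel()}).to_csv(
            out / "rf_maps.csv", index=False)
        res["rf_thresholds"] = {"upper": rf_rand.upper, "lower": rf_rand.lower}
        bins = inference.bin_by_rdf(rdf_scores[img_ids], pc, stim.freqs,
                                    n_bins=config.n_bins, band=config.gamma_band)
        bins.to_csv(out / "rdf_bins.csv", index=False)
        res["bins_gamma_change"] = bins["gamma_change_pct"].tolist()
        return res

    summary["inference"] = _inference()

    if config.run_decoding:
        @_stage("decoding")
        def _decode():
            ids = epochs.image_ids
            pairs = dec.enumerate_pairs(np.unique(ids))
            problems = dec.build_problems(ids, seed=config.analysis_seed)
            spec = dec.decoding_spectrum(stim.power, stim.freqs, ids,
                                         centers=config.decoding_centers,
                                         problems=problems)
            best = dec.select_best_sites(spec, 3)
            gamma_centers = [c for c in sorted(spec["center_freq"].unique())
                             if config.gamma_band[0] <= c <= config.gamma_band[1]]
            concat = dec.decoding_spectrum(
                stim.power, stim.freqs, ids, centers=gamma_centers,
                site_groups=[("concat", tuple(best))], problems=problems)
            full = pd.concat([spec, concat], ignore_index=True)
            full.to_csv(out / "decoding_spectrum.csv", index=False)
            info = {"n_pairs": len(pairs), "best_sites": best,
                    "peak_accuracy": float(spec["accuracy"].max()),
                    "concat_peak_accuracy": float(concat["accuracy"].max())}
            if config.n_rand_decode:
                thr, _ = dec.decode_significance(
                    stim.power, stim.freqs, ids,
                    centers=config.decoding_centers,
                    n_rand=config.n_rand_decode, seed=config.analysis_seed)
                info["threshold"] = thr
            return info

        summary["decoding"] = _decode()

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str))
    logger.info("run %s complete -> %s", chash, out)
    return summary
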