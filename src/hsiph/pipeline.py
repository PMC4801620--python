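"""End-to-end pipeline: simulate -> calibrate -> extract -> train -> map.

Orchestrates the full workflow behind a single config (YAML/JSON/dict):
reflectance calibration, dish segmentation, pixel-spectra extraction,
wavelet denoising and averaging, 2:1 calibration/prediction split, band
selection (SPA / random frog / VIP), PLS and BPNN calibration, metric
tables, and the pixel-wise pH distribution map.  Every stage writes its
artefacts under the output directory and the run ends with a JSON
manifest recording seeds, configuration, metric rows and file hashes, so
a rerun with the same config is verifiably identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import calibrate as cal
from . import io as hio
from . import mapping as hmap
from . import preprocess as prep
from . import selection as sel
from . import synthetic as syn

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

_LOG_FORMAT = "%(asctime)s %(name)s %(levelname)s %(message)s"


def _setup_logging(out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    root = logging.getLogger("hsiph")
    root.setLevel(logging.INFO)
    if not any(isinstance(h, logging.FileHandler)
               and getattr(h, "_hsiph_run", None) == out_dir
               for h in root.handlers):
        handler = logging.FileHandler(os.path.join(out_dir, "run.log"))
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        handler._hsiph_run = out_dir  # type: ignore[attr-defined]
        root.addHandler(handler)


@dataclass
class PipelineConfig:
    """Run configuration with study-matching defaults.

    Defaults: db5/level-5 wavelet, crop 1042.16-1578.13 nm, 2:1 split,
    SPA chain lengths 5-30, random frog N = 10 000, VIP threshold 1.21.
    """

    out_dir: str = "hsiph_run"
    seed: int = 0
    # data source: simulate a phantom study, or point at existing files
    simulate: bool = True
    n_samples: int = 93
    n_pixels_per_sample: int = 300                # dish-interior subsample
    phantom: dict = field(default_factory=dict)   # PhantomConfig overrides
    # external inputs (used when simulate = False)
    raw_cube: str | None = None
    white_cube: str | None = None
    dark_cube: str | None = None
    sample_spectra_csv: str | None = None
    reference_ph_csv: str | None = None
    # processing
    crop_nm: tuple[float, float] = (1042.16, 1578.13)
    wavelet: dict = field(default_factory=dict)   # WaveletSpec overrides
    split_ratio: tuple[int, int] = (2, 1)
    erode_px: int | None = None                   # default: phantom ring width
    # modelling
    selection_methods: tuple[str, ...] = ("spa",)
    spa_k: tuple[int, int] = (5, 30)
    rf_iterations: int = 10_000
    vip_threshold: float = 1.21
    models: tuple[str, ...] = ("pls", "bpnn")
    max_lv: int = 15
    cv_folds: int = 5
    bpnn_epochs: int = 1500
    bpnn_learning_rate: float = 0.01
    # mapping
    map_model: str = "spa+bpnn"                   # "<selection|full>+<model>"
    colormap: str = "jet"

    def wavelet_spec(self) -> prep.WaveletSpec:
        return prep.WaveletSpec(**self.wavelet)

    def phantom_config(self) -> syn.PhantomConfig:
        kwargs = dict(self.phantom)
        kwargs.setdefault("seed", self.seed)
        return syn.PhantomConfig(**kwargs)


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Load a YAML/JSON config document; unknown keys are rejected."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("crop_nm", "split_ratio", "selection_methods", "models", "spa_k"):
        if key in doc and isinstance(doc[key], list):
            doc[key] = tuple(doc[key])
    return PipelineConfig(**doc)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, cause: Exception, manifest: dict):
        super().__init__(f"pipeline aborted at stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause
        self.manifest = manifest


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages (each usable on its own through the CLI)
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> dict:
    """Generate the phantom study: one mapped scene + the sample set.

    Sample spectra follow the study's flow — crop each noisy pixel spectrum
    to the working range, wavelet-denoise it, then average over the dish —
    so the nonlinear shrinkage acts on the same noise level at training time
    as when the model is later applied pixel-wise.
    """
    pc = cfg.phantom_config()
    paths = syn.save_phantom(os.path.join(cfg.out_dir, "phantom"), pc)
    rng = np.random.default_rng(pc.seed + 1)
    wspec = cfg.wavelet_spec()
    lo, hi = cfg.crop_nm
    rows, phs, wl_crop = [], [], None
    for pixels, ph_i in syn.generate_sample_pixels(
            pc, cfg.n_samples, rng=rng, n_pixels=cfg.n_pixels_per_sample):
        sel = (pixels.wavelengths >= lo - 1e-6) & (pixels.wavelengths <= hi + 1e-6)
        wl_crop = pixels.wavelengths[sel]
        sub = hio.SpectraMatrix(pixels.data[:, sel], wl_crop, pixels.ids)
        rows.append(prep.mean_sample_spectrum(sub, wspec))
        phs.append(ph_i)
    ids = [f"s{i:03d}" for i in range(cfg.n_samples)]
    spectra = hio.SpectraMatrix(np.stack(rows), wl_crop, ids)
    ph = np.asarray(phs)
    sample_path = os.path.join(cfg.out_dir, "samples.csv")
    syn.save_sample_set(sample_path, spectra, ph)
    ph_path = os.path.join(cfg.out_dir, "reference_ph.csv")
    pd.DataFrame({"id": spectra.ids, "ph": ph}).to_csv(ph_path, index=False)
    paths.update(samples=sample_path, reference_ph=ph_path)
    logger.info("simulated %d samples and one phantom scene", cfg.n_samples)
    return paths


def stage_calibrate(cfg: PipelineConfig, paths: dict) -> dict:
    raw = hio.read_envi(paths["raw"])
    white = hio.read_envi(paths["white"])
    dark = hio.read_envi(paths["dark"])
    refl = hio.calibrate_reflectance(raw, white, dark)
    refl = hio.crop_bands(refl, *cfg.crop_nm)
    out = hio.write_envi(refl, os.path.join(cfg.out_dir, "reflectance.img"),
                         dtype=np.float32)
    return {"reflectance": out}


def stage_extract(cfg: PipelineConfig, paths: dict) -> dict:
    cube = hio.read_envi(paths["reflectance"])
    erode = cfg.erode_px
    if erode is None:
        erode = int(np.ceil(cfg.phantom_config().edge_ring_width)) if cfg.simulate else 0
    roi = hio.segment_dish(cube, erode_px=erode)
    pixels = hio.extract_roi_spectra(cube, roi)
    out = os.path.join(cfg.out_dir, "roi_mask.csv")
    np.savetxt(out, roi.mask.astype(int), delimiter=",", fmt="%d")
    px_path = os.path.join(cfg.out_dir, "roi_spectra.csv")
    pixels.to_csv(px_path)
    return {"roi_mask": out, "roi_spectra": px_path, "n_roi_pixels": roi.n_pixels}


def _load_samples(cfg: PipelineConfig, paths: dict):
    spectra_path = paths.get("samples") or cfg.sample_spectra_csv
    if spectra_path is None or not os.path.exists(spectra_path):
        raise FileNotFoundError("sample spectra CSV not found")
    ph_path = paths.get("reference_ph") or cfg.reference_ph_csv
    spectra, ph = syn.load_sample_set(spectra_path)
    return spectra, ph, ph_path


def stage_train(cfg: PipelineConfig, paths: dict) -> dict:
    """Denoise/crop sample spectra, split, select bands, fit + evaluate models."""
    spectra, ph, ph_path = _load_samples(cfg, paths)
    wspec = cfg.wavelet_spec()
    cube_like = hio.Hypercube(spectra.data[None, :, :], spectra.wavelengths)
    cropped = hio.crop_bands(cube_like, *cfg.crop_nm)
    X_all = np.stack([prep.wavelet_denoise(s, wspec) for s in cropped.data[0]])
    wl = cropped.wavelengths

    # split (the reference-pH table is the split's authority)
    if ph_path is None or not os.path.exists(str(ph_path)):
        raise FileNotFoundError("reference-pH CSV not found")
    ref = pd.read_csv(ph_path)
    ids = ref["id"].astype(str).tolist()
    ph = ref["ph"].to_numpy(float)
    split = prep.split_samples(ids, ph, ratio=cfg.split_ratio, seed=cfg.seed)
    id_index = {sid: i for i, sid in enumerate(spectra.ids)}
    cal_idx = np.array([id_index[i] for i in split.calibration_ids])
    prd_idx = np.array([id_index[i] for i in split.prediction_ids])
    Xc, yc = X_all[cal_idx], ph[cal_idx]
    Xp, yp = X_all[prd_idx], ph[prd_idx]
    split_path = os.path.join(cfg.out_dir, "split.csv")
    pd.DataFrame({
        "id": split.calibration_ids + split.prediction_ids,
        "set": ["calibration"] * split.n_calibration
               + ["prediction"] * split.n_prediction,
        "ph": np.concatenate([yc, yp]),
    }).to_csv(split_path, index=False)

    # band selection on the calibration set
    selections: dict[str, sel.SelectionResult | None] = {"full": None}
    max_lv = min(cfg.max_lv, Xc.shape[1], len(yc) - 1)
    a_full, _ = cal.choose_n_components(Xc, yc, max_lv, cfg.cv_folds, cfg.seed)
    pls_full = cal.fit_pls(Xc, yc, a_full)
    for method in cfg.selection_methods:
        if method == "spa":
            selections["spa"] = sel.spa_select(
                Xc, yc, *cfg.spa_k, folds=cfg.cv_folds, seed=cfg.seed,
                wavelengths=wl)
        elif method == "rf":
            _, res = sel.random_frog(
                Xc, yc, n_iterations=cfg.rf_iterations, seed=cfg.seed,
                wavelengths=wl)
            selections["rf"] = res
        elif method == "vip":
            selections["vip"] = sel.vip_select(
                sel.vip_scores(pls_full, cfg.vip_threshold), wavelengths=wl)
        else:
            raise ValueError(f"unknown selection method {method!r}")

    # fit + evaluate each (selection, model) pair
    rows = []
    trained: dict[str, Any] = {}
    val_n = max(len(yc) // 5, 2)
    rng = np.random.default_rng(cfg.seed)
    val_idx = rng.choice(len(yc), val_n, replace=False)
    tr_idx = np.setdiff1d(np.arange(len(yc)), val_idx)
    for sname, selection in selections.items():
        if selection is not None and selection.n_selected == 0:
            logger.warning("selection %s is empty; skipped", sname)
            continue
        cols = (selection.selected_indices if selection is not None
                else np.arange(X_all.shape[1]))
        Xc_s, Xp_s = Xc[:, cols], Xp[:, cols]
        for mname in cfg.models:
            if mname == "pls":
                a, _ = cal.choose_n_components(
                    Xc_s, yc, min(cfg.max_lv, len(cols), len(yc) - 1),
                    cfg.cv_folds, cfg.seed)
                model = cal.fit_pls(Xc_s, yc, a)
                size_label = f"{a} LVs"
            elif mname == "bpnn":
                tc = cal.BPNNTrainConfig(cfg.bpnn_epochs,
                                         cfg.bpnn_learning_rate, cfg.seed)
                model, nodes, _ = cal.select_bpnn_nodes(
                    Xc_s[tr_idx], yc[tr_idx],
                    validation=(Xc_s[val_idx], yc[val_idx]), train_config=tc)
                model = cal.fit_bpnn(Xc_s, yc, nodes,
                                     cal.BPNNTrainConfig(cfg.bpnn_epochs,
                                                         cfg.bpnn_learning_rate,
                                                         cfg.seed + nodes))
                size_label = f"{nodes} nodes"
            else:
                raise ValueError(f"unknown model {mname!r}")
            report = cal.evaluate_model(model, Xc_s, yc, Xp_s, yp)
            key = f"{sname}+{mname}"
            trained[key] = (model, selection)
            rows.append({"model": key, "n_bands": len(cols),
                         "size": size_label, **report.to_row()})
            logger.info("%s: r_p=%.3f RMSEP=%.4f", key, report.r_p, report.rmsep)
    metrics = pd.DataFrame(rows)
    metrics_path = os.path.join(cfg.out_dir, "metrics.csv")
    metrics.to_csv(metrics_path, index=False)

    return {
        "split": split_path,
        "metrics": metrics_path,
        "metrics_rows": rows,
        "split_stats": {"calibration": split.calibration_stats,
                        "prediction": split.prediction_stats,
                        "attempts": split.attempts},
        "selections": {k: v.to_dict() for k, v in selections.items()
                       if v is not None},
        "trained": trained,
        "calibration_range": (float(yc.min()), float(yc.max())),
        "wavelengths": wl,
    }


def stage_map(cfg: PipelineConfig, paths: dict, train_out: dict) -> dict:
    cube = hio.read_envi(paths["reflectance"])
    mask = np.loadtxt(paths["roi_mask"], delimiter=",").astype(bool)
    roi = hio.ROIMask(mask)
    key = cfg.map_model
    if key not in train_out["trained"]:
        raise ValueError(f"map_model {key!r} was not trained "
                         f"(available: {sorted(train_out['trained'])})")
    model, selection = train_out["trained"][key]
    dist = hmap.predict_map(
        cube, roi, model, selection=selection, wavelet=cfg.wavelet_spec(),
        calibration_range=train_out["calibration_range"])
    png = hmap.render_map(dist, os.path.join(cfg.out_dir, "ph_map.png"),
                          colormap_name=cfg.colormap)
    out = {"map_png": png,
           "fraction_out_of_range": dist.fraction_flagged}
    truth_path = paths.get("ph_map")
    if truth_path and os.path.exists(truth_path):
        truth = np.loadtxt(truth_path, delimiter=",")
        both = roi.mask & np.isfinite(truth)
        out["map_mae_vs_truth"] = float(
            np.mean(np.abs(dist.values[both] - truth[both])))
    return out


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Execute the full workflow; returns (and writes) the run manifest."""
    cfg = (config if isinstance(config, PipelineConfig)
           else PipelineConfig(**config))
    os.makedirs(cfg.out_dir, exist_ok=True)
    _setup_logging(cfg.out_dir)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "seed": cfg.seed,
        "stages": {},
    }
    paths: dict = {}
    stage = "simulate"
    try:
        if cfg.simulate:
            paths.update(stage_simulate(cfg))
        else:
            for k, p in (("raw", cfg.raw_cube), ("white", cfg.white_cube),
                         ("dark", cfg.dark_cube)):
                if p is not None:
                    paths[k] = p
            if cfg.sample_spectra_csv:
                paths["samples"] = cfg.sample_spectra_csv
            if cfg.reference_ph_csv:
                paths["reference_ph"] = cfg.reference_ph_csv
        manifest["stages"]["simulate"] = {k: v for k, v in paths.items()
                                          if isinstance(v, str)}
        if all(k in paths for k in ("raw", "white", "dark")):
            stage = "calibrate"
            paths.update(stage_calibrate(cfg, paths))
            manifest["stages"]["calibrate"] = {"reflectance": paths["reflectance"]}
            stage = "extract"
            extract_out = stage_extract(cfg, paths)
            paths.update(extract_out)
            manifest["stages"]["extract"] = {
                k: v for k, v in extract_out.items() if not isinstance(v, dict)}
        stage = "split"
        # the reference-pH table must exist before training can split
        ph_path = paths.get("reference_ph") or cfg.reference_ph_csv
        if ph_path is None or not os.path.exists(str(ph_path)):
            raise FileNotFoundError("reference-pH CSV not found")
        stage = "train"
        train_out = stage_train(cfg, paths)
        manifest["stages"]["train"] = {
            "split": train_out["split"],
            "metrics": train_out["metrics_rows"],
            "split_stats": train_out["split_stats"],
            "selections": train_out["selections"],
        }
        if "reflectance" in paths and cfg.map_model in train_out["trained"]:
            stage = "map"
            map_out = stage_map(cfg, paths, train_out)
            manifest["stages"]["map"] = map_out
    except Exception as exc:
        manifest["aborted_at"] = stage
        manifest["error"] = str(exc)
        _write_manifest(cfg, manifest)
        raise PipelineStageError(stage, exc, manifest) from exc

    manifest["file_hashes"] = {
        k: _sha256(v) for k, v in sorted(paths.items())
        if isinstance(v, str) and os.path.isfile(v)}
    _write_manifest(cfg, manifest)
    return manifest


def _write_manifest(cfg: PipelineConfig, manifest: dict) -> str:
    path = os.path.join(cfg.out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
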