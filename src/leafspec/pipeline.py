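"""Orchestration of the four-step workflow: characteristic-wavelength
selection from spectra, leaf-image feature extraction, network
training, and prediction/evaluation.

Each stage reads CSV/PNG artifacts, writes new files into its output
directory (inputs are never mutated), and records its seeds and timing
in a JSON manifest so a run is reproducible from the config alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnn as _cnn
from . import metrics as _metrics
from .chemometrics import compare_bands, compare_preprocessing
from .imaging import extract_features_dir
from .preprocess import PreprocessMethod, SGFilterSpec, apply_method
from .spectra import SpectraMatrix
from .wavelengths import CharacteristicBandSelector

log = logging.getLogger("leafspec")

__all__ = ["PipelineConfig", "run_wavelength_stage", "run_training_stage",
           "run_predict"]


@dataclass
class PipelineConfig:
    """Paths, preprocessing and model settings for a full run."""

    spectra_csv: str = ""
    image_dir: str = ""
    labels_csv: str = ""
    output_dir: str = "leafspec_out"
    preprocessing: str = "sg_smoothing"
    sg_window: int = 11
    sg_order: int = 3
    n_bands: int = 7
    min_separation: float = 30.0
    pls_components: int = 5
    test_fraction: float = 0.2
    split_seed: int = 0
    seg_channel: str = "gray"
    cnn: _cnn.CNNConfig = field(default_factory=_cnn.CNNConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cnn_cfg = _cnn.CNNConfig(**raw.pop("cnn", {}))
        return cls(cnn=cnn_cfg, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def sg_spec(self) -> SGFilterSpec:
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        return SGFilterSpec((self.sg_window - 1) // 2, self.sg_order)


def _load_labels(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"labels file not found: {path}")
    df = pd.read_csv(path)
    if not {"sample_id", "concentration"} <= set(df.columns):
        raise ValueError(f"{path}: need sample_id and concentration columns")
    return df


def _manifest(out: Path, stage: str, cfg: PipelineConfig, t0: float,
              extra: dict) -> None:
    payload = {"stage": stage, "elapsed_s": round(time.perf_counter() - t0, 3),
               "config": cfg.to_dict(), **extra}
    (out / f"{stage}_manifest.json").write_text(json.dumps(payload, indent=2))


def run_wavelength_stage(cfg: PipelineConfig) -> dict:
    """Preprocess spectra, screen characteristic bands, and write the
    preprocessing- and band-comparison tables plus a band JSON report."""
    t0 = time.perf_counter()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    spectra_path = Path(cfg.spectra_csv)
    if not spectra_path.exists():
        raise FileNotFoundError(f"spectra file not found: {spectra_path}")
    M, conc = SpectraMatrix.from_csv(spectra_path)
    if conc is None:
        conc = _load_labels(cfg.labels_csv)["concentration"].to_numpy(float)
    if np.ptp(conc) == 0:
        raise ValueError("labels are constant; selection impossible")

    sg = cfg.sg_spec()
    log.info("wavelength stage: %d spectra x %d bands", M.n_samples, M.n_wavelengths)

    pre_table = compare_preprocessing(M, conc, test_fraction=cfg.test_fraction,
                                      seed=cfg.split_seed, sg=sg,
                                      n_components=cfg.pls_components)
    pre_table.to_csv(out / "preprocessing_comparison.csv", index=False)

    Mp = apply_method(M, PreprocessMethod(cfg.preprocessing), sg)
    selector = CharacteristicBandSelector(
        wavelengths=M.wavelengths, n_bands=cfg.n_bands,
        min_separation=cfg.min_separation)
    selector.fit(Mp.values, conc)
    selection = selector.selection_

    band_table = compare_bands(Mp, conc, selection.wavelengths,
                               test_fraction=cfg.test_fraction,
                               seed=cfg.split_seed,
                               n_components=cfg.pls_components)
    band_table.to_csv(out / "band_comparison.csv", index=False)

    pd.DataFrame({"wavelength_nm": selector.curve_.wavelengths,
                  "r": selector.curve_.r,
                  "r_squared": selector.curve_.r_squared}
                 ).to_csv(out / "correlation_curve.csv", index=False)
    (out / "bands.json").write_text(json.dumps(selection.to_dict(), indent=2))

    _manifest(out, "wavelength", cfg, t0,
              {"n_samples": M.n_samples, "primary_band_nm": selection.primary})
    return {"selection": selection, "preprocessing_table": pre_table,
            "band_table": band_table}


def run_training_stage(cfg: PipelineConfig) -> dict:
    """Batch-segment the image directory, extract features, train the
    network, and write features, model, training log and metric report."""
    t0 = time.perf_counter()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    image_dir = Path(cfg.image_dir)
    if not image_dir.is_dir():
        raise FileNotFoundError(f"image directory not found: {image_dir}")
    labels = _load_labels(cfg.labels_csv).set_index("sample_id")

    features = extract_features_dir(image_dir, channel=cfg.seg_channel)
    if features.empty:
        raise RuntimeError("no image segmented successfully")
    for name in features.attrs.get("skipped", []):
        log.warning("skipped unsegmentable image %s", name)
    features.to_csv(out / "features.csv", index=False)

    matched = features[features["sample_id"].isin(labels.index)]
    if matched.empty:
        raise ValueError("no overlap between image names and label sample_ids")
    y = labels.loc[matched["sample_id"], "concentration"].to_numpy(float)
    X = matched.drop(columns="sample_id").to_numpy(float)

    model = _cnn.CNNFeatureRegressor(config=cfg.cnn).fit(X, y)
    model.save(out / "model.npz")

    tl = model.train_log_
    pd.DataFrame({"iteration": tl.iterations, "loss_mse": tl.loss,
                  "r2": tl.r2}).to_csv(out / "training_log.csv", index=False)
    reports = _metrics.report(
        y[model.train_idx_], model.predict(X[model.train_idx_]),
        y[model.test_idx_], model.predict(X[model.test_idx_]))
    _metrics.report_frame(reports).to_csv(out / "eval_report.csv", index=False)

    _manifest(out, "training", cfg, t0,
              {"n_images": int(len(features)),
               "n_skipped": len(features.attrs.get("skipped", [])),
               "final": tl.final})
    return {"model": model, "features": features, "reports": reports}


def run_predict(cfg: PipelineConfig, image_path) -> float | pd.DataFrame:
    """Predict mg/kg for one image, or one row per image for a directory."""
    model_path = Path(cfg.output_dir) / "model.npz"
    model = _cnn.CNNFeatureRegressor.load(model_path)

    image_path = Path(image_path)
    if image_path.is_dir():
        feats = extract_features_dir(image_path, channel=cfg.seg_channel)
        X = feats.drop(columns="sample_id").to_numpy(float)
        feats["predicted_mg_per_kg"] = model.predict(X)
        return feats[["sample_id", "predicted_mg_per_kg"]]
    from PIL import Image

    from .imaging import extract_features
    img = np.asarray(Image.open(image_path).convert("RGB"))
    fv = extract_features(img, channel=cfg.seg_channel)
    return float(model.predict(fv.to_array()[None, :])[0])
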