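"""End-to-end pipeline: config validation, stage orchestration, artifacts.

A single YAML config drives simulate -> preprocess -> features ->
train/cross-validate -> report.  Every artifact carries provenance (the
config hash and global seed), and rerunning an identical config
reproduces the deterministic artifacts bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import yaml

from .features import FeatureConfig, SubjectDataset
from .gabor import GaborConfig
from .losses import FusionConfig
from .network import LayerSpec, Model, ModelSpec, build_model, get_preset
from .preprocess import FilterConfig
from .synth import SyntheticCohortSpec, generate_cohort
from .traineval import TrainConfig, cross_validate, split_80_10_10, train

logger = logging.getLogger(__name__)

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "out_dir", "log_level", "simulate", "preprocess", "gabor",
         "model", "train", "evaluate"},
    "simulate": {"n_pd", "n_hc", "n_channels", "fs", "duration", "beta_ratio",
                 "noise_sd", "line_freq", "line_amp", "blink_rate",
                 "gain_spread", "write_files", "format"},
    "preprocess": {"band_low", "band_high", "notch_freq", "notch_q",
                   "window_len", "hop", "amp_thresh_sd", "use_ica"},
    "gabor": {"sigma_t", "fmin", "fmax", "df", "n_steps", "log_magnitude"},
    "model": {"preset", "units"},
    "train": {"learning_rate", "batch_size", "epochs", "dropout", "patience"},
    "evaluate": {"mode", "k", "level", "fusion_widths"},
}


class ConfigError(ValueError):
    """Raised when a pipeline config contains unknown or invalid keys."""


def validate_config(cfg: dict) -> dict:
    for key in cfg:
        if key not in _SCHEMA[""]:
            raise ConfigError(f"unknown config key {key!r}")
        if key in _SCHEMA and isinstance(cfg.get(key), dict):
            for sub in cfg[key]:
                if sub not in _SCHEMA[key]:
                    raise ConfigError(f"unknown config key {key}.{sub}")
    return cfg


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def demo_config() -> dict:
    """Tiny cohort (4+4 subjects, 30 s) that completes in minutes on one CPU."""
    return validate_config({
        "seed": 0,
        "simulate": {"n_pd": 4, "n_hc": 4, "n_channels": 8, "fs": 128.0,
                     "duration": 30.0, "beta_ratio": 3.0},
        "preprocess": {"band_low": 0.5, "band_high": 45.0, "notch_freq": 50.0,
                       "window_len": 256, "amp_thresh_sd": 5.0},
        "gabor": {"sigma_t": 0.1, "fmin": 4.0, "fmax": 40.0, "df": 4.0,
                  "n_steps": 32},
        "model": {"preset": "table3_bilstm", "units": 16},
        "train": {"epochs": 10, "batch_size": 64, "learning_rate": 0.001},
        "evaluate": {"mode": "crossval", "k": 4, "level": "subject"},
    })


def _cohort_spec_from(cfg: dict, seed: int) -> SyntheticCohortSpec:
    sim = dict(cfg.get("simulate", {}))
    beta_ratio = sim.pop("beta_ratio", 2.0)
    sim.pop("write_files", None)
    sim.pop("format", None)
    from .synth import default_band_powers_for

    fs = sim.get("fs", 512.0)
    control = default_band_powers_for(fs)
    spec = SyntheticCohortSpec(**sim, seed=seed,
                               band_powers={"control": control,
                                            "pd": dict(control)})
    return spec.with_beta_ratio(beta_ratio) if beta_ratio is not None else spec


def _feature_config_from(cfg: dict) -> FeatureConfig:
    pre = dict(cfg.get("preprocess", {}))
    gab = dict(cfg.get("gabor", {}))
    filter_cfg = FilterConfig(
        band_low=pre.get("band_low", 0.5), band_high=pre.get("band_high", 45.0),
        notch_freq=pre.get("notch_freq", 50.0), notch_q=pre.get("notch_q", 30.0))
    gabor_cfg = GaborConfig(
        sigma_t=gab.get("sigma_t", 0.1),
        freqs=np.arange(gab.get("fmin", 4.0), gab.get("fmax", 40.0) + 1e-9,
                        gab.get("df", 4.0)),
        n_steps=gab.get("n_steps", 32),
        log_magnitude=gab.get("log_magnitude", True))
    return FeatureConfig(filter_cfg=filter_cfg,
                         window_len=pre.get("window_len", 256),
                         hop=pre.get("hop"),
                         amp_thresh_sd=pre.get("amp_thresh_sd", 5.0),
                         gabor_cfg=gabor_cfg)


def run_pipeline(cfg: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline; writes artifacts and returns the report."""
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    validate_config(cfg)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", "pdeeg_run"))
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": config_hash(cfg), "seed": seed}
    logging.basicConfig(level=getattr(logging, cfg.get("log_level", "INFO")))

    logger.info("stage simulate: generating cohort")
    spec = _cohort_spec_from(cfg, seed)
    sim = cfg.get("simulate", {})
    records, manifest = generate_cohort(
        spec, out_dir=out / "cohort" if sim.get("write_files") else None,
        file_format=sim.get("format", "hdf5"))
    manifest.to_csv(out / "manifest.csv", index=False)

    logger.info("stage preprocess+gabor: extracting features")
    feat_cfg = _feature_config_from(cfg)
    dataset = SubjectDataset.from_records(records, feat_cfg)
    sample = dataset.features_for(dataset.subjects[0])
    _, steps, width = sample.shape

    model_cfg = cfg.get("model", {})
    preset = model_cfg.get("preset", "table3_bilstm")
    units = model_cfg.get("units", 16)

    def spec_builder() -> ModelSpec:
        return get_preset(preset, units=units, input_width=width, steps=steps)

    tr = cfg.get("train", {})
    train_cfg = TrainConfig(learning_rate=tr.get("learning_rate", 0.001),
                            batch_size=tr.get("batch_size", 64),
                            epochs=tr.get("epochs", 20),
                            dropout=tr.get("dropout", 0.4),
                            patience=tr.get("patience", 5), seed=seed)

    ev = cfg.get("evaluate", {})
    mode = ev.get("mode", "crossval")
    if mode == "crossval":
        logger.info("stage crossval: %d-fold %s-level", ev.get("k", 6),
                    ev.get("level", "subject"))
        report = cross_validate(
            dataset, spec_builder, train_cfg, k=ev.get("k", 6),
            level=ev.get("level", "subject"),
            fusion=FusionConfig(ev.get("fusion_widths", [1, 3, 5])))
    elif mode == "split":
        report = _split_evaluation(dataset, spec_builder, train_cfg, seed)
    else:
        raise ConfigError(f"unknown evaluate.mode {mode!r}")

    report["provenance"] = provenance
    (out / "metrics.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    logger.info("pipeline complete: %s", out / "metrics.json")
    return report


def _split_evaluation(dataset: SubjectDataset, spec_builder, train_cfg: TrainConfig,
                      seed: int) -> dict:
    """Single 80-10-10 subject split: train, early-stop on val, report test."""
    from .metrics import ConfusionMatrix, compute_metrics, roc_auc
    from .traineval import _fuse_subject, _gather, _standardize_fit

    tr_sids, val_sids, te_sids = split_80_10_10(dataset.subjects,
                                                dataset.labels, seed=seed)
    X_tr, y_tr = _gather(dataset, tr_sids)
    X_va, y_va = _gather(dataset, val_sids)
    mean, sd = _standardize_fit(X_tr)
    model = build_model(spec_builder(), seed=seed)
    model, history = train(model, ((X_tr - mean) / sd, y_tr),
                           ((X_va - mean) / sd, y_va), train_cfg)
    y_true, y_pred, scores = [], [], []
    for sid in te_sids:
        X_te = (dataset.features_for(sid) - mean) / sd
        seg_scores = model.predict_step_scores(X_te).mean(axis=1)
        fused = _fuse_subject(seg_scores, FusionConfig())
        scores.append(float(fused[1]))
        y_pred.append(int(fused[1] >= 0.5))
        y_true.append(dataset.label_for(sid))
    cm = ConfusionMatrix.from_predictions(np.array(y_true), np.array(y_pred))
    report = compute_metrics(cm).as_dict()
    try:
        auc, _, _ = roc_auc(np.array(scores), np.array(y_true))
        report["auc"] = auc
    except ValueError:
        pass
    report["history"] = history
    report["split"] = {"train": tr_sids, "val": val_sids, "test": te_sids}
    return report


# ---------------------------------------------------------------------------
# model persistence

def save_model(model: Model, path: str | Path) -> None:
    spec_json = json.dumps([asdict(l) for l in model.spec.layers])
    with h5py.File(path, "w") as f:
        f.attrs["spec"] = spec_json
        f.attrs["fingerprint"] = hashlib.sha256(spec_json.encode()).hexdigest()[:16]
        for i, w in enumerate(model.get_weights()):
            f.create_dataset(f"w_{i:03d}", data=w)


def load_model(path: str | Path) -> Model:
    with h5py.File(path, "r") as f:
        layers = [LayerSpec(**d) for d in json.loads(f.attrs["spec"])]
        model = build_model(ModelSpec(layers))
        weights = [f[k][()] for k in sorted(f.keys())]
    model.set_weights(weights)
    return model
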