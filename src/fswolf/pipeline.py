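"""End-to-end orchestration: preprocess -> features -> SCC filter ->
AGWO selection/tuning -> FS-ResNet train/eval, plus the four-arm
ablation (baseline, fuzzy-only, AGWO-only, full).

Every run is fully determined by its configuration and seed; artifacts
(metrics JSON, prediction CSV, history JSONL, reproducibility
manifest) contain no timestamps, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fswolf import __version__
from fswolf.agwo import (
    SearchSpace,
    agwo_minimize,
    decode_hyperparams,
    encode_hyperparams,
    select_features_agwo,
)
from fswolf.fsnet import (
    FSResNet,
    FuzzyScoringConfig,
    NetworkConfig,
    images_to_tensor,
    predict,
)
from fswolf.metrics import (
    SplitSpec,
    compare_models,
    confusion,
    metrics,
    roc_auc,
    split_dataset,
)
from fswolf.preprocess import (
    LabeledImageSet,
    correlation_redundancy_filter,
    load_labeled_images,
    reference_stats_from_images,
    standardize_image,
)
from fswolf.synthetic import SyntheticDatasetSpec, generate_dataset
from fswolf.wavelets import extract_features

__all__ = ["PipelineConfig", "run_pipeline", "run_ablation", "load_config"]


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults are the desk-scale study conditions."""

    # data source: a manifest CSV or the synthetic generator
    manifest: str | None = None
    n_per_class: int = 100
    side: int = 64
    separability: float = 1.0
    pixel_noise_sd: float = 0.02

    # preprocessing
    reinhard: bool = True
    wavelet: str = "haar"
    levels: int = 3
    scc_threshold: float = 0.95

    # AGWO feature selection on the wavelet table
    select_features: bool = True
    fs_wolves: int = 15
    fs_iters: int = 25

    # AGWO hyperparameter tuning for the CNN (optional); proxies run at
    # tune_epochs fidelity and the pack is warm-started with the incumbent
    tune_hyperparams: bool = False
    tune_wolves: int = 4
    tune_iters: int = 1
    tune_epochs: int = 5

    # network / training
    epochs: int = 25
    learning_rate: float = 1e-3
    batch_size: int = 16
    weight_decay: float = 1e-4
    fuzzy_enabled: bool = True
    tune_thresholds: bool = False
    restore_best: bool = False  # keep the best-validation-epoch parameters

    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config file; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _load_data(config: PipelineConfig) -> LabeledImageSet:
    if config.manifest is not None:
        return load_labeled_images(config.manifest)
    return generate_dataset(
        SyntheticDatasetSpec(
            n_per_class=config.n_per_class,
            side=config.side,
            separability=config.separability,
            pixel_noise_sd=config.pixel_noise_sd,
            seed=config.seed,
        )
    )


def _standardize_split(
    train: LabeledImageSet,
    val: LabeledImageSet,
    test: LabeledImageSet,
    config: PipelineConfig,
):
    ref = reference_stats_from_images(train.images) if config.reinhard else None
    out = []
    for subset in (train, val, test):
        std = [
            standardize_image(im, ref=ref, side=config.side) for im in subset.images
        ]
        out.append(LabeledImageSet(ids=subset.ids, images=std, labels=subset.labels))
    return out


def _write_json(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")


def _network_config(config: PipelineConfig) -> NetworkConfig:
    return NetworkConfig(
        input_side=config.side,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        weight_decay=config.weight_decay,
        epochs=config.epochs,
        seed=config.seed,
        restore_best=config.restore_best,
    )


def _tune_hyperparams(
    config: PipelineConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
) -> tuple[float, int, float]:
    """Bi-objective AGWO over (lr, batch, weight decay) decoded from [0,1]^3.

    Objectives: validation error rate and validation cross-entropy of a
    short proxy training run. The pack is warm-started with the
    incumbent configuration, so the tuner never regresses below the
    defaults as judged on validation. The lowest-error archive member
    wins (ties: lowest loss).
    """

    def objectives(position):
        lr, batch, wd = decode_hyperparams(position)
        cfg = _network_config(config)
        cfg.learning_rate, cfg.batch_size, cfg.weight_decay = lr, batch, wd
        cfg.epochs = config.tune_epochs
        model = FSResNet(cfg)
        model.fuzzy_enabled = config.fuzzy_enabled
        model.fit(X_train, y_train)
        rec = model._monitor(X_val, y_val, "val")
        return (1.0 - rec["val_accuracy"], rec["val_loss"])

    incumbent = encode_hyperparams(
        config.learning_rate, config.batch_size, config.weight_decay
    )
    archive, _ = agwo_minimize(
        objectives,
        SearchSpace.unit(3),
        n_wolves=config.tune_wolves,
        T=config.tune_iters,
        seed=config.seed,
        init_positions=incumbent[None, :],
    )
    best = min(archive.members, key=lambda w: w.fitness)
    return decode_hyperparams(best.position)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full method and return the evaluation report.

    Stages: load/generate -> split 60/20/20 -> standardize -> wavelet
    features -> correlation redundancy filter -> AGWO feature selection
    -> optional AGWO hyperparameter tuning -> FS-ResNet training ->
    test-set evaluation.
    """
    data = _load_data(config)
    train, val, test = split_dataset(data, SplitSpec(seed=config.seed))
    train, val, test = _standardize_split(train, val, test, config)

    report: dict = {"config_hash": config.hash(), "version": __version__}

    # texture feature table + redundancy filter (fit on the train rows only)
    F_train, y_train, names = extract_features(train, config.wavelet, config.levels)
    F_val, y_val, _ = extract_features(val, config.wavelet, config.levels)
    F_test, y_test, _ = extract_features(test, config.wavelet, config.levels)
    kept = correlation_redundancy_filter(F_train, config.scc_threshold)
    report["scc_kept_columns"] = kept
    kept_names = [names[j] for j in kept]

    selection = None
    if config.select_features:
        mask, archive, _ = select_features_agwo(
            F_train[:, kept],
            y_train,
            n_wolves=config.fs_wolves,
            T=config.fs_iters,
            seed=config.seed,
        )
        selection = {
            "selected_features": [kept_names[j] for j in np.where(mask)[0]],
            "n_selected": int(mask.sum()),
            "archive_size": len(archive.members),
        }
        report["feature_selection"] = selection

    X_train = images_to_tensor(train.images)
    X_val = images_to_tensor(val.images)
    X_test = images_to_tensor(test.images)

    if config.tune_hyperparams:
        lr, batch, wd = _tune_hyperparams(
            config, X_train, y_train, X_val, np.asarray(val.labels)
        )
        report["tuned_hyperparams"] = {
            "learning_rate": lr,
            "batch_size": batch,
            "weight_decay": wd,
        }
        config = dataclasses.replace(
            config, learning_rate=lr, batch_size=batch, weight_decay=wd
        )

    net_cfg = _network_config(config)
    model = FSResNet(net_cfg, FuzzyScoringConfig(m=2))
    model.fuzzy_enabled = config.fuzzy_enabled
    history = model.fit(X_train, train.labels, X_val, val.labels)
    if config.tune_thresholds:
        model.tune_head(X_val, val.labels)

    preds = predict(model, X_test, ids=test.ids)
    counts = confusion(test.labels, preds["label"].to_numpy())
    rep = metrics(counts)
    auc = roc_auc(preds["P_malignant"].to_numpy(), test.labels)
    report["test"] = {
        "accuracy": rep.accuracy,
        "precision": rep.precision,
        "recall": rep.recall,
        "f1": rep.f1,
        "roc_auc": auc,
        "confusion": dataclasses.asdict(counts),
        "n_test": len(test),
    }
    report["history"] = history
    report["test_ids"] = list(test.ids)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_json(out_dir / "metrics.json", report["test"])
        preds.to_csv(out_dir / "predictions.csv", index=False)
        with open(out_dir / "history.jsonl", "w") as fh:
            for rec in history:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
        manifest = {
            "config": config.to_dict(),
            "config_hash": config.hash(),
            "seed": config.seed,
            "version": __version__,
        }
        if selection is not None:
            manifest["feature_selection"] = selection
        _write_json(out_dir / "manifest.json", manifest)
    return report


#: per-arm switches; every other setting is shared with the baseline
ABLATION_ARMS = {
    "baseline": {
        "fuzzy_enabled": False,
        "tune_hyperparams": False,
        "select_features": False,
    },
    "fuzzy_only": {
        "fuzzy_enabled": True,
        "tune_hyperparams": False,
        "select_features": False,
    },
    "agwo_only": {
        "fuzzy_enabled": False,
        "tune_hyperparams": True,
        "select_features": True,
    },
    "full": {
        "fuzzy_enabled": True,
        "tune_hyperparams": True,
        "select_features": True,
    },
}


def tune_hyperparams_for_config(config: PipelineConfig) -> tuple[float, int, float]:
    """Run only the AGWO hyperparameter-tuning stage for a configuration."""
    data = _load_data(config)
    train, val, test = split_dataset(data, SplitSpec(seed=config.seed))
    train, val, _ = _standardize_split(train, val, test, config)
    return _tune_hyperparams(
        config,
        images_to_tensor(train.images),
        np.asarray(train.labels),
        images_to_tensor(val.images),
        np.asarray(val.labels),
    )


def run_ablation(
    config: PipelineConfig,
    n_repeats: int = 5,
    out_dir: str | Path | None = None,
) -> dict:
    """Four-arm ablation on shared splits and seeds.

    Each repeat r uses seed config.seed + r for data, split and
    training; all four arms see identical splits within a repeat, and
    the two AGWO arms share one hyperparameter-tuning run (proxies
    ranked with the crisp head, so tuning selects general optimization
    hyperparameters rather than head-specific ones). The report carries
    per-arm accuracy vectors across repeats and the normality-gated
    significance test of each arm against the baseline.
    """
    accuracies: dict[str, list[float]] = {arm: [] for arm in ABLATION_ARMS}
    tuned_per_repeat: list[dict] = []
    for r in range(n_repeats):
        seed = config.seed + r
        tuned: tuple[float, int, float] | None = None
        if any(sw["tune_hyperparams"] for sw in ABLATION_ARMS.values()):
            tuned = tune_hyperparams_for_config(
                dataclasses.replace(
                    config, seed=seed, fuzzy_enabled=False, select_features=False
                )
            )
            tuned_per_repeat.append(
                {"learning_rate": tuned[0], "batch_size": tuned[1], "weight_decay": tuned[2]}
            )
        repeat_ids: list[str] | None = None
        for arm, switches in ABLATION_ARMS.items():
            arm_cfg = dataclasses.replace(config, seed=seed, **switches)
            if switches["tune_hyperparams"] and tuned is not None:
                arm_cfg = dataclasses.replace(
                    arm_cfg,
                    tune_hyperparams=False,
                    learning_rate=tuned[0],
                    batch_size=tuned[1],
                    weight_decay=tuned[2],
                )
            rep = run_pipeline(arm_cfg)
            accuracies[arm].append(rep["test"]["accuracy"])
            if repeat_ids is None:
                repeat_ids = rep["test_ids"]
            elif rep["test_ids"] != repeat_ids:
                raise RuntimeError("ablation arms evaluated on misaligned test sets")
    out: dict = {"arms": {}, "n_repeats": n_repeats}
    if tuned_per_repeat:
        out["tuned_hyperparams_per_repeat"] = tuned_per_repeat
    for arm in ABLATION_ARMS:
        entry: dict = {
            "accuracies": accuracies[arm],
            "mean_accuracy": float(np.mean(accuracies[arm])),
            "switches": ABLATION_ARMS[arm],
        }
        if arm != "baseline" and n_repeats >= 5:
            sig = compare_models(accuracies[arm], accuracies["baseline"])
            entry["vs_baseline"] = {
                "shapiro_p": sig.shapiro_p,
                "test": sig.test_name,
                "statistic": sig.statistic,
                "p_value": sig.p_value,
                "mean_difference": sig.mean_difference,
                "ci": [sig.ci_low, sig.ci_high],
            }
        out["arms"][arm] = entry
    if out_dir is not None:
        _write_json(Path(out_dir) / "ablation.json", out)
    return out
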