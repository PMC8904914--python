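"""End-to-end experiment orchestration.

``run_experiment`` executes the four pipeline stages in order — corpus
(simulated or loaded), median-filter preprocessing, feature extraction
with AWGN augmentation, FASSO-trained maxout classification — under one
of two evaluation protocols (stratified percentage split or stratified
K-fold), writes every artifact to the output directory, and returns a
report.  A single master seed fans out to fixed per-stage sub-seeds so
that, e.g., toggling augmentation does not perturb the optimizer's random
stream.
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
from sklearn.preprocessing import StandardScaler

from .augmentation import AugmentConfig, augment_dataset
from .classifier import MaxoutFassoClassifier
from .data import SignalDataset, read_dataset
from .evaluation import evaluate_predictions, kfold, split_train_percentage
from .exceptions import ConfigurationError
from .features import FeatureLayout, FeatureMatrix
from .maxout import Architecture
from .preprocessing import median_filter
from .synthetic import SynthConfig, generate_corpus

# Fixed per-stage seed offsets (master seed + offset, kept well below 2**31).
_SEED_OFFSETS = {"synth": 0, "augment": 1009, "split": 2003, "optimizer": 3001}


@dataclass
class ExperimentConfig:
    """Nested configuration for one full run; loadable from YAML."""

    seed: int = 0
    output_dir: str = "eegmotion_run"
    input_manifest: str | None = None  # if set, load instead of simulating
    synth: dict = field(default_factory=dict)
    preprocessing: dict = field(default_factory=lambda: {"window": 3, "edge_mode": "replicate"})
    features: dict = field(default_factory=dict)
    augmentation: dict = field(default_factory=lambda: {"snr_db": 20.0, "copies": 1})
    # Experiment profile: a single maxout layer keeps the searched parameter
    # count in the low thousands (the metaheuristic's effective regime), and
    # a small committee of restarts averages out run-to-run search noise.
    network: dict = field(
        default_factory=lambda: {"hidden": [], "pieces": 2, "restarts": 3}
    )
    optimizer: dict = field(default_factory=lambda: {"max_iter": 1000})
    protocol: str = "train_pct"
    train_pct: float = 70.0
    k_folds: int = 5
    standardize: bool = True

    def __post_init__(self):
        if self.protocol not in ("train_pct", "kfold"):
            raise ConfigurationError(
                f"protocol must be 'train_pct' or 'kfold', got {self.protocol!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) + _SEED_OFFSETS[stage]


@dataclass
class ExperimentReport:
    """Outcome of one run: headline macro metrics plus provenance."""

    config_hash: str
    seed: int
    protocol: str
    metrics: dict
    per_fold: list[dict] = field(default_factory=list)
    artifacts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _feature_layout(cfg: ExperimentConfig) -> FeatureLayout:
    kwargs = dict(cfg.features)
    if "logbp_bands" in kwargs:
        kwargs["logbp_bands"] = tuple(tuple(b) for b in kwargs["logbp_bands"])
    if "relative_band" in kwargs:
        kwargs["relative_band"] = tuple(kwargs["relative_band"])
    return FeatureLayout(**kwargs)


def build_feature_matrix(cfg: ExperimentConfig) -> FeatureMatrix:
    """Stages 1-3: corpus, median filtering, feature extraction + augmentation."""
    if cfg.input_manifest:
        dataset = read_dataset(cfg.input_manifest)
    else:
        dataset = generate_corpus(SynthConfig(seed=cfg.stage_seed("synth"), **cfg.synth))
    window = int(cfg.preprocessing.get("window", 3))
    edge_mode = cfg.preprocessing.get("edge_mode", "replicate")
    filtered = SignalDataset(
        recordings=[median_filter(r, window, edge_mode) for r in dataset],
        vocabulary=dataset.vocabulary,
    )
    aug = AugmentConfig(
        snr_db=float(cfg.augmentation.get("snr_db", 20.0)),
        copies=int(cfg.augmentation.get("copies", 1)),
        seed=cfg.stage_seed("augment"),
    )
    return augment_dataset(filtered, _feature_layout(cfg), aug)


def _make_classifier(cfg: ExperimentConfig) -> MaxoutFassoClassifier:
    return MaxoutFassoClassifier(
        hidden_layer_sizes=tuple(cfg.network.get("hidden", ())),
        pieces=int(cfg.network.get("pieces", 2)),
        n_restarts=int(cfg.network.get("restarts", 1)),
        random_state=cfg.stage_seed("optimizer"),
        **cfg.optimizer,
    )


def _fit_and_score(
    fm: FeatureMatrix,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    cfg: ExperimentConfig,
):
    scaler = StandardScaler() if cfg.standardize else None
    X_train, X_test = fm.X[train_idx], fm.X[test_idx]
    if scaler is not None:
        X_train = scaler.fit_transform(X_train)
        X_test = scaler.transform(X_test)
    clf = _make_classifier(cfg)
    clf.fit(X_train, fm.labels[train_idx])
    y_pred = clf.predict(X_test)
    n_classes = len(fm.label_names) or int(fm.labels.max()) + 1
    report = evaluate_predictions(fm.labels[test_idx], y_pred, n_classes)
    return clf, scaler, report


def save_feature_csv(fm: FeatureMatrix, path: str | Path) -> None:
    df = pd.DataFrame(fm.X, columns=fm.column_names())
    df["label"] = fm.labels
    df["group"] = fm.groups
    df.to_csv(path, index=False)


def load_feature_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (X, labels, groups) from a feature CSV written by this package."""
    df = pd.read_csv(path)
    labels = df.pop("label").to_numpy(dtype=int)
    groups = df.pop("group").to_numpy(dtype=int) if "group" in df else np.arange(len(df))
    return df.to_numpy(dtype=float), labels, groups


def save_model_bundle(path, clf: MaxoutFassoClassifier, scaler, label_names) -> None:
    arch: Architecture = clf.architecture_
    payload = {
        "architecture": {
            "input_dim": arch.input_dim,
            "n_classes": arch.n_classes,
            "hidden": list(arch.hidden),
            "pieces": arch.pieces,
        },
        "thetas": [t.tolist() for t in clf.thetas_],
        "input_scale": clf.input_scale_,
        "classes": clf.classes_.tolist(),
        "label_names": list(label_names),
        "scaler": None
        if scaler is None
        else {"mean": scaler.mean_.tolist(), "scale": scaler.scale_.tolist()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model_bundle(path):
    from .maxout import unflatten_params

    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    a = payload["architecture"]
    arch = Architecture(
        input_dim=a["input_dim"],
        n_classes=a["n_classes"],
        hidden=tuple(a["hidden"]),
        pieces=a["pieces"],
    )
    params = [unflatten_params(np.asarray(t), arch) for t in payload["thetas"]]
    return params, payload


def run_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """Execute the full pipeline under ``cfg`` and persist all artifacts."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fm = build_feature_matrix(cfg)

    artifacts = {"features": str(out / "features.csv")}
    save_feature_csv(fm, out / "features.csv")
    layout_meta = {
        "layout": dataclasses.asdict(fm.layout),
        "label_names": list(fm.label_names),
        "blocks": {k: [s.start, s.stop] for k, s in fm.spans.items()},
    }
    with open(out / "layout.json", "w", encoding="utf-8") as fh:
        json.dump(layout_meta, fh, indent=1)
    artifacts["layout"] = str(out / "layout.json")

    per_fold = []
    if cfg.protocol == "train_pct":
        train_idx, test_idx = split_train_percentage(
            fm.labels, cfg.train_pct, seed=cfg.stage_seed("split"), groups=fm.groups
        )
        clf, scaler, report = _fit_and_score(fm, train_idx, test_idx, cfg)
        headline = report.to_dict()
        per_fold.append(headline)
        _save_trace(clf, out / "trace.csv")
        save_model_bundle(out / "model.json", clf, scaler, fm.label_names)
        artifacts.update(model=str(out / "model.json"), trace=str(out / "trace.csv"))
    else:
        folds = kfold(
            fm.labels, cfg.k_folds, seed=cfg.stage_seed("split"), groups=fm.groups
        )
        reports = []
        for f, (train_idx, test_idx) in enumerate(folds):
            clf, scaler, report = _fit_and_score(fm, train_idx, test_idx, cfg)
            reports.append(report)
            per_fold.append(report.to_dict())
        _save_trace(clf, out / "trace.csv")
        save_model_bundle(out / "model.json", clf, scaler, fm.label_names)
        artifacts.update(model=str(out / "model.json"), trace=str(out / "trace.csv"))
        headline = {
            "macro": {
                m: float(np.mean([getattr(r, m) for r in reports]))
                for m in ("accuracy", "sensitivity", "specificity")
            },
            "micro_accuracy": float(np.mean([r.micro_accuracy for r in reports])),
            "n_folds": len(reports),
        }

    result = ExperimentReport(
        config_hash=cfg.config_hash(),
        seed=cfg.seed,
        protocol=cfg.protocol,
        metrics=headline,
        per_fold=per_fold,
        artifacts=artifacts,
    )
    with open(out / "metrics.json", "w", encoding="utf-8") as fh:
        json.dump(result.to_dict(), fh, indent=1)
    with open(out / "config.json", "w", encoding="utf-8") as fh:
        json.dump({"hash": cfg.config_hash(), "config": cfg.to_dict()}, fh, indent=1)
    return result


def _save_trace(clf: MaxoutFassoClassifier, path) -> None:
    pd.DataFrame(clf.trace_.to_dict()).to_csv(path, index=False)
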