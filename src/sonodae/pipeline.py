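"""Two-arm experiment driver.

Runs the original-vs-corrected comparison: build (or load) a labelled
ROI dataset, train one SDAE-LR classifier on the raw images and one on
the bias-corrected images — with the SAME split and the SAME training
seed, so the only difference between the arms is the correction — and
report confusion counts and derived metrics per arm.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inhomogeneity import correct_image
from .metrics import confusion, metric_suite, rounded_suite, ConfusionCounts
from .sdae import SDAEClassifier, TrainConfig, train_classifier
from .synthdata import DatasetSplit, make_dataset

logger = logging.getLogger(__name__)

METRICS_SCHEMA_VERSION = 1


@dataclass
class CorrectionConfig:
    enabled: bool = True
    degree: int = 2
    cell_size: int = 4
    max_outer_iter: int = 10
    tol: float = 1e-4


@dataclass
class SyntheticConfig:
    n_benign: int = 74
    n_malignant: int = 96
    test_fraction: float = 27.0 / 170.0
    bias_strength: float = 0.15
    size: int = 28
    speckle_sigma: float = 0.05


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a two-arm run byte-for-byte."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    correction: CorrectionConfig = field(default_factory=CorrectionConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    split_seed: int = 0
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["train"] = self.train.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "synthetic" in d:
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        if "correction" in d:
            d["correction"] = CorrectionConfig(**d["correction"])
        if "train" in d:
            d["train"] = TrainConfig(**d["train"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class ArmResult:
    arm: str
    counts: ConfusionCounts
    metrics: dict[str, float]
    metrics_rounded: dict[str, float]
    train_accuracy: float
    probabilities: np.ndarray
    predictions: np.ndarray
    traces: dict
    weight_checksum: str
    model: SDAEClassifier


@dataclass
class ExperimentReport:
    arms: dict[str, ArmResult]
    config: ExperimentConfig
    n_train: int
    n_test: int

    def metrics_payload(self) -> dict:
        """Deterministic JSON-able summary (no timestamps)."""
        cfg = self.config.to_dict()
        cfg.pop("output_dir", None)  # location must not affect the payload bytes
        return {
            "schema_version": METRICS_SCHEMA_VERSION,
            "config": cfg,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "arms": {
                name: {
                    "counts": asdict(arm.counts),
                    "metrics": arm.metrics,
                    "metrics_rounded": arm.metrics_rounded,
                    "train_accuracy": arm.train_accuracy,
                    "weight_checksum": arm.weight_checksum,
                }
                for name, arm in sorted(self.arms.items())
            },
        }


def _checksum(model: SDAEClassifier) -> str:
    h = hashlib.sha256()
    for layer in model.layers:
        h.update(layer.W.tobytes())
        h.update(layer.b.tobytes())
    h.update(np.asarray(model.V).tobytes())
    h.update(np.float64(model.c).tobytes())
    return h.hexdigest()[:16]


def correct_batch(images: list[np.ndarray], cfg: CorrectionConfig) -> list[np.ndarray]:
    out = []
    for img in images:
        res = correct_image(
            img,
            degree=cfg.degree,
            cell_size=cfg.cell_size,
            max_outer_iter=cfg.max_outer_iter,
            tol=cfg.tol,
        )
        out.append(res.corrected)
    return out


def _run_arm(name: str, X_train, y_train, X_test, y_test, train_cfg: TrainConfig) -> ArmResult:
    logger.info("arm %s: training SDAE on %d samples", name, X_train.shape[0])
    model, traces = train_classifier(X_train, y_train, train_cfg)
    prob_train, pred_train = model.predict(X_train)
    prob_test, pred_test = model.predict(X_test)
    counts = confusion(y_test, pred_test)
    res = ArmResult(
        arm=name,
        counts=counts,
        metrics=metric_suite(counts),
        metrics_rounded=rounded_suite(counts),
        train_accuracy=float((pred_train == y_train).mean()),
        probabilities=prob_test,
        predictions=pred_test,
        traces=traces,
        weight_checksum=_checksum(model),
        model=model,
    )
    logger.info(
        "arm %s: test accuracy %.3f (train %.3f), checksum %s",
        name, res.metrics["accuracy"], res.train_accuracy, res.weight_checksum,
    )
    return res


def run_experiment(config: ExperimentConfig, split: DatasetSplit | None = None) -> ExperimentReport:
    """Execute the original and corrected arms and (optionally) write
    metrics.json, per-arm predictions and a text summary to output_dir."""
    if split is None:
        s = config.synthetic
        split = make_dataset(
            n_benign=s.n_benign,
            n_malignant=s.n_malignant,
            test_fraction=s.test_fraction,
            seed=config.split_seed,
            bias_strength=s.bias_strength,
            size=s.size,
            speckle_sigma=s.speckle_sigma,
        )

    X_train, y_train = split.arrays("train")
    X_test, y_test = split.arrays("test")

    arms: dict[str, ArmResult] = {}
    arms["original"] = _run_arm("original", X_train, y_train, X_test, y_test, config.train)

    if config.correction.enabled:
        logger.info("correcting %d images", len(split.train) + len(split.test))
        corr_train = correct_batch([s.image for s in split.train], config.correction)
        corr_test = correct_batch([s.image for s in split.test], config.correction)
        Xc_train = np.stack([im.ravel() for im in corr_train])
        Xc_test = np.stack([im.ravel() for im in corr_test])
        arms["corrected"] = _run_arm(
            "corrected", Xc_train, y_train, Xc_test, y_test, config.train
        )

    report = ExperimentReport(
        arms=arms, config=config, n_train=len(split.train), n_test=len(split.test)
    )

    if config.output_dir is not None:
        _write_outputs(report, split, Path(config.output_dir))
    return report


def _write_outputs(report: ExperimentReport, split: DatasetSplit, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "metrics.json", "w") as fh:
        json.dump(report.metrics_payload(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(report.config.to_dict(), fh, sort_keys=True)
    rows = []
    names = [s.name for s in split.test]
    truth = [s.label for s in split.test]
    for arm_name, arm in sorted(report.arms.items()):
        for fname, prob, pred, t in zip(names, arm.probabilities, arm.predictions, truth):
            rows.append(
                {"filename": fname, "prob": float(prob), "pred_label": int(pred),
                 "true_label": int(t), "arm": arm_name}
            )
    pd.DataFrame(rows).to_csv(out / "predictions.csv", index=False)
    with open(out / "summary.txt", "w") as fh:
        fh.write(format_summary(report))


def format_summary(report: ExperimentReport) -> str:
    lines = [
        f"Two-arm experiment: {report.n_train} train / {report.n_test} test images",
        "",
        f"{'metric':<12}" + "".join(f"{name:>12}" for name in sorted(report.arms)),
    ]
    for m in ("precision", "recall", "specificity", "accuracy", "f_measure"):
        lines.append(
            f"{m:<12}"
            + "".join(f"{report.arms[n].metrics[m]:>12.3f}" for n in sorted(report.arms))
        )
    lines.append("")
    for name in sorted(report.arms):
        c = report.arms[name].counts
        lines.append(
            f"{name}: TP={c.TP} TN={c.TN} FP={c.FP} FN={c.FN} "
            f"(train acc {report.arms[name].train_accuracy:.3f}, "
            f"weights {report.arms[name].weight_checksum})"
        )
    return "\n".join(lines) + "\n"
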