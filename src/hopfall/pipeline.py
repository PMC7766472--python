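"""End-to-end fall-detection pipeline and its configuration.

The pipeline chains the whole method: generate (or load) recordings ->
fuse and binarize -> extract the 5x5 fall template from ONE fall sample ->
Hebbian training -> associative recall of every test sample's template
through the network (ideal digital dynamics or the behavioral analog
circuit) -> cosine-threshold fall decision -> confusion counts and
accuracy.  One training sample suffices because Hebbian storage is
one-shot; the training recording is held out of the evaluation set.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as hio
from .analog import CircuitConfig, map_weights_to_circuit, simulate_circuit
from .classify import (
    DEFAULT_DECISION_THRESHOLD,
    FALL_LABEL,
    EvaluationReport,
    classify_sample,
    evaluate,
)
from .features import DEFAULT_THRESHOLDS, PatternTemplate, binarize, extract_template, fuse_axes
from .hopfield import recall, train_hebb
from .imu_synth import SynthConfig, generate_dataset

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "recall_template"]

log = logging.getLogger("hopfall")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one end-to-end run."""

    seed: int = 42
    n_per_class: int = 10
    sample_rate: float = 50.0
    duration: float = 6.0
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    pairing_mode: str = "per-feature"     # or "thermometer"
    flip_template: bool = False
    eta: float = 1.0
    backend: str = "digital"              # or "analog"
    recall_mode: str = "async"            # digital backend update order
    max_sweeps: int = 100
    gain: float = 10.0                    # analog backend
    tau: float = 1.0
    noise_sd: float = 0.0
    decision_threshold: float = DEFAULT_DECISION_THRESHOLD
    output_dir: str | None = None

    def synth_config(self) -> SynthConfig:
        return SynthConfig(
            sample_rate=self.sample_rate,
            duration=self.duration,
            n_per_class=self.n_per_class,
            seed=self.seed,
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        doc = asdict(self)
        doc["thresholds"] = list(self.thresholds)
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        if "thresholds" in doc:
            doc["thresholds"] = tuple(doc["thresholds"])
        return cls(**doc)

    def config_hash(self) -> str:
        doc = asdict(self)
        doc["thresholds"] = list(self.thresholds)
        doc.pop("output_dir")  # artifact location does not affect the result
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:12]


@dataclass(frozen=True)
class PipelineResult:
    report: EvaluationReport
    decisions: list[tuple[str, bool, float]]   # (true label, fall decision, confidence)
    fall_template: PatternTemplate
    config: PipelineConfig


def recall_template(template: PatternTemplate, weights, config: PipelineConfig, seed: int):
    """Relax one extracted template through the configured backend."""
    if config.backend == "digital":
        result = recall(
            weights,
            template.vector.astype(float),
            mode=config.recall_mode,
            max_sweeps=config.max_sweeps,
            seed=seed,
        )
        return result.v
    if config.backend == "analog":
        circuit = map_weights_to_circuit(weights)
        analog_cfg = CircuitConfig(gain=config.gain, tau=config.tau, noise_sd=config.noise_sd)
        result = simulate_circuit(circuit, analog_cfg, template.vector.astype(float), seed=seed)
        return result.readout
    raise ValueError(f"unknown backend {config.backend!r}; use 'digital' or 'analog'")


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Run synthesis -> extraction -> training -> recall -> evaluation.

    Identical config (including seed) always yields an identical report.
    """
    config = config or PipelineConfig()
    log.info("pipeline start: seed=%d config_hash=%s", config.seed, config.config_hash())

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    recordings = stage("synth", generate_dataset, config.synth_config())

    def extract(rec):
        feat = fuse_axes(rec)
        bin_matrix = binarize(feat, config.thresholds, mode=config.pairing_mode)
        return extract_template(bin_matrix, class_label=rec.label, flip=config.flip_template)

    # One fall sample generates the standard pattern; hold it out of the test set.
    train_rec = next(r for r in recordings if r.label == FALL_LABEL)
    fall_template = stage("extract-train", extract, train_rec)
    weights = stage("train", train_hebb, fall_template, config.eta)
    log.info("trained on %s recording seed=%d (held out)", train_rec.label, train_rec.seed)

    decisions: list[tuple[str, bool, float]] = []
    test_recs = [r for r in recordings if r is not train_rec]
    for i, rec in enumerate(test_recs):
        template = stage("extract", extract, rec)
        recalled = stage("recall", recall_template, template, weights, config, config.seed + 7919 + i)
        cls = stage(
            "classify",
            classify_sample,
            recalled,
            {FALL_LABEL: fall_template},
            threshold=config.decision_threshold,
        )
        decisions.append((rec.label, cls.is_fall, cls.confidence))

    report = stage("evaluate", evaluate, [(lbl, pos) for lbl, pos, _ in decisions])
    log.info(
        "evaluated %d samples: TP=%d FP=%d TN=%d FN=%d accuracy=%.4f",
        report.total, report.tp, report.fp, report.tn, report.fn, report.accuracy,
    )

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        hio.write_template_json(fall_template, out / "fall_template.json")
        hio.write_weights_json(weights, out / "weights.json")
        report_doc = {
            "tp": report.tp, "fp": report.fp, "tn": report.tn, "fn": report.fn,
            "accuracy": report.accuracy,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "decisions": [
                {"label": lbl, "fall": pos, "confidence": conf}
                for lbl, pos, conf in decisions
            ],
        }
        (out / "report.json").write_text(json.dumps(report_doc, indent=2) + "\n")

    return PipelineResult(
        report=report, decisions=decisions, fall_template=fall_template, config=config
    )
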