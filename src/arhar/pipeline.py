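"""End-to-end train / evaluate / classify orchestration.

Training runs the full chain on a labeled corpus of recordings:

    remove_gravity -> smooth -> segment -> extract_features (AR coefficients)
    -> z-score standardization -> fit_kda -> project -> train_ann

and returns a serializable :class:`PipelineBundle`. Evaluation classifies
every window of a labeled corpus and reports a row-normalized confusion
matrix whose mean accuracy is the unweighted mean of per-class recall (the
diagonal), the convention under which a printed per-class diagonal
reproduces its printed mean. Subject-independent evaluation — the honest
protocol for activity recognition — refuses any overlap between training
and evaluation subjects.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import yaml

from . import ann as ann_mod
from . import kda as kda_mod
from .ar_model import extract_features
from .exceptions import DataError, FormatError, ParameterError, ProtocolError
from .kda import KDAModel
from .signal_io import AccelerometerRecording, remove_gravity, segment, smooth

_FORMAT_VERSION = 1


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the deployment defaults."""

    gravity_alpha: float = 0.8
    smooth_order: int = 3
    window_seconds: float = 3.0
    overlap_fraction: float = 0.0
    ar_order: int = 10
    use_kda: bool = True
    kda_gamma: float | None = None
    kda_components: int | None = None
    kda_eps: float | None = None
    hidden_size: int = 3
    learning_rate: float = 0.1
    epochs: int = 500
    batch_size: int = 32
    momentum: float = 0.9
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise FormatError(f"config file {path} must hold a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=False)


@dataclass
class ConfusionMatrix:
    """Row-normalized confusion matrix in the per-class-recall convention."""

    classes: list[str]
    counts: np.ndarray  # (C, C) ints, rows = true class

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise ParameterError(
                f"counts must be ({c}, {c}), got {self.counts.shape}"
            )

    @property
    def row_percent(self) -> np.ndarray:
        """Each non-empty row as percentages summing to 100."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = 100.0 * self.counts / totals
        out[totals[:, 0] == 0] = np.nan
        return out

    @property
    def per_class_accuracy(self) -> np.ndarray:
        return np.diag(self.row_percent)

    @property
    def mean_accuracy(self) -> float:
        """Unweighted mean of per-class recall, ignoring empty rows."""
        diag = self.per_class_accuracy
        return float(np.nanmean(diag))

    @property
    def n_windows(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_labels(
        cls, classes: Sequence[str], true_labels, predicted_labels
    ) -> "ConfusionMatrix":
        index = {name: i for i, name in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(true_labels, predicted_labels, strict=True):
            counts[index[str(t)], index[str(p)]] += 1
        return cls(classes=list(classes), counts=counts)

    def to_table(self) -> str:
        """Tab-separated table: header, one percentage row per class, Mean row."""
        lines = ["Activity\t" + "\t".join(self.classes)]
        rp = self.row_percent
        for i, name in enumerate(self.classes):
            cells = "\t".join(
                "-" if np.isnan(v) else f"{v:.1f}" for v in rp[i]
            )
            lines.append(f"{name}\t{cells}")
        lines.append(f"Mean\t{self.mean_accuracy:.1f}")
        return "\n".join(lines)


@dataclass
class PipelineBundle:
    """Everything needed to classify a raw recording, serializable to JSON."""

    config: PipelineConfig
    class_names: list[str]
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    kda: KDAModel | None
    ann: ann_mod.ANNModel
    #: z-score statistics of the classifier inputs (KDA projections differ
    #: by orders of magnitude across components)
    input_mean: np.ndarray | None = None
    input_scale: np.ndarray | None = None
    training_subjects: list[str] = field(default_factory=list)
    format_version: int = _FORMAT_VERSION


def _recording_features(rec: AccelerometerRecording, config: PipelineConfig):
    cleaned = smooth(remove_gravity(rec, config.gravity_alpha), config.smooth_order)
    windows = segment(cleaned, config.window_seconds, config.overlap_fraction)
    return [extract_features(w, config.ar_order) for w in windows]


def _corpus_features(corpus, config):
    features, labels, subjects = [], [], []
    for rec in corpus:
        for fv in _recording_features(rec, config):
            features.append(fv.values)
            labels.append(fv.activity_label)
            subjects.append(fv.subject_id)
    return np.asarray(features), labels, subjects


def train(config: PipelineConfig, corpus: Sequence[AccelerometerRecording]) -> PipelineBundle:
    """Fit the full pipeline on a labeled corpus.

    All randomness (network init, batch shuffling) derives from
    ``config.seed``; identical corpus and config give an identical bundle.
    """
    x, labels, subjects = _corpus_features(corpus, config)
    if x.size == 0:
        raise DataError("corpus produced no windows")
    if any(lab is None for lab in labels):
        raise DataError("corpus contains recordings without activity labels")
    class_names = sorted(set(labels))
    if len(class_names) < 2:
        raise DataError(f"need at least 2 activity classes, got {class_names}")

    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0.0] = 1.0
    xs = (x - mean) / scale

    kda_model: KDAModel | None = None
    if config.use_kda:
        kda_model = kda_mod.fit_kda(
            xs,
            np.asarray(labels),
            gamma=config.kda_gamma,
            n_components=config.kda_components,
            eps=config.kda_eps,
            standardize=False,
        )
        classifier_inputs = kda_mod.project(kda_model, xs)
    else:
        classifier_inputs = xs

    input_mean = classifier_inputs.mean(axis=0)
    input_scale = classifier_inputs.std(axis=0)
    input_scale[input_scale == 0.0] = 1.0
    network = ann_mod.train_ann(
        (classifier_inputs - input_mean) / input_scale,
        labels,
        hidden_size=config.hidden_size,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        momentum=config.momentum,
        seed=config.seed,
        class_names=class_names,
    )
    return PipelineBundle(
        config=config,
        class_names=class_names,
        feature_mean=mean,
        feature_scale=scale,
        kda=kda_model,
        ann=network,
        input_mean=input_mean,
        input_scale=input_scale,
        training_subjects=sorted({s for s in subjects if s is not None}),
    )


def _classify_features(bundle: PipelineBundle, x: np.ndarray):
    xs = (x - bundle.feature_mean) / bundle.feature_scale
    if bundle.kda is not None:
        xs = kda_mod.project(bundle.kda, xs)
    if bundle.input_mean is not None:
        xs = (xs - bundle.input_mean) / bundle.input_scale
    return ann_mod.predict_batch(bundle.ann, np.atleast_2d(xs))


def evaluate(
    bundle: PipelineBundle,
    corpus: Sequence[AccelerometerRecording],
    subject_independent: bool = False,
) -> ConfusionMatrix:
    """Per-window classification of a labeled corpus, pooled over windows.

    With ``subject_independent`` the evaluation subjects must be disjoint
    from the bundle's recorded training subjects.
    """
    if subject_independent:
        eval_subjects = {r.subject_id for r in corpus if r.subject_id is not None}
        overlap = eval_subjects & set(bundle.training_subjects)
        if overlap:
            raise ProtocolError(
                f"subject-independent evaluation but subjects {sorted(overlap)} "
                "appear in both training and evaluation corpora"
            )
    x, labels, _ = _corpus_features(corpus, bundle.config)
    if x.size == 0:
        raise DataError("evaluation corpus produced no windows")
    if any(lab is None for lab in labels):
        raise DataError("evaluation corpus contains unlabeled recordings")
    unknown = set(labels) - set(bundle.class_names)
    if unknown:
        raise DataError(f"evaluation corpus has classes unseen in training: {sorted(unknown)}")
    predicted, _ = _classify_features(bundle, x)
    return ConfusionMatrix.from_labels(bundle.class_names, labels, predicted)


def classify_stream(
    bundle: PipelineBundle, rec: AccelerometerRecording
) -> list[tuple[int, str, np.ndarray]]:
    """Window-by-window classification of one recording (the online path).

    Returns (window index, predicted label, score vector) triples; a
    recording shorter than one window yields an empty list. Identical to
    :func:`evaluate`'s per-window path.
    """
    features = _recording_features(rec, bundle.config)
    if not features:
        return []
    x = np.vstack([f.values for f in features])
    labels, scores = _classify_features(bundle, x)
    return [(i, labels[i], scores[i]) for i in range(len(labels))]


def ablate_kda(
    config: PipelineConfig,
    corpus_train: Sequence[AccelerometerRecording],
    corpus_eval: Sequence[AccelerometerRecording],
    subject_independent: bool = True,
) -> tuple[ConfusionMatrix, ConfusionMatrix]:
    """Train/evaluate twice under identical seeds: with and without KDA.

    Returns (matrix with KDA, matrix without KDA); the accuracy delta
    quantifies how much position-induced within-class variance KDA removed.
    """
    from dataclasses import replace

    cm_with = evaluate(
        train(replace(config, use_kda=True), corpus_train),
        corpus_eval,
        subject_independent=subject_independent,
    )
    cm_without = evaluate(
        train(replace(config, use_kda=False), corpus_train),
        corpus_eval,
        subject_independent=subject_independent,
    )
    return cm_with, cm_without


# ---------------------------------------------------------------------------
# bundle serialization


def _kda_to_dict(model: KDAModel) -> dict:
    return {
        "training_vectors": model.training_vectors.tolist(),
        "labels": [str(v) for v in model.labels],
        "gamma": model.gamma,
        "alpha": model.alpha.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "n_components": model.n_components,
        "eps": model.eps,
        "feature_mean": model.feature_mean.tolist(),
        "feature_scale": model.feature_scale.tolist(),
        "kernel_row_mean": (
            None if model.kernel_row_mean is None else model.kernel_row_mean.tolist()
        ),
        "kernel_grand_mean": model.kernel_grand_mean,
    }


def _kda_from_dict(payload: dict) -> KDAModel:
    return KDAModel(
        training_vectors=np.asarray(payload["training_vectors"], dtype=float),
        labels=np.asarray(payload["labels"]),
        gamma=float(payload["gamma"]),
        alpha=np.asarray(payload["alpha"], dtype=float),
        eigenvalues=np.asarray(payload["eigenvalues"], dtype=float),
        n_components=int(payload["n_components"]),
        eps=float(payload["eps"]),
        feature_mean=np.asarray(payload["feature_mean"], dtype=float),
        feature_scale=np.asarray(payload["feature_scale"], dtype=float),
        kernel_row_mean=(
            None
            if payload.get("kernel_row_mean") is None
            else np.asarray(payload["kernel_row_mean"], dtype=float)
        ),
        kernel_grand_mean=float(payload.get("kernel_grand_mean", 0.0)),
    )


def save_bundle(bundle: PipelineBundle, path) -> None:
    """Serialize a bundle to a single JSON document (round-trip exact)."""
    payload = {
        "format_version": bundle.format_version,
        "config": asdict(bundle.config),
        "class_names": bundle.class_names,
        "feature_mean": bundle.feature_mean.tolist(),
        "feature_scale": bundle.feature_scale.tolist(),
        "kda": _kda_to_dict(bundle.kda) if bundle.kda is not None else None,
        "ann": ann_mod.model_to_dict(bundle.ann),
        "input_mean": None if bundle.input_mean is None else bundle.input_mean.tolist(),
        "input_scale": None if bundle.input_scale is None else bundle.input_scale.tolist(),
        "training_subjects": bundle.training_subjects,
    }
    with open(path, "w") as handle:
        json.dump(payload, handle)


def load_bundle(path) -> PipelineBundle:
    try:
        with open(path) as handle:
            payload = json.load(handle)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise FormatError(f"could not parse bundle file {path}: {exc}") from exc
    try:
        return PipelineBundle(
            config=PipelineConfig(**payload["config"]),
            class_names=list(payload["class_names"]),
            feature_mean=np.asarray(payload["feature_mean"], dtype=float),
            feature_scale=np.asarray(payload["feature_scale"], dtype=float),
            kda=_kda_from_dict(payload["kda"]) if payload["kda"] is not None else None,
            ann=ann_mod.model_from_dict(payload["ann"]),
            input_mean=(
                None
                if payload.get("input_mean") is None
                else np.asarray(payload["input_mean"], dtype=float)
            ),
            input_scale=(
                None
                if payload.get("input_scale") is None
                else np.asarray(payload["input_scale"], dtype=float)
            ),
            training_subjects=list(payload.get("training_subjects", [])),
            format_version=int(payload.get("format_version", _FORMAT_VERSION)),
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"invalid bundle payload in {path}: {exc}") from exc
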