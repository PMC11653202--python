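"""Splitting, metrics, and the repeated train/evaluate experiment.

The protocol: split samples into 70% training / 30% testing (stratified by
default), preprocess each modality (selection and scaling statistics fit
on the training split), build the fused hypergraph operator over all
samples from the scaled features, train the network transductively on the
training labels, and score the held-out samples. The experiment repeats
``n_repeats`` times (default 5) with fresh splits; the mean and sample SD
across repeats are reported.

Binary tasks report ACC, F1 (positive class = 1) and AUC; multi-class
tasks report ACC, weighted F1 and macro F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score

from .containers import OmicsMatrix
from .hypergraph import build_fused_operator
from .model import ModelConfig, MoreModel
from .preprocessing import PreprocessConfig, preprocess_modality
from .training import TrainConfig, fit

BINARY_METRICS = ("acc", "f1", "auc")
MULTICLASS_METRICS = ("acc", "f1_weighted", "f1_macro")


@dataclass
class SplitSpec:
    train_fraction: float = 0.70
    stratified: bool = True
    n_repeats: int = 5
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def split(
    labels: np.ndarray, spec: SplitSpec, repeat_index: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic train/test indices for one repeat.

    Stratified mode rounds ``train_fraction * n_c`` to the nearest integer
    per class, then clamps so every class keeps at least one training and
    one testing sample. Indices are returned sorted.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng((spec.base_seed, repeat_index))
    if not spec.stratified:
        perm = rng.permutation(len(labels))
        n_train = int(round(spec.train_fraction * len(labels)))
        n_train = min(max(n_train, 1), len(labels) - 1)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])
    train: list[np.ndarray] = []
    test: list[np.ndarray] = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            raise ValueError(f"class {c} has {len(idx)} sample(s); need >= 2")
        perm = idx[rng.permutation(len(idx))]
        n_train = int(round(spec.train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    y_score: np.ndarray | None = None,
    task: str = "binary",
    n_classes: int | None = None,
) -> dict[str, float]:
    """The metric suite for one prediction set.

    ``y_score`` is the positive-class probability (binary only; required
    for AUC). Multi-class F1 averages treat classes absent from ``y_true``
    as F1 = 0, with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out = {"acc": float(accuracy_score(y_true, y_pred))}
    if task == "binary":
        out["f1"] = float(f1_score(y_true, y_pred, zero_division=0))
        if y_score is not None:
            out["auc"] = float(roc_auc_score(y_true, y_score))
    elif task == "multiclass":
        if y_score is not None:
            raise ValueError("AUC is reported for binary tasks only")
        k = n_classes or int(max(y_true.max(), y_pred.max()) + 1)
        labels = np.arange(k)
        missing = np.setdiff1d(labels, np.unique(y_true))
        if len(missing):
            warnings.warn(
                f"classes {missing.tolist()} absent from y_true; "
                "they contribute F1=0 to the macro average",
                stacklevel=2,
            )
        common = dict(labels=labels, zero_division=0)
        out["f1_weighted"] = float(f1_score(y_true, y_pred, average="weighted", **common))
        out["f1_macro"] = float(f1_score(y_true, y_pred, average="macro", **common))
    else:
        raise ValueError(f"unknown task {task!r}")
    return out


@dataclass
class MetricReport:
    """Per-repeat metric values plus mean and sample SD."""

    per_repeat: list[dict[str, float]]

    @property
    def mean(self) -> dict[str, float]:
        keys = self.per_repeat[0].keys()
        return {k: float(np.mean([r[k] for r in self.per_repeat])) for k in keys}

    @property
    def sd(self) -> dict[str, float]:
        keys = self.per_repeat[0].keys()
        return {
            k: float(np.std([r[k] for r in self.per_repeat], ddof=1))
            if len(self.per_repeat) > 1
            else 0.0
            for k in keys
        }

    def summary(self) -> dict[str, dict[str, float]]:
        return {"mean": self.mean, "sd": self.sd}


@dataclass
class RunBundle:
    """One trained repeat, frozen for later inspection or ablation."""

    model: MoreModel
    X_list: list[np.ndarray]
    G: np.ndarray
    feature_ids: list[list[str]]
    modalities: list[str]
    y: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    task: str
    metrics: dict[str, float]
    history: dict = field(default_factory=dict, repr=False)


@dataclass
class ExperimentConfig:
    """Everything one repeated experiment needs besides the data."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    k: int = 2
    metric_name: str = "euclidean"
    include_self_in_k: bool = True
    modalities: list[str] | None = None  # None = use all


def run_single(
    matrices: list[OmicsMatrix],
    labels: np.ndarray,
    cfg: ExperimentConfig,
    repeat_index: int = 0,
) -> RunBundle:
    """One split -> preprocess -> hypergraph -> train -> test evaluation."""
    labels = np.asarray(labels, dtype=int)
    if cfg.modalities is not None:
        matrices = [m for m in matrices if m.modality in cfg.modalities]
        if not matrices:
            raise ValueError("modality subset matched no input matrix")
    ids = matrices[0].sample_ids
    for m in matrices[1:]:
        if m.sample_ids != ids:
            raise ValueError("sample ids/order differ across modalities")
    n_classes = int(labels.max()) + 1
    task = "binary" if n_classes == 2 else "multiclass"

    train_idx, test_idx = split(labels, cfg.split, repeat_index)
    processed = []
    for m in matrices:
        scaled, _, _ = preprocess_modality(m, labels, cfg.preprocess, train_idx)
        processed.append(scaled)

    X_list = [p.values for p in processed]
    op, _ = build_fused_operator(
        X_list,
        list(ids),
        cfg.k,
        cfg.metric_name,
        include_self_in_k=cfg.include_self_in_k,
    )

    train_cfg = TrainConfig(
        **{**cfg.train.__dict__, "seed": (cfg.train.seed + 7919 * repeat_index) % (2**31)}
    )
    model, history = fit(
        X_list, op.G, labels, train_idx, n_classes, cfg.model, train_cfg
    )

    proba = model.predict_proba(X_list, op.G)
    y_pred = proba.argmax(axis=1)
    score = proba[:, 1] if task == "binary" else None
    metrics = compute_metrics(
        labels[test_idx],
        y_pred[test_idx],
        None if score is None else score[test_idx],
        task=task,
        n_classes=n_classes,
    )
    return RunBundle(
        model=model,
        X_list=X_list,
        G=op.G,
        feature_ids=[p.feature_ids for p in processed],
        modalities=[p.modality for p in processed],
        y=labels,
        train_idx=train_idx,
        test_idx=test_idx,
        task=task,
        metrics=metrics,
        history=history,
    )


def repeat_experiment(
    matrices: list[OmicsMatrix],
    labels: np.ndarray,
    cfg: ExperimentConfig,
) -> tuple[MetricReport, list[RunBundle]]:
    """Run the full protocol ``cfg.split.n_repeats`` times."""
    runs = [
        run_single(matrices, labels, cfg, repeat_index=r)
        for r in range(cfg.split.n_repeats)
    ]
    return MetricReport([r.metrics for r in runs]), runs
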