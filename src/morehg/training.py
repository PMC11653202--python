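"""Two-step optimization of the network.

Step one trains each omics-specific encoder (plus its head) alone on its
cross-entropy loss; step two optimizes every parameter on the total loss

    L = sum_i L_omics-specific^(i) + L_multi-omics,

where each term is a cross-entropy over the training vertices only. The
losses use the mean over training samples rather than the raw sum — the
two differ by the constant factor N and the mean keeps learning rates
comparable across split sizes. An end-to-end mode skips step one and
optimizes the total loss from random initialization.

Training is transductive: features of all samples (and the operator G
built from them) enter the forward pass, but only training-vertex labels
ever touch a loss or gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, masked_cross_entropy
from .model import ModelConfig, MoreModel

VARIANT_ARCHITECTURES = {
    "full": ("mohe", "mosa"),
    "nn_nn": ("nn", "nn"),
    "nn_mosa": ("nn", "mosa"),
    "mohe_nn": ("mohe", "nn"),
}


@dataclass
class TrainConfig:
    pretrain_epochs: int = 200
    joint_epochs: int = 500
    lr: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    mode: str = "two_step"  # "two_step" | "end_to_end"
    variant: str = "full"  # keys of VARIANT_ARCHITECTURES

    def __post_init__(self) -> None:
        if self.pretrain_epochs < 1 or self.joint_epochs < 1:
            raise ValueError("epoch counts must be >= 1")
        if self.mode not in ("two_step", "end_to_end"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.variant not in VARIANT_ARCHITECTURES:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class LossReport:
    """Loss decomposition at one logged epoch; total = sum of the parts."""

    epoch: int
    per_omics: list[float] = field(default_factory=list)
    multi_omics: float = 0.0

    @property
    def total(self) -> float:
        return float(sum(self.per_omics) + self.multi_omics)


def cross_entropy(scores: np.ndarray, y: np.ndarray, from_logits: bool = True) -> float:
    """Mean negative log-probability of the true class.

    ``scores`` holds per-sample class logits (default) or probabilities.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite scores")
    y = np.asarray(y, dtype=int)
    if scores.ndim != 2 or len(y) != scores.shape[0]:
        raise ValueError("scores must be n_samples x n_classes, one label each")
    if (y < 0).any() or (y >= scores.shape[1]).any():
        raise ValueError("label out of range")
    if from_logits:
        z = scores - scores.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    else:
        logp = np.log(scores)
    return float(-logp[np.arange(len(y)), y].mean())


def _check_finite(value: float, context: str) -> None:
    if not np.isfinite(value):
        raise FloatingPointError(f"{context}: loss diverged to {value}")


def pretrain(
    model: MoreModel,
    X_list: list[np.ndarray],
    G: np.ndarray | None,
    y: np.ndarray,
    train_idx: np.ndarray,
    cfg: TrainConfig,
) -> list[list[float]]:
    """Step one: optimize each encoder + head on its own loss.

    Returns one loss trace per modality. Only ``y[train_idx]`` is read.
    """
    traces: list[list[float]] = []
    for i, enc in enumerate(model.encoders):
        rng = np.random.default_rng((cfg.seed, 1, i))
        opt = Adam(enc.parameters(), lr=cfg.lr)
        trace: list[float] = []
        Gt = None if G is None else Tensor(G)
        for _ in range(cfg.pretrain_epochs):
            opt.zero_grad()
            _, logits = enc.forward(Tensor(X_list[i]), Gt, training=True, rng=rng)
            loss = masked_cross_entropy(logits, y, train_idx)
            _check_finite(loss.data, f"pretraining modality {i}")
            loss.backward()
            opt.step()
            trace.append(float(loss.data))
        traces.append(trace)
    return traces


def train_joint(
    model: MoreModel,
    X_list: list[np.ndarray],
    G: np.ndarray | None,
    y: np.ndarray,
    train_idx: np.ndarray,
    cfg: TrainConfig,
) -> list[LossReport]:
    """Step two: optimize all parameters on the total loss."""
    rng = np.random.default_rng((cfg.seed, 2))
    opt = Adam(model.parameters(), lr=cfg.lr)
    reports: list[LossReport] = []
    for epoch in range(cfg.joint_epochs):
        opt.zero_grad()
        omics_logits, fused_logits, _ = model.forward(
            X_list, G, training=True, rng=rng
        )
        parts = [masked_cross_entropy(lg, y, train_idx) for lg in omics_logits]
        multi = masked_cross_entropy(fused_logits, y, train_idx)
        loss = parts[0]
        for p in parts[1:]:
            loss = loss + p
        loss = loss + multi
        _check_finite(loss.data, f"joint epoch {epoch}")
        loss.backward()
        opt.step()
        reports.append(
            LossReport(
                epoch=epoch,
                per_omics=[float(p.data) for p in parts],
                multi_omics=float(multi.data),
            )
        )
    return reports


def fit(
    X_list: list[np.ndarray],
    G: np.ndarray | None,
    y: np.ndarray,
    train_idx: np.ndarray,
    n_classes: int,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> tuple[MoreModel, dict]:
    """Build and train a model per the configured mode and variant."""
    encoder, fusion = VARIANT_ARCHITECTURES[train_cfg.variant]
    cfg = ModelConfig(**{**model_cfg.__dict__, "encoder": encoder, "fusion": fusion})
    model = MoreModel(
        [x.shape[1] for x in X_list], n_classes, cfg, seed=train_cfg.seed
    )
    history: dict = {}
    if train_cfg.mode == "two_step":
        history["pretrain"] = pretrain(model, X_list, G, y, train_idx, train_cfg)
    history["joint"] = train_joint(model, X_list, G, y, train_idx, train_cfg)
    return model, history
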