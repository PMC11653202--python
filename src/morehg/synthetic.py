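"""Synthetic aligned multi-omics data with planted class signal.

The generator emulates the situation the pipeline is built for: several
feature matrices (e.g. mRNA expression, DNA methylation, miRNA expression)
measured on the same samples, where a small planted subset of features per
modality separates the classes by a mean shift while everything else is
noise. It deliberately keeps the marginals Gaussian: a mean-shift-plus-noise
model is the simplest structure that exercises ANOVA selection, kNN
hypergraph locality, classification, and biomarker recovery end to end.

Class ``c`` shifts each signal feature's mean to ``c * effect_size *
noise_sd``; non-signal features have mean 0 for every class. A configurable
fraction of non-signal features is set entirely to NaN so the
missing-feature preprocessing step has something to do. Values are left
unscaled on purpose — mapping to [0, 1] is the preprocessing stage's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import GroundTruth, OmicsMatrix

DEFAULT_MODALITIES = ("mRNA", "meth", "miRNA")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic multi-omics dataset.

    ``effect_size`` is the between-class mean shift in units of ``noise_sd``;
    ``signal_features_per_modality[i]`` features in modality ``i`` carry it.
    ``missing_fraction`` of each modality's features (drawn from the
    non-signal ones) are set entirely to NaN.
    """

    n_samples: int = 351
    n_classes: int = 2
    features_per_modality: tuple[int, ...] = (200, 200, 200)
    signal_features_per_modality: tuple[int, ...] = (20, 20, 20)
    effect_size: float = 1.5
    noise_sd: float = 1.0
    missing_fraction: float = 0.0
    seed: int = 0
    modalities: tuple[str, ...] = field(default=DEFAULT_MODALITIES)

    def __post_init__(self) -> None:
        self.features_per_modality = tuple(self.features_per_modality)
        self.signal_features_per_modality = tuple(self.signal_features_per_modality)
        if len(self.modalities) != len(self.features_per_modality):
            # default names for a non-standard modality count
            self.modalities = tuple(
                f"omics{i}" for i in range(len(self.features_per_modality))
            )
        if len(self.signal_features_per_modality) != len(self.features_per_modality):
            raise ValueError("signal_features_per_modality length mismatch")
        for sig, tot in zip(
            self.signal_features_per_modality, self.features_per_modality
        ):
            if sig > tot:
                raise ValueError(f"{sig} signal features but only {tot} features")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_samples < self.n_classes:
            raise ValueError("need at least one sample per class")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")


def generate_multiomics(
    spec: SyntheticSpec,
) -> tuple[list[OmicsMatrix], GroundTruth]:
    """Draw aligned modality matrices plus the planted ground truth.

    Sample ids are ``S0001...``; feature ids are ``<modality>_f<idx>`` with
    the signal features occupying the low indices (a documented prefix, so
    recovery can be asserted). Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples

    # near-balanced labels, shuffled
    labels = np.arange(n) % spec.n_classes
    rng.shuffle(labels)

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    matrices: list[OmicsMatrix] = []
    signal_ids: dict[str, list[str]] = {}
    missing_ids: dict[str, list[str]] = {}

    for mod, p, n_sig in zip(
        spec.modalities, spec.features_per_modality, spec.signal_features_per_modality
    ):
        feature_ids = [f"{mod}_f{j}" for j in range(p)]
        means = np.zeros((n, p))
        means[:, :n_sig] = (labels * spec.effect_size * spec.noise_sd)[:, None]
        values = means + rng.normal(0.0, spec.noise_sd, size=(n, p))

        n_missing = int(round(spec.missing_fraction * p))
        n_missing = min(n_missing, p - n_sig)  # never blank a signal feature
        if n_missing > 0:
            cols = rng.choice(np.arange(n_sig, p), size=n_missing, replace=False)
            values[:, cols] = np.nan
            missing_ids[mod] = sorted(
                (feature_ids[c] for c in cols), key=feature_ids.index
            )
        else:
            missing_ids[mod] = []

        matrices.append(
            OmicsMatrix(values, list(sample_ids), feature_ids, modality=mod)
        )
        signal_ids[mod] = feature_ids[:n_sig]

    truth = GroundTruth(
        labels=labels.astype(int),
        signal_feature_ids=signal_ids,
        missing_feature_ids=missing_ids,
    )
    return matrices, truth
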