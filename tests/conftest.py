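import numpy as np
import pytest

import morehg as mh


@pytest.fixture(scope="session")
def recovery_conditions():
    """The reference synthetic recovery setting: 300 samples, 2 classes,
    200 features per modality with 20 planted signal features, effect 2."""
    spec = mh.SyntheticSpec(
        n_samples=300,
        n_classes=2,
        features_per_modality=(200, 200, 200),
        signal_features_per_modality=(20, 20, 20),
        effect_size=2.0,
        noise_sd=1.0,
        seed=11,
    )
    matrices, truth = mh.generate_multiomics(spec)
    return spec, matrices, truth


@pytest.fixture(scope="session")
def recovery_runs(recovery_conditions):
    """Five trained repeats of the full protocol at the reference setting.

    Shared by the end-to-end classification and biomarker-recovery checks
    so the models are trained once per session.
    """
    _, matrices, truth = recovery_conditions
    cfg = mh.ExperimentConfig()
    cfg.preprocess.n_select = 200
    cfg.train.pretrain_epochs = 60
    cfg.train.joint_epochs = 150
    cfg.split.n_repeats = 5
    cfg.k = 2
    report, runs = mh.repeat_experiment(matrices, truth.labels, cfg)
    return report, runs, truth


@pytest.fixture(scope="session")
def noisy_runs():
    """Two trained repeats at a deliberately hard setting (effect 0.8,
    5 planted of 60 features) where accuracy is imperfect and single-feature
    ablation drops are informative rather than exactly zero."""
    spec = mh.SyntheticSpec(
        n_samples=160,
        n_classes=2,
        features_per_modality=(60, 60, 60),
        signal_features_per_modality=(5, 5, 5),
        effect_size=0.8,
        seed=0,
    )
    matrices, truth = mh.generate_multiomics(spec)
    cfg = mh.ExperimentConfig()
    cfg.preprocess.n_select = 60
    cfg.train.pretrain_epochs = 40
    cfg.train.joint_epochs = 100
    cfg.split.n_repeats = 2
    report, runs = mh.repeat_experiment(matrices, truth.labels, cfg)
    return report, runs, truth


@pytest.fixture()
def tiny_dataset():
    """Small separable dataset for fast unit-level training checks."""
    spec = mh.SyntheticSpec(
        n_samples=60,
        n_classes=2,
        features_per_modality=(15, 15),
        signal_features_per_modality=(4, 4),
        effect_size=3.0,
        seed=5,
        modalities=("mRNA", "meth"),
    )
    matrices, truth = mh.generate_multiomics(spec)
    return matrices, truth


def random_incidence(rng: np.random.Generator) -> mh.IncidenceStructure:
    """Random fused kNN incidence: N <= 40 vertices, <= 3 modalities, k <= 5."""
    n = int(rng.integers(4, 41))
    n_mod = int(rng.integers(1, 4))
    k = int(rng.integers(1, min(5, n) + 1))
    parts = [
        mh.knn_hyperedges(
            rng.normal(size=(n, int(rng.integers(2, 6)))),
            [f"v{i}" for i in range(n)],
            k,
        )
        for _ in range(n_mod)
    ]
    return mh.fuse_incidence(parts)
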