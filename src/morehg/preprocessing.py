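"""Feature cleaning, variance filtering, ANOVA selection, [0,1] scaling.

The stages run in a fixed order — drop all-or-partly missing features,
filter low-variance features with a per-modality threshold (0.1 for mRNA,
0.001 for methylation, 0 for miRNA by default), keep the features with the
largest one-way ANOVA F statistic, then min-max scale each surviving
feature to [0, 1]. Variance uses the population (divide-by-n) formula.

Selection and scaling can be fit on training samples only (default,
avoiding test leakage) or on all samples (transductive); both are exposed
because either convention appears in this literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import MinMaxScaler

from .containers import OmicsMatrix

DEFAULT_VARIANCE_THRESHOLDS = {"mRNA": 0.1, "meth": 0.001, "miRNA": 0.0}


@dataclass
class FeatureScore:
    """One feature's ANOVA F statistic and its rank (1 = largest F)."""

    feature_id: str
    f_value: float
    rank: int


@dataclass
class PreprocessConfig:
    """Per-modality variance thresholds and ANOVA survivor counts.

    ``variance_thresholds`` falls back to 0.0 for modality names it does not
    list. ``n_select`` caps the features kept per modality after ANOVA
    ranking (clamped to the number of available features). ``fit_on``
    selects whether selection/scaling statistics use training samples only
    ("train") or every sample ("all").
    """

    variance_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VARIANCE_THRESHOLDS)
    )
    n_select: int = 200
    fit_on: str = "train"

    def threshold_for(self, modality: str) -> float:
        return float(self.variance_thresholds.get(modality, 0.0))


def drop_missing(m: OmicsMatrix) -> OmicsMatrix:
    """Remove every feature column that contains at least one NaN."""
    keep = ~np.isnan(m.values).any(axis=0)
    if not keep.any():
        raise ValueError(f"all features of modality {m.modality!r} contain NaN")
    return m.select_features(np.flatnonzero(keep))


def variance_filter(m: OmicsMatrix, threshold: float) -> OmicsMatrix:
    """Keep features whose population variance exceeds ``threshold``.

    With ``threshold=0`` only constant features are removed.
    """
    if np.isnan(m.values).any():
        raise ValueError("variance_filter requires a NaN-free matrix")
    var = m.values.var(axis=0)  # ddof=0: population variance
    keep = var > threshold
    if not keep.any():
        raise ValueError(
            f"no feature of modality {m.modality!r} has variance > {threshold}"
        )
    return m.select_features(np.flatnonzero(keep))


def anova_f_values(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic per column.

    F = (between-group SS / (k-1)) / (within-group SS / (n-k)). Columns with
    zero within-group variance get +inf when the between-group part is
    positive and 0.0 when the column is constant overall.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    n, _ = values.shape
    k = len(classes)
    grand = values.mean(axis=0)
    ssb = np.zeros(values.shape[1])
    ssw = np.zeros(values.shape[1])
    for c in classes:
        grp = values[labels == c]
        gm = grp.mean(axis=0)
        ssb += len(grp) * (gm - grand) ** 2
        ssw += ((grp - gm) ** 2).sum(axis=0)
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    f = np.where(msw == 0, np.where(msb > 0, np.inf, 0.0), f)
    return f


def anova_select(
    m: OmicsMatrix,
    labels: np.ndarray,
    n_select: int,
    *,
    fit_rows: np.ndarray | None = None,
) -> tuple[OmicsMatrix, list[FeatureScore]]:
    """Keep the ``n_select`` features with the largest F statistic.

    ``labels`` must align with ``fit_rows`` (or with all rows when
    ``fit_rows`` is None). Column order among survivors is preserved; ties
    in F break toward the lower column index. Scores are returned for every
    feature, ranked 1 = largest F.
    """
    labels = np.asarray(labels)
    values = m.values if fit_rows is None else m.values[np.asarray(fit_rows)]
    if len(labels) != values.shape[0]:
        raise ValueError("labels length does not match the fitted rows")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or (counts < 2).any():
        raise ValueError("need >=2 classes with >=2 samples each")
    if n_select > m.n_features:
        raise ValueError(f"n_select={n_select} > {m.n_features} features")

    f = anova_f_values(values, labels)
    # descending F, ties toward the lower column index
    order = np.lexsort((np.arange(len(f)), -f))
    ranks = np.empty(len(f), dtype=int)
    ranks[order] = np.arange(1, len(f) + 1)
    scores = [
        FeatureScore(fid, float(fv), int(r))
        for fid, fv, r in zip(m.feature_ids, f, ranks)
    ]
    keep = np.sort(order[:n_select])
    return m.select_features(keep), scores


def minmax_scale(
    train: OmicsMatrix, others: list[OmicsMatrix] | None = None
) -> tuple[OmicsMatrix, list[OmicsMatrix], np.ndarray, np.ndarray]:
    """Scale features to [0,1] with min/max fit on ``train``.

    Held-out matrices in ``others`` are transformed with the training
    min/max and clipped to [0,1]. Returns the scaled matrices plus the
    per-feature minima and maxima.
    """
    scaler = MinMaxScaler(clip=True)
    scaled_train = scaler.fit_transform(train.values)
    rng_span = scaler.data_max_ - scaler.data_min_
    if (rng_span == 0).any():
        j = int(np.flatnonzero(rng_span == 0)[0])
        raise ValueError(
            f"constant feature {train.feature_ids[j]!r} reached scaling; "
            "variance_filter should have removed it"
        )
    out_train = OmicsMatrix(
        scaled_train, list(train.sample_ids), list(train.feature_ids), train.modality
    )
    out_others = []
    for o in others or []:
        if o.feature_ids != train.feature_ids:
            raise ValueError("feature ids of held-out matrix do not match train")
        out_others.append(
            OmicsMatrix(
                o.values.copy() if o.n_samples == 0 else scaler.transform(o.values),
                list(o.sample_ids),
                list(o.feature_ids),
                o.modality,
            )
        )
    return out_train, out_others, scaler.data_min_.copy(), scaler.data_max_.copy()


def preprocess_modality(
    m: OmicsMatrix,
    labels: np.ndarray,
    config: PreprocessConfig,
    train_rows: np.ndarray | None = None,
) -> tuple[OmicsMatrix, list[FeatureScore], dict[str, int]]:
    """Full pipeline for one modality; returns the scaled matrix.

    ``labels`` must cover all rows of ``m``. With ``fit_on="train"`` the
    ANOVA selection and the min/max statistics use only ``train_rows``; the
    remaining rows are transformed with the training statistics (clipped).
    The returned matrix keeps all samples in their original order.
    """
    counts = {"input": m.n_features}
    m = drop_missing(m)
    counts["after_drop_missing"] = m.n_features
    m = variance_filter(m, config.threshold_for(m.modality))
    counts["after_variance_filter"] = m.n_features

    labels = np.asarray(labels)
    if train_rows is None or config.fit_on == "all":
        fit_rows = np.arange(m.n_samples)
    else:
        fit_rows = np.asarray(train_rows, dtype=int)
    n_select = min(config.n_select, m.n_features)
    m, scores = anova_select(m, labels[fit_rows], n_select, fit_rows=fit_rows)
    counts["after_anova_select"] = m.n_features

    train_part = m.select_samples(fit_rows)
    rest_rows = np.setdiff1d(np.arange(m.n_samples), fit_rows)
    rest_part = m.select_samples(rest_rows)
    scaled_train, scaled_rest, _, _ = minmax_scale(train_part, [rest_part])
    values = np.empty_like(m.values)
    values[fit_rows] = scaled_train.values
    values[rest_rows] = scaled_rest[0].values
    out = OmicsMatrix(values, list(m.sample_ids), list(m.feature_ids), m.modality)
    return out, scores, counts
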