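"""Biomarker ranking by zero-out feature ablation.

Because every input feature is scaled to [0, 1], setting a feature's
column to 0 removes it from the forward pass without retraining. The
importance of a feature is the drop in the test metric (F1 for binary
tasks, macro F1 for multi-class) it causes, summed over the repeated
trained runs; features are ranked per modality by that summed drop.

The trained model — including its propagation operator G — is frozen
during ablation: the hypergraph is deliberately not rebuilt from the
ablated features, so the measured drop isolates the feature's effect on
the forward pass rather than conflating it with a graph change
(``rebuild_graph=True`` restores the alternative). Negative drops
(ablation helps) are kept and naturally rank last; ties break toward the
lower feature index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import RunBundle, compute_metrics
from .hypergraph import build_fused_operator


@dataclass
class BiomarkerTable:
    """Per-feature summed metric drops with per-modality ranks."""

    table: pd.DataFrame  # modality, feature_id, drop_run{r}..., summed_drop, rank
    metric: str

    def top(self, top_k: int = 10) -> pd.DataFrame:
        return (
            self.table[self.table["rank"] <= top_k]
            .sort_values(["modality", "rank"])
            .reset_index(drop=True)
        )


def _metric_name(task: str) -> str:
    return "f1" if task == "binary" else "f1_macro"


def _test_metric(run: RunBundle, X_list: list[np.ndarray], G: np.ndarray) -> float:
    proba = run.model.predict_proba(X_list, G)
    y_pred = proba.argmax(axis=1)
    name = _metric_name(run.task)
    m = compute_metrics(
        run.y[run.test_idx],
        y_pred[run.test_idx],
        proba[run.test_idx, 1] if run.task == "binary" else None,
        task=run.task,
        n_classes=int(run.y.max()) + 1,
    )
    return m[name]


def ablate_feature(
    run: RunBundle,
    modality: str,
    feature_id: str,
    *,
    rebuild_graph: bool = False,
    baseline: float | None = None,
    k: int | None = None,
) -> float:
    """Metric drop (baseline - ablated) from zeroing one feature everywhere.

    The column is zeroed for all samples; the metric is computed on the
    test vertices. ``baseline`` can be passed to avoid recomputing it.
    """
    try:
        mi = run.modalities.index(modality)
    except ValueError:
        raise KeyError(f"unknown modality {modality!r}") from None
    try:
        fi = run.feature_ids[mi].index(feature_id)
    except ValueError:
        raise KeyError(f"unknown feature {feature_id!r} in {modality!r}") from None

    if baseline is None:
        baseline = _test_metric(run, run.X_list, run.G)
    X_abl = list(run.X_list)
    col = np.array(X_abl[mi])
    col[:, fi] = 0.0
    X_abl[mi] = col
    if rebuild_graph:
        if k is None:
            raise ValueError("rebuild_graph requires k")
        op, _ = build_fused_operator(
            X_abl, [str(i) for i in range(len(run.y))], k
        )
        G = op.G
    else:
        G = run.G
    return baseline - _test_metric(run, X_abl, G)


def rank_biomarkers(
    runs: list[RunBundle],
    top_k: int = 10,
) -> BiomarkerTable:
    """Sum per-run ablation drops for every feature and rank per modality.

    Ranking is descending in summed drop; ties break toward the lower
    feature index within the modality. ``top_k`` only affects the
    convenience accessor — the table always holds every feature.
    """
    if not runs:
        raise ValueError("need at least one trained run")
    ref = runs[0]
    metric = _metric_name(ref.task)
    baselines = [_test_metric(r, r.X_list, r.G) for r in runs]

    records: list[dict] = []
    for mi, modality in enumerate(ref.modalities):
        # selection is refit per repeat, so feature sets may differ; rank
        # over the union, a run contributing 0 for features it never saw
        feature_ids: list[str] = []
        seen: set[str] = set()
        for run in runs:
            for fid in run.feature_ids[mi]:
                if fid not in seen:
                    seen.add(fid)
                    feature_ids.append(fid)
        drops = np.zeros((len(runs), len(feature_ids)))
        for ri, run in enumerate(runs):
            present = set(run.feature_ids[mi])
            for fi, fid in enumerate(feature_ids):
                if fid in present:
                    drops[ri, fi] = ablate_feature(
                        run, modality, fid, baseline=baselines[ri]
                    )
        summed = drops.sum(axis=0)
        order = np.lexsort((np.arange(len(summed)), -summed))
        ranks = np.empty(len(summed), dtype=int)
        ranks[order] = np.arange(1, len(summed) + 1)
        for fi, fid in enumerate(feature_ids):
            rec = {"modality": modality, "feature_id": fid}
            for ri in range(len(runs)):
                rec[f"drop_run{ri}"] = drops[ri, fi]
            rec["summed_drop"] = summed[fi]
            rec["rank"] = int(ranks[fi])
            records.append(rec)

    table = pd.DataFrame.from_records(records)
    return BiomarkerTable(table=table, metric=metric)
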