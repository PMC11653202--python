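"""Readers, writers, config loading, and run manifests.

Omics matrices travel as CSV/TSV with the sample-id column first and
feature ids in the header; empty cells or ``NaN`` mark missing values.
Labels are a two-column CSV (sample_id, label). Reports and manifests are
JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import OmicsMatrix


def read_omics_csv(path: str | Path, modality: str | None = None) -> OmicsMatrix:
    """Load one modality matrix; ids come from the file, order preserved."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})
    sample_ids = [str(s) for s in df.index]
    feature_ids = [str(c) for c in df.columns]
    for name, ids in (("sample", sample_ids), ("feature", feature_ids)):
        dupes = pd.Series(ids)[pd.Series(ids).duplicated()]
        if len(dupes):
            raise ValueError(f"duplicate {name} id {dupes.iloc[0]!r} in {path}")
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as err:
        raise ValueError(f"non-numeric cell in {path}: {err}") from None
    return OmicsMatrix(
        values, sample_ids, feature_ids, modality=modality or path.stem
    )


def write_omics_csv(m: OmicsMatrix, path: str | Path) -> None:
    pd.DataFrame(m.values, index=m.sample_ids, columns=m.feature_ids).to_csv(
        path, index_label="sample_id"
    )


def read_labels_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, dtype={0: str})
    ids = [str(s) for s in df.iloc[:, 0]]
    return ids, df.iloc[:, 1].to_numpy(dtype=int)


def write_labels_csv(sample_ids: list[str], labels: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "label": labels}).to_csv(path, index=False)


def align_modalities(
    matrices: list[OmicsMatrix], sample_ids: list[str]
) -> list[OmicsMatrix]:
    """Reorder each matrix's rows to ``sample_ids``; error on set mismatch."""
    out = []
    for m in matrices:
        if m.sample_ids == sample_ids:
            out.append(m)
            continue
        if set(m.sample_ids) != set(sample_ids):
            missing = sorted(set(sample_ids) - set(m.sample_ids))[:3]
            extra = sorted(set(m.sample_ids) - set(sample_ids))[:3]
            raise ValueError(
                f"sample sets differ for modality {m.modality!r}: "
                f"missing {missing}, extra {extra}"
            )
        pos = {s: i for i, s in enumerate(m.sample_ids)}
        out.append(m.select_samples(np.array([pos[s] for s in sample_ids])))
    return out


def content_hash(paths: list[str | Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(str(p) for p in paths):
        h.update(Path(p).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: str | Path, payload: dict) -> Path:
    out = Path(out_dir) / "manifest.json"
    out.write_text(json.dumps(payload, indent=2, default=str))
    return out


def export_incidence_coo(H: np.ndarray, vertex_ids: list[str], path: str | Path) -> None:
    """Sparse coordinate text export of an incidence matrix."""
    rows, cols = np.nonzero(H)
    pd.DataFrame(
        {"vertex_id": [vertex_ids[r] for r in rows], "hyperedge_id": cols}
    ).to_csv(path, index=False)
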