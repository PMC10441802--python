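"""Delimited-text and JSON input/output.

Cluster indices are 1-based in all files (``cluster_1``, ``cluster_2``,
...); the in-memory arrays are 0-based.  Conversion lives here only.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .civi import ModelWeights
from .core import AllocationMatrix, LabeledDataset, SimilarityMatrix
from .ssmf import EnsembleResult
from .synthetic_data import SimSpec


def write_allocation(alloc: AllocationMatrix, path) -> None:
    """Allocation matrix as CSV: observation id plus one column per cluster."""
    df = pd.DataFrame(
        alloc.values, columns=[f"cluster_{k + 1}" for k in range(alloc.n_clusters)]
    )
    df.insert(0, "observation", np.arange(1, alloc.n_points + 1))
    df.to_csv(path, index=False)


def read_allocation(path, model_id: str | None = None) -> AllocationMatrix:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("cluster_")]
    if not cols:
        raise ValueError(f"{path}: no cluster_* columns found")
    return AllocationMatrix(
        df[cols].to_numpy(dtype=float), model_id=model_id or Path(path).stem
    )


def write_similarity(sim: SimilarityMatrix, path) -> None:
    """Square CSV with matching observation ids on rows and columns."""
    ids = [f"obs_{i + 1}" for i in range(sim.n_points)]
    pd.DataFrame(sim.values, index=ids, columns=ids).to_csv(path)


def read_similarity(path) -> SimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    return SimilarityMatrix(df.to_numpy(dtype=float))


def similarity_long_format(sim: SimilarityMatrix) -> pd.DataFrame:
    """Heatmap-ready (i, j, value) long table, 1-based ids."""
    n = sim.n_points
    i, j = np.meshgrid(np.arange(1, n + 1), np.arange(1, n + 1), indexing="ij")
    return pd.DataFrame(
        {"i": i.ravel(), "j": j.ravel(), "value": sim.values.ravel()}
    )


def write_dataset(data: LabeledDataset, path, sidecar: bool = True) -> None:
    """Features + label column as CSV, with a JSON sidecar of the settings."""
    df = pd.DataFrame(
        data.features, columns=[f"x{d + 1}" for d in range(data.n_dims)]
    )
    df["label"] = data.labels
    df.to_csv(path, index=False)
    if sidecar:
        Path(str(path) + ".json").write_text(json.dumps(data.meta, indent=2))


def read_dataset(path) -> LabeledDataset:
    df = pd.read_csv(path)
    labels = df.pop("label").to_numpy(dtype=int)
    meta = {}
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    sizes = tuple(np.bincount(labels)[1:].tolist())
    return LabeledDataset(
        features=df.to_numpy(dtype=float),
        labels=labels,
        separation=float(meta.get("sep_val", 0.0)),
        sizes=sizes,
        meta=meta,
    )


def spec_from_meta(meta: dict) -> SimSpec:
    return SimSpec(
        n_clusters=int(meta["n_clusters"]),
        points_per_cluster=int(meta["points_per_cluster"]),
        n_dims=int(meta["n_dims"]),
        sep_val=float(meta["sep_val"]),
        seed=int(meta.get("seed", 0)),
    )


def write_weights(weights: ModelWeights, path) -> None:
    Path(path).write_text(json.dumps(weights.as_dict(), indent=2))


def write_result(result: EnsembleResult, prefix) -> None:
    """EnsembleResult to ``<prefix>_allocations.csv`` and ``<prefix>_summary.json``.

    The allocation CSV carries per-cluster probabilities, the hardened
    label and the per-point uncertainty; the summary JSON the weights,
    surviving cluster count and solver diagnostics.
    """
    prefix = str(prefix)
    alloc = result.allocations
    df = pd.DataFrame(
        alloc.values, columns=[f"cluster_{k + 1}" for k in range(alloc.n_clusters)]
    )
    df.insert(0, "observation", np.arange(1, alloc.n_points + 1))
    df["hard_label"] = alloc.hard_labels()
    df["uncertainty"] = result.uncertainty
    df.to_csv(prefix + "_allocations.csv", index=False)
    summary = {
        "weights": result.weights.as_dict(),
        "surviving_clusters": int(result.surviving_clusters),
        "final_objective": float(result.objective_trace[-1]),
        **{k: v for k, v in result.meta.items()},
    }
    Path(prefix + "_summary.json").write_text(json.dumps(summary, indent=2, default=str))
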