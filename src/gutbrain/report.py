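"""Deterministic file-based outputs: clustered heat-map orderings, manifests.

Figures themselves are not the tested surface; the leaf orderings and the
reordered matrices behind them are, so those are what this module computes
and writes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage as scipy_linkage
from scipy.spatial.distance import pdist

__all__ = ["ClusteredMatrix", "cluster_heatmap", "write_manifest"]

_DISTANCES = ("euclidean", "correlation")
_LINKAGES = ("average", "complete")


@dataclass(frozen=True)
class ClusteredMatrix:
    """A matrix reordered by the leaf orders of two hierarchical clusterings."""

    matrix: pd.DataFrame
    row_order: tuple
    col_order: tuple
    distance: str
    linkage: str

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path, float_format="%.17g")


def _leaf_order(values: np.ndarray, distance: str, method: str) -> np.ndarray:
    if values.shape[0] < 2:
        return np.arange(values.shape[0])
    d = pdist(values, metric=distance)
    if not np.all(np.isfinite(d)):
        raise ValueError(
            f"{distance} distances are undefined for this matrix "
            "(constant rows under correlation?)"
        )
    return leaves_list(scipy_linkage(d, method=method))


def cluster_heatmap(
    matrix: pd.DataFrame, distance: str = "euclidean", linkage: str = "average"
) -> ClusteredMatrix:
    """Agglomeratively cluster rows and columns; return the reordered matrix.

    Rows and columns are pre-sorted by label before the distances are
    computed, so equal-distance merges are resolved identically on every
    run — the leaf orders depend only on the values and labels, never on
    input order.
    """
    if distance not in _DISTANCES:
        raise ValueError(f"distance must be one of {_DISTANCES}, got {distance!r}")
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}, got {linkage!r}")
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("clustering needs at least 2 rows and 2 columns")
    arr = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("matrix contains NaN or infinite entries")
    m = matrix.sort_index(axis=0, key=lambda ix: ix.map(str)).sort_index(
        axis=1, key=lambda ix: ix.map(str)
    )
    vals = m.to_numpy(dtype=float)
    rows = _leaf_order(vals, distance, linkage)
    cols = _leaf_order(vals.T, distance, linkage)
    reordered = m.iloc[rows, cols]
    return ClusteredMatrix(
        matrix=reordered,
        row_order=tuple(reordered.index),
        col_order=tuple(reordered.columns),
        distance=distance,
        linkage=linkage,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(config: dict, inputs, outputs, path) -> dict:
    """Record a run: parameters, input digests, output file list.

    Raises FileNotFoundError if any declared output is missing. The
    ``created`` timestamp is the only field that differs between reruns of
    an identical configuration.
    """
    inputs = [Path(p) for p in inputs]
    outputs = [Path(p) for p in outputs]
    for p in outputs:
        if not p.exists():
            raise FileNotFoundError(f"declared output is missing: {p}")
    manifest = {
        "config": dict(config),
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": sorted(p.name for p in outputs),
        "created": datetime.now(timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
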