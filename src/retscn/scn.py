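"""Group-level structural covariance networks (SCNs).

Nodes are the 63 (layer, sector) thickness measurements; the edge between
two nodes is the absolute Pearson correlation of their age-residualised
values across the eyes of one group.  Residualising each node on age with an
intercept before correlating is algebraically identical to the first-order
partial correlation given age, which is the standard SCN construction when a
single confounder is named.

Negative raw correlations are kept as absolute values, never zeroed; their
pre-absolute share is recorded as ``negative_fraction`` and a warning is
emitted when it reaches 5% of node pairs, the level at which the sign
pattern would start to matter for interpretation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import NODE_LABELS, CohortTable, Group

logger = logging.getLogger(__name__)

#: Share of negative raw correlations above which a warning is logged.
NEGATIVE_FRACTION_WARN = 0.05


class FormatError(ValueError):
    """A persisted matrix file violates the adjacency contract."""


class ZeroVarianceError(ValueError):
    """A node has no residual variance; its correlations are undefined."""


@dataclass
class AdjacencyMatrix:
    """Symmetric nonnegative weighted SCN with labelled nodes."""

    weights: np.ndarray
    node_labels: tuple[str, ...]
    group: str
    n_samples: int
    negative_fraction: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise FormatError(f"weights must be square, got shape {w.shape}")
        if w.shape[0] != len(self.node_labels):
            raise FormatError(
                f"{len(self.node_labels)} labels for a {w.shape[0]}-node matrix"
            )
        if not np.all(np.isfinite(w)):
            raise FormatError("weights must be finite")
        if not np.allclose(w, w.T, atol=1e-12):
            raise FormatError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise FormatError("diagonal must be zero")
        if w.min() < 0 or w.max() > 1:
            raise FormatError("weights must lie in [0, 1]")
        self.weights = w
        self.node_labels = tuple(self.node_labels)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def residualize_on_age(values: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Residuals of the least-squares regression of ``values`` on ``ages``
    (intercept included).  Falls back to mean-centering, with a warning, when
    all ages are identical (the slope is then undefined)."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.shape != ages.shape or values.ndim != 1:
        raise ValueError("values and ages must be 1-D and of equal length")
    if len(values) < 3:
        raise ValueError("need at least 3 observations to residualize")
    age_c = ages - ages.mean()
    denom = age_c @ age_c
    if denom == 0.0:
        warnings.warn(
            "all ages identical; falling back to mean-centering", stacklevel=2
        )
        return values - values.mean()
    slope = (age_c @ (values - values.mean())) / denom
    fitted = values.mean() + slope * age_c
    return values - fitted


def build_scn(cohort: CohortTable, group: Group) -> AdjacencyMatrix:
    """Construct the group's SCN from a cohort table.

    Each node's thicknesses across the group's eyes are residualised on age;
    the edge weight is the absolute Pearson correlation of the residuals,
    with a zero diagonal.
    """
    sub = cohort.subset(group)
    n = len(sub)
    if n < 4:
        raise ValueError(f"group {group.value} has {n} eyes; at least 4 required")
    data = sub.matrix()  # (n_eyes, 63)
    ages = sub.ages()

    age_c = ages - ages.mean()
    denom = age_c @ age_c
    centred = data - data.mean(axis=0, keepdims=True)
    if denom == 0.0:
        warnings.warn(
            "all ages identical; falling back to mean-centering", stacklevel=2
        )
        resid = centred
    else:
        slopes = (age_c @ centred) / denom
        resid = centred - np.outer(age_c, slopes)

    sd = resid.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ZeroVarianceError(
            "zero residual variance at node(s): "
            + ", ".join(NODE_LABELS[i] for i in dead)
        )

    corr = np.corrcoef(resid, rowvar=False)
    off = ~np.eye(corr.shape[0], dtype=bool)
    negative_fraction = float(np.mean(corr[off] < 0))
    weights = np.abs(corr)
    np.fill_diagonal(weights, 0.0)
    np.clip(weights, 0.0, 1.0, out=weights)
    weights = (weights + weights.T) / 2.0

    if negative_fraction >= NEGATIVE_FRACTION_WARN:
        logger.warning(
            "group %s: %.1f%% of raw correlations are negative (>= %.0f%% threshold)",
            group.value,
            100 * negative_fraction,
            100 * NEGATIVE_FRACTION_WARN,
        )
    return AdjacencyMatrix(
        weights=weights,
        node_labels=NODE_LABELS,
        group=group.value,
        n_samples=n,
        negative_fraction=negative_fraction,
    )


# ---------------------------------------------------------------------------
# Persistence: TSV matrix with labelled rows/columns + JSON metadata sidecar


def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def save_scn(matrix: AdjacencyMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        matrix.weights, index=matrix.node_labels, columns=matrix.node_labels
    )
    df.to_csv(path, sep="\t", float_format="%.17g")
    _meta_path(path).write_text(
        json.dumps(
            {
                "group": matrix.group,
                "n_samples": matrix.n_samples,
                "negative_fraction": matrix.negative_fraction,
            },
            indent=2,
        )
    )


def load_scn(path: str | Path, expect_nodes: int | None = 63) -> AdjacencyMatrix:
    """Load a persisted SCN.  ``expect_nodes=None`` enables the reduced-node
    mode used for small test fixtures."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    labels = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != labels:
        raise FormatError("row and column labels disagree")
    if expect_nodes is not None and len(labels) != expect_nodes:
        raise FormatError(f"expected {expect_nodes} nodes, found {len(labels)}")
    meta_file = _meta_path(path)
    if meta_file.exists():
        meta = json.loads(meta_file.read_text())
    else:
        meta = {"group": "NA", "n_samples": 0, "negative_fraction": 0.0}
    return AdjacencyMatrix(
        weights=df.to_numpy(dtype=float),
        node_labels=labels,
        group=str(meta["group"]),
        n_samples=int(meta["n_samples"]),
        negative_fraction=float(meta["negative_fraction"]),
    )


def load_edge_list(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a plain edge-list TSV (node_i, node_j, weight) into a dense
    symmetric adjacency; a generic-graph entry point for the community
    detection stage."""
    df = pd.read_csv(path, sep="\t", header=None, names=["i", "j", "w"])
    labels: list[str] = []
    index: dict[str, int] = {}
    for name in pd.concat([df["i"], df["j"]]).astype(str):
        if name not in index:
            index[name] = len(labels)
            labels.append(name)
    n = len(labels)
    A = np.zeros((n, n))
    for _, row in df.iterrows():
        a, b = index[str(row["i"])], index[str(row["j"])]
        A[a, b] = A[b, a] = float(row["w"])
    np.fill_diagonal(A, 0.0)
    return A, tuple(labels)
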