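"""Weighted modularity with a resolution parameter and a Louvain optimizer.

The quality function is Newman-Girvan modularity with resolution gamma on a
weighted undirected graph, in the doubled-sum convention:

    Q = (1/2m) * sum_ij ( A_ij - gamma * k_i * k_j / (2m) ) * delta(c_i, c_j)

where ``A`` is the symmetric nonnegative adjacency, ``k_i`` the node
strengths, ``2m`` the total (doubled) edge weight, and the sum runs over both
orientations of every pair, including i = j.  At gamma = 1 the all-in-one
partition scores exactly 0, so positive Q certifies community structure
beyond the strength-preserving null model.

The general multilayer form of this quality function adds an inter-layer
coupling term; with a single network per group that coupling vanishes and
the function reduces to the expression above, which is what this module
optimizes.

``louvain_run`` is a from-scratch two-phase Louvain: greedy single-node
moves to the community with the largest positive modularity gain, then graph
aggregation, repeated until no gain remains.  The node sweep order is drawn
from the run's seed, which is the algorithm's only source of randomness.
``brute_force_optimal`` enumerates every set partition (restricted-growth
strings, Bell-number many) and serves as the exact oracle on small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

#: Minimum modularity gain treated as an improvement (guards against
#: floating-point livelock on plateaus).
GAIN_TOL = 1e-12


class UndefinedModularityError(ValueError):
    """Total edge weight is zero; Q is undefined."""


@dataclass
class Partition:
    """Assignment of each node to a community id.

    Ids are canonicalized to 0..k-1 in order of first appearance, so two
    partitions with the same membership structure compare equal.
    """

    membership: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.membership)
        if m.ndim != 1:
            raise ValueError("membership must be 1-D")
        self.membership = m.astype(int)

    @classmethod
    def from_labels(cls, labels) -> "Partition":
        return cls(np.asarray(labels)).canonicalize()

    def canonicalize(self) -> "Partition":
        seen: dict[int, int] = {}
        out = np.empty_like(self.membership)
        for i, c in enumerate(self.membership):
            out[i] = seen.setdefault(int(c), len(seen))
        return Partition(out)

    @property
    def n_nodes(self) -> int:
        return len(self.membership)

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.membership))

    def communities(self) -> list[list[int]]:
        canon = self.canonicalize()
        groups: list[list[int]] = [[] for _ in range(canon.n_communities)]
        for i, c in enumerate(canon.membership):
            groups[c].append(i)
        return groups

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return np.array_equal(
            self.canonicalize().membership, other.canonicalize().membership
        )


@dataclass
class ModularityModel:
    """Adjacency plus resolution; validates the graph contract on creation."""

    A: np.ndarray
    gamma: float = 1.0
    _strengths: np.ndarray = field(init=False, repr=False)
    _two_m: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {A.shape}")
        if not np.all(np.isfinite(A)):
            raise ValueError("adjacency must be finite")
        if not np.allclose(A, A.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if A.min() < 0:
            raise ValueError("adjacency must be nonnegative")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        self.A = A
        self._strengths = A.sum(axis=1)
        self._two_m = float(A.sum())
        if self._two_m <= 0:
            raise UndefinedModularityError("total edge weight is zero")

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def strengths(self) -> np.ndarray:
        return self._strengths

    @property
    def two_m(self) -> float:
        return self._two_m


def modularity(model: ModularityModel, partition: Partition) -> float:
    """Evaluate Q for a partition (doubled-sum convention)."""
    if partition.n_nodes != model.n_nodes:
        raise ValueError(
            f"partition covers {partition.n_nodes} nodes, graph has {model.n_nodes}"
        )
    return _modularity_raw(
        model.A, model.strengths, model.two_m, model.gamma, partition.membership
    )


def _modularity_raw(
    A: np.ndarray, k: np.ndarray, two_m: float, gamma: float, membership: np.ndarray
) -> float:
    q = 0.0
    for c in np.unique(membership):
        idx = membership == c
        q += A[np.ix_(idx, idx)].sum() - gamma * k[idx].sum() ** 2 / two_m
    return q / two_m


def _one_level(
    A: np.ndarray, two_m: float, gamma: float, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """One Louvain phase of local moves on a (possibly aggregated) graph.

    ``A`` may carry self-loops from aggregation; they follow their node and
    cancel out of every gain comparison.  ``two_m`` is the total weight of
    the original graph (invariant under aggregation).  Returns the membership
    and whether any move improved Q.
    """
    n = A.shape[0]
    k = A.sum(axis=1)
    comm = np.arange(n)
    sigma_tot = k.copy()  # total strength per community
    improved_any = False

    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            ci = comm[i]
            # take i out of its community
            sigma_tot[ci] -= k[i]
            # strength from i to every community (excluding the self-loop,
            # which moves with i and cancels from all comparisons)
            w_i = A[i].copy()
            w_i[i] = 0.0
            links = np.bincount(comm, weights=w_i, minlength=n)
            gains = links - gamma * k[i] * sigma_tot[:n] / two_m
            best = int(np.argmax(gains))
            if gains[best] > gains[ci] + GAIN_TOL:
                comm[i] = best
                sigma_tot[best] += k[i]
                improved = True
                improved_any = True
            else:
                comm[i] = ci
                sigma_tot[ci] += k[i]
    return comm, improved_any


def _aggregate(A: np.ndarray, membership: np.ndarray) -> np.ndarray:
    """Collapse communities to super-nodes; internal weight becomes a
    self-loop (keeping the doubled-sum bookkeeping exact)."""
    ids = np.unique(membership)
    remap = {c: i for i, c in enumerate(ids)}
    S = np.zeros((A.shape[0], len(ids)))
    for i, c in enumerate(membership):
        S[i, remap[c]] = 1.0
    return S.T @ A @ S


def louvain_run(model: ModularityModel, seed: int) -> tuple[Partition, float]:
    """One seeded Louvain optimization; returns the partition and its Q
    (recomputed from scratch on the original graph)."""
    rng = np.random.default_rng(seed)
    A = model.A
    mapping = np.arange(model.n_nodes)
    while True:
        level_comm, improved = _one_level(A, model.two_m, model.gamma, rng)
        if not improved:
            break
        mapping = level_comm[mapping]
        A = _aggregate(A, level_comm)
        # relabel mapping to the aggregated node ids
        ids = np.unique(level_comm)
        remap = {c: i for i, c in enumerate(ids)}
        mapping = np.array([remap[c] for c in mapping])
        if A.shape[0] == 1:
            break
    partition = Partition(mapping).canonicalize()
    return partition, modularity(model, partition)


def _set_partitions(n: int) -> Iterator[np.ndarray]:
    """All set partitions of n items as restricted-growth strings."""
    a = np.zeros(n, dtype=int)
    b = np.zeros(n, dtype=int)  # b[i] = max(a[:i+1])
    yield a.copy()
    while True:
        # find rightmost position that can be incremented
        i = n - 1
        while i > 0 and a[i] == b[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        a[i] += 1
        b[i] = max(b[i - 1], a[i])
        for j in range(i + 1, n):
            a[j] = 0
            b[j] = b[i]
        yield a.copy()


def brute_force_optimal(
    model: ModularityModel, max_nodes: int = 10
) -> tuple[Partition, float]:
    """Exact maximum-modularity partition by exhaustive enumeration.

    Bell-number growth restricts this to small graphs; it is the oracle the
    heuristic optimizer is validated against.
    """
    n = model.n_nodes
    if n > max_nodes:
        raise ValueError(f"brute force limited to {max_nodes} nodes, got {n}")
    best_q = -np.inf
    best: np.ndarray | None = None
    A, k, two_m, gamma = model.A, model.strengths, model.two_m, model.gamma
    for membership in _set_partitions(n):
        q = _modularity_raw(A, k, two_m, gamma, membership)
        if q > best_q:
            best_q = q
            best = membership.copy()
    assert best is not None
    return Partition(best).canonicalize(), float(best_q)


def save_partition(
    partition: Partition, node_labels, path
) -> None:
    """Two-column TSV: node_label, community_id."""
    import pandas as pd

    pd.DataFrame(
        {"node": list(node_labels), "community": partition.canonicalize().membership}
    ).to_csv(path, sep="\t", index=False)
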