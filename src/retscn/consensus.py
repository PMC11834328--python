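"""Louvain run ensembles, consensus partitions and the group Q comparison.

Community ids returned by a stochastic optimizer are arbitrary labels, so a
per-node majority vote ("mode of Ci") is only well-defined after the runs
are label-aligned.  Each run is aligned to the highest-Q run by optimal
matching on the community contingency table (Hungarian assignment); the
consensus assignment is then the per-node mode of the aligned labels, with
ties broken toward the best run's label.  The ensemble's modularity is the
arithmetic mean of the run-level Q values, and two groups' ensembles are
compared with a two-sample t-test on those run-level Q samples (Welch by
default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .modularity import ModularityModel, Partition, louvain_run

DEFAULT_N_RUNS = 50


@dataclass
class EnsembleResult:
    """Per-run partitions and Q values plus their consensus summary."""

    runs: list[tuple[Partition, float]]
    consensus: Partition
    mean_q: float
    group: str
    seed: int

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def q_values(self) -> np.ndarray:
        return np.array([q for _, q in self.runs])


@dataclass
class ModularityComparison:
    t_statistic: float
    p_value: float
    mean_q_a: float
    mean_q_b: float
    n_runs_a: int
    n_runs_b: int
    variant: str = "welch"


def contingency(reference: Partition, other: Partition) -> np.ndarray:
    """Community-overlap counts; rows index reference ids, columns other ids."""
    ref = reference.canonicalize().membership
    oth = other.canonicalize().membership
    table = np.zeros((ref.max() + 1, oth.max() + 1), dtype=int)
    np.add.at(table, (ref, oth), 1)
    return table


def align_partitions(reference: Partition, other: Partition) -> Partition:
    """Relabel ``other``'s communities to maximize node overlap with
    ``reference``; membership structure is unchanged.

    Matching is the optimal assignment on the contingency table; other-
    communities left unmatched (or matched with zero overlap) receive fresh
    labels beyond the reference's range.
    """
    if reference.n_nodes != other.n_nodes:
        raise ValueError(
            f"partitions cover different node counts "
            f"({reference.n_nodes} vs {other.n_nodes})"
        )
    table = contingency(reference, other)
    n_ref, n_oth = table.shape
    size = max(n_ref, n_oth)
    padded = np.zeros((size, size), dtype=int)
    padded[:n_ref, :n_oth] = table
    rows, cols = linear_sum_assignment(-padded)

    mapping = np.full(n_oth, -1, dtype=int)
    for r, c in zip(rows, cols):
        if c < n_oth and r < n_ref and padded[r, c] > 0:
            mapping[c] = r
    fresh = n_ref
    for c in range(n_oth):
        if mapping[c] == -1:
            mapping[c] = fresh
            fresh += 1
    return Partition(mapping[other.canonicalize().membership])


def consensus_partition(
    runs: list[Partition], qualities: np.ndarray
) -> Partition:
    """Per-node mode of label-aligned run assignments.

    All runs are aligned to the highest-Q run; ties in the per-node vote go
    to that run's label (and to the smallest label if it is not among the
    tied maxima).
    """
    if not runs:
        raise ValueError("empty run set")
    best_idx = int(np.argmax(qualities))
    reference = runs[best_idx].canonicalize()
    aligned = np.stack(
        [align_partitions(reference, p).membership for p in runs]
    )  # (n_runs, n_nodes)
    n_nodes = aligned.shape[1]
    n_labels = int(aligned.max()) + 1
    consensus = np.empty(n_nodes, dtype=int)
    for node in range(n_nodes):
        counts = np.bincount(aligned[:, node], minlength=n_labels)
        winners = np.flatnonzero(counts == counts.max())
        ref_label = reference.membership[node]
        consensus[node] = ref_label if ref_label in winners else winners[0]
    return Partition(consensus).canonicalize()


def run_ensemble(
    model: ModularityModel,
    n_runs: int = DEFAULT_N_RUNS,
    seed: int = 0,
    group: str = "NA",
) -> EnsembleResult:
    """Run ``n_runs`` seeded Louvain optimizations and summarise them."""
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    run_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_runs)
    runs = [louvain_run(model, int(s)) for s in run_seeds]
    qualities = np.array([q for _, q in runs])
    consensus = consensus_partition([p for p, _ in runs], qualities)
    return EnsembleResult(
        runs=runs,
        consensus=consensus,
        mean_q=float(qualities.mean()),
        group=group,
        seed=seed,
    )


def compare_modularity(
    ensemble_a: EnsembleResult,
    ensemble_b: EnsembleResult,
    variant: str = "welch",
) -> ModularityComparison:
    """Two-sample t-test on the two ensembles' run-level Q values.

    The run-level Q samples are the test's inputs; note they quantify
    optimizer restart variability around each group's network, not sampling
    variability of the cohorts.
    """
    qa, qb = ensemble_a.q_values, ensemble_b.q_values
    if len(qa) == 0 or len(qb) == 0:
        raise ValueError("ensembles must be nonempty")
    if len(qa) == 1 and len(qb) == 1:
        raise ValueError("both ensembles have a single run; no degrees of freedom")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if qa.std() == 0 and qb.std() == 0 and qa.mean() == qb.mean():
        t, p = 0.0, 1.0
    else:
        with warnings.catch_warnings():
            # restart Q values are often numerically near-identical; the
            # resulting precision-loss warning is expected, not actionable
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(qa, qb, equal_var=(variant == "pooled"))
        t, p = float(t), float(p)
        if np.isnan(t):  # identical constants handled above; remaining NaNs
            t, p = 0.0, 1.0  # arise from zero variance at equal means
    return ModularityComparison(
        t_statistic=t,
        p_value=p,
        mean_q_a=ensemble_a.mean_q,
        mean_q_b=ensemble_b.mean_q,
        n_runs_a=len(qa),
        n_runs_b=len(qb),
        variant=variant,
    )
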