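"""One-command orchestration of the full analysis.

Stage order: cohort (simulated or loaded) -> per-group structural covariance
network -> per-group Louvain ensemble (50 runs, gamma 1 by default) ->
between-group modularity comparison -> trajectory and group-mean reports.
Every intermediate artifact is persisted, and every number in the run report
is recomputable from those artifacts.  All randomness flows from one master
seed through named substreams (one per stage and group), so any stage can be
reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__
from .cohort import (
    DEFAULT_COMPOSITE_SCHEME,
    CohortTable,
    Group,
    Layer,
    load_cohort,
    save_cohort,
)
from .consensus import DEFAULT_N_RUNS, compare_modularity, run_ensemble
from .modularity import ModularityModel, save_partition
from .scn import build_scn, save_scn
from .synthetic import GeneratorConfig, default_config, generate_cohort
from .trajectories import group_means_report, trajectory_report

logger = logging.getLogger(__name__)

#: Stable offsets added to the master seed, one per random substream.
_SUBSTREAMS = {"generator": 0, "ensemble_hc": 1, "ensemble_dwor": 2}


def _substream_seed(master_seed: int, name: str) -> int:
    return int(
        np.random.SeedSequence([master_seed, _SUBSTREAMS[name]]).generate_state(1)[0]
        % (2**31 - 1)
    )


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; defaults match the study
    settings (gamma 1, 50 Louvain runs per group)."""

    input_path: str | None = None  # None -> simulate
    generator: GeneratorConfig | None = None
    gamma: float = 1.0
    n_runs: int = DEFAULT_N_RUNS
    seed: int = 0
    composite_scheme: Mapping | None = None
    t_test_variant: str = "welch"
    out_dir: str | Path = "retscn_out"


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    mean_q: dict[str, float]
    consensus_communities: dict[str, int]
    t_statistic: float
    p_value: float
    negative_fraction: dict[str, float]
    n_eyes: dict[str, int]
    trajectory_rows: int
    trajectory_q_lt_05: int
    gamma: float
    n_runs: int
    seed: int
    version: str = __version__
    composite_scheme: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _resolve_cohort(config: RunConfig, out: Path) -> CohortTable:
    if config.input_path is not None:
        logger.info("loading cohort from %s", config.input_path)
        return load_cohort(config.input_path)
    gen = config.generator or default_config()
    gen = dataclasses.replace(gen, seed=_substream_seed(config.seed, "generator"))
    logger.info("simulating cohort (generator seed %d)", gen.seed)
    table, truth = generate_cohort(gen)
    save_cohort(table, out / "cohort.csv")
    truth.to_json(out / "truth.json")
    return table


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage and persist all artifacts under ``out_dir``."""
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    scheme = (
        dict(config.composite_scheme)
        if config.composite_scheme is not None
        else DEFAULT_COMPOSITE_SCHEME
    )

    try:
        cohort = _resolve_cohort(config, out)
    except Exception as exc:
        raise RuntimeError(f"cohort stage failed: {exc}") from exc

    ensembles = {}
    networks = {}
    for group, stream in ((Group.HC, "ensemble_hc"), (Group.DWOR, "ensemble_dwor")):
        try:
            net = build_scn(cohort, group)
        except Exception as exc:
            raise RuntimeError(f"SCN stage failed for {group.value}: {exc}") from exc
        networks[group] = net
        save_scn(net, out / f"scn_{group.value}.tsv")
        model = ModularityModel(net.weights, gamma=config.gamma)
        ens = run_ensemble(
            model,
            n_runs=config.n_runs,
            seed=_substream_seed(config.seed, stream),
            group=group.value,
        )
        ensembles[group] = ens
        save_partition(ens.consensus, net.node_labels, out / f"consensus_{group.value}.tsv")
        np.savetxt(
            out / f"q_runs_{group.value}.tsv",
            ens.q_values,
            fmt="%.17g",
            header="Q",
            comments="",
        )
        logger.info(
            "group %s: mean Q = %.4f over %d runs, %d consensus communities",
            group.value,
            ens.mean_q,
            ens.n_runs,
            ens.consensus.n_communities,
        )

    try:
        comparison = compare_modularity(
            ensembles[Group.HC], ensembles[Group.DWOR], variant=config.t_test_variant
        )
    except Exception as exc:
        raise RuntimeError(f"comparison stage failed: {exc}") from exc
    (out / "comparison.json").write_text(
        json.dumps(
            {
                "t": comparison.t_statistic,
                "p": comparison.p_value,
                "meanQ_hc": comparison.mean_q_a,
                "meanQ_dwor": comparison.mean_q_b,
                "n_runs": config.n_runs,
                "seed": config.seed,
                "gamma": config.gamma,
            },
            indent=2,
        )
    )

    try:
        traj = trajectory_report(cohort, scheme=scheme)
        means = group_means_report(
            cohort, scheme=scheme, variant=config.t_test_variant
        )
    except Exception as exc:
        raise RuntimeError(f"trajectory stage failed: {exc}") from exc
    traj.to_csv(out / "trajectories.tsv", sep="\t", index=False)
    means.to_csv(out / "group_means.tsv", sep="\t", index=False)

    report = RunReport(
        mean_q={g.value: ensembles[g].mean_q for g in ensembles},
        consensus_communities={
            g.value: ensembles[g].consensus.n_communities for g in ensembles
        },
        t_statistic=comparison.t_statistic,
        p_value=comparison.p_value,
        negative_fraction={g.value: networks[g].negative_fraction for g in networks},
        n_eyes={g.value: len(cohort.subset(g)) for g in Group},
        trajectory_rows=len(traj),
        trajectory_q_lt_05=int((traj["q"] < 0.05).sum()),
        gamma=config.gamma,
        n_runs=config.n_runs,
        seed=config.seed,
        composite_scheme={
            k.value: [l.value for l in v] for k, v in scheme.items()
        },
    )
    report.to_json(out / "report.json")
    logger.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    return report
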