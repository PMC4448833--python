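"""End-to-end study pipeline: filters -> networks -> metrics -> nulls ->
communities -> overlap -> report.

Stages run in a fixed order with per-stage derived seeds, writing every
intermediate (filtered table, networks, partitions, test results) plus a
consolidated JSON report whose tables mirror the study layout: one
metrics/group-size row per network, one permutation-test block per
network, and a symmetric community-overlap matrix.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import communities as comm
from . import metrics as met
from . import null_models as nm
from . import stats_tests as st
from .association import ActivityNetwork, build_activity_network, write_edgelist, write_graphml
from .sightings import (
    ALL,
    Activity,
    filter_dependent_calves,
    filter_resights,
    read_registry,
    read_sightings,
    summarize_sampling,
    write_sightings,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StudyReport", "run_pipeline", "activity_for_label"]

#: Network labels in report order; "overall" pools every sighting.
DEFAULT_NETWORKS = ("overall", "socialize", "travel", "forage")


def activity_for_label(label: str) -> str:
    """Map a network label to the activity selector ('overall' -> all)."""
    if label == "overall":
        return ALL
    try:
        Activity(label)
    except ValueError:
        raise ValueError(f"unknown activity name {label!r}") from None
    return label


@dataclass(frozen=True)
class PipelineConfig:
    sightings_path: str = "sightings.csv"
    registry_path: str = "registry.csv"
    out_dir: str = "podnet_run"
    networks: tuple[str, ...] = DEFAULT_NETWORKS
    # Per-network pruning thresholds: 3 for activity networks; 1 for the
    # overall network, which by convention retains every individual.
    min_sightings: Mapping[str, int] = field(
        default_factory=lambda: {"overall": 1, "socialize": 3, "travel": 3, "forage": 3}
    )
    n_permutations: int = 200_000
    swaps_per_step: int = 1
    burn_in: int = 1000  # cumulative scheme only
    permutation_scheme: str = "serial"
    n_random: int = 10_000
    swaps_per_edge: int = 1
    randomization_metrics: tuple[str, ...] = nm.NULL_METRICS
    walk_length: int = 4
    vi_log_base: str = "2"
    vi_vertex_handling: str = "union_singletons"
    alpha_permutation: float = 0.05
    alpha_randomization: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        for label in self.networks:
            activity_for_label(label)
            if label not in self.min_sightings:
                raise ValueError(f"no min_sightings threshold for network {label!r}")
        for n in (self.n_permutations, self.n_random, self.walk_length):
            if n < 1:
                raise ValueError("counts must be >= 1")

    @classmethod
    def from_yaml(cls, path: "str | Path", **overrides) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        for key in ("networks", "randomization_metrics"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def as_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["networks"] = list(self.networks)
        out["randomization_metrics"] = list(self.randomization_metrics)
        out["min_sightings"] = dict(self.min_sightings)
        return out


def _derived_seed(base: int, stage: str, label: str = "") -> int:
    """Stable per-stage seed below 2**31."""
    digest = np.random.SeedSequence(
        [base] + [ord(c) for c in f"{stage}/{label}"]
    ).generate_state(1)[0]
    return int(digest) & 0x7FFFFFFF


@dataclass(frozen=True)
class StudyReport:
    config: dict
    derived_seeds: dict
    sampling_summary: dict
    networks: dict  # label -> {metrics, group_sizes, partition, permutation, randomization}
    overlap_matrix: dict  # label -> label -> VI
    group_size_tests: list

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: "str | Path") -> None:
        with Path(path).open("w") as fh:
            json.dump(self.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute every stage and write all artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds: dict[str, int] = {}

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    table = stage("read_sightings", read_sightings, config.sightings_path)
    registry = stage("read_registry", read_registry, config.registry_path)
    table = stage("filter_calves", filter_dependent_calves, table, registry)
    table = stage("filter_resights", filter_resights, table)
    write_sightings(table, out / "filtered_sightings.csv")
    summary = stage("summarize_sampling", summarize_sampling, table)

    networks: dict[str, dict] = {}
    partitions: dict[str, comm.Partition] = {}
    for label in config.networks:
        activity = activity_for_label(label)
        threshold = config.min_sightings[label]
        net = stage(
            f"build[{label}]", build_activity_network, table, activity, threshold
        )
        write_graphml(net, out / f"network_{label}.graphml")
        write_edgelist(net, out / f"network_{label}.csv")

        metrics = stage(f"metrics[{label}]", met.network_metrics, net)
        sizes = stage(f"group_sizes[{label}]", met.group_size_stats, table, activity)

        perm_seed = _derived_seed(config.seed, "permtest", label)
        seeds[f"permtest/{label}"] = perm_seed
        perm = stage(
            f"permtest[{label}]",
            nm.permute_group_memberships,
            table,
            activity=activity,
            min_sightings=threshold,
            n_permutations=config.n_permutations,
            swaps_per_step=config.swaps_per_step,
            burn_in=config.burn_in,
            scheme=config.permutation_scheme,
            seed=perm_seed,
        )

        rand_seed = _derived_seed(config.seed, "randtest", label)
        seeds[f"randtest/{label}"] = rand_seed
        rand = stage(
            f"randtest[{label}]",
            nm.edge_rearrangement_null,
            net,
            metrics=config.randomization_metrics,
            n_random=config.n_random,
            swaps_per_edge=config.swaps_per_edge,
            seed=rand_seed,
            significance_level=config.alpha_randomization,
        )

        partition = stage(
            f"communities[{label}]", comm.walktrap_partition, net, config.walk_length
        )
        partitions[label] = partition
        comm.write_partition(partition, out / f"communities_{label}.csv")

        networks[label] = {
            "activity": net.activity,
            "min_sightings_threshold": threshold,
            "n_sightings": net.n_sightings_used,
            "metrics": metrics.as_dict(),
            "group_sizes": {"mean": sizes.mean, "sd": sizes.sd, "n": len(sizes.sizes)},
            "partition": {
                "n_communities": partition.n_communities,
                "average_community_size": partition.average_community_size,
                "modularity": partition.modularity,
                "walk_length": partition.walk_length,
            },
            "permutation_test": perm.as_dict(),
            "randomization_tests": [r.as_dict() for r in rand],
        }
        with (out / f"permtest_{label}.json").open("w") as fh:
            json.dump(perm.as_dict(), fh, indent=2, sort_keys=True)
        with (out / f"randtest_{label}.json").open("w") as fh:
            json.dump([r.as_dict() for r in rand], fh, indent=2, sort_keys=True)

    base = "e" if config.vi_log_base == "e" else 2
    overlap: dict[str, dict[str, float]] = {a: {} for a in config.networks}
    for a in config.networks:
        for b in config.networks:
            if a == b:
                overlap[a][b] = 0.0
            elif b in overlap and a in overlap[b]:
                overlap[a][b] = overlap[b][a]
            else:
                res = stage(
                    f"overlap[{a},{b}]",
                    comm.variation_of_information,
                    partitions[a],
                    partitions[b],
                    log_base=base,
                    vertex_handling=config.vi_vertex_handling,
                )
                overlap[a][b] = res.vi

    tests = []
    labels = list(config.networks)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            res = stage(
                f"mannwhitney[{a},{b}]",
                st.mann_whitney_group_sizes,
                table,
                activity_for_label(a),
                activity_for_label(b),
            )
            tests.append(res.as_dict())

    report = StudyReport(
        config=config.as_dict(),
        derived_seeds=seeds,
        sampling_summary=dataclasses.asdict(summary),
        networks=networks,
        overlap_matrix=overlap,
        group_size_tests=tests,
    )
    report.to_json(out / "report.json")
    _write_metrics_csv(report, out / "network_metrics.csv")
    _write_overlap_csv(report, out / "overlap_matrix.csv")
    return report


def _write_metrics_csv(report: StudyReport, path: Path) -> None:
    """One row per network, mirroring the study's summary-table column order."""
    import csv

    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "network", "n_sightings", "n_vertices", "n_edges",
                "group_size_mean", "group_size_sd",
                "average_degree", "average_strength", "average_edge_weight",
                "n_connected_components", "average_clustering",
                "n_communities", "average_community_size",
            ]
        )
        for label, block in report.networks.items():
            m = block["metrics"]
            writer.writerow(
                [
                    label, block["n_sightings"], m["n_vertices"], m["n_edges"],
                    round(block["group_sizes"]["mean"], 3),
                    round(block["group_sizes"]["sd"], 3),
                    round(m["average_degree"], 3),
                    round(m["average_strength"], 3),
                    round(m["average_edge_weight"], 3),
                    m["n_connected_components"],
                    round(m["average_clustering"], 3),
                    block["partition"]["n_communities"],
                    round(block["partition"]["average_community_size"], 3),
                ]
            )


def _write_overlap_csv(report: StudyReport, path: Path) -> None:
    import csv

    labels = list(report.overlap_matrix)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["network"] + labels)
        for a in labels:
            writer.writerow([a] + [round(report.overlap_matrix[a][b], 3) for b in labels])
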