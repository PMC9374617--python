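"""End-to-end analysis workflow: tests, graphs, metrics, communities, report.

:func:`run_analysis` orchestrates the full pipeline on one events-by-units
table: per-condition significance tests against all other conditions,
bipartite occurrence/specificity graphs with community structure, per-
condition significance networks with a density/transitivity summary table,
and blind community detection on the pooled co-occurrence network.  All
outputs are deterministic given the configuration seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .event_table import (
    EventTable,
    filter_units,
    read_event_table,
    subset_by_condition,
    write_event_table,
)
from .networks import (
    build_bipartite_graph,
    build_cooccurrence_graph,
    build_significance_graph,
    detect_communities,
    export_graph,
    graph_metrics,
    metrics_table,
)
from .probability import specificity, unconditional_probabilities
from .resampling import results_to_frame, test_between_conditions

__all__ = ["RunConfig", "run_analysis"]


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    input: str | None = None  # wide CSV; None = packaged synthetic demo data
    out_dir: str = "aunet_out"
    iterations: int = 1000
    seed: int = 1
    alpha: float = 0.01
    max_order: int = 2
    min_probability: float = 0.3  # conditional-graph edge threshold (strict >)
    min_count: int = 3  # conditional-graph minimum joint count
    min_unit_count: int = 2  # rarity filter: units occurring fewer times are dropped
    drop_units: tuple[str, ...] = ()
    cluster_by: str | None = None
    strata_by: str | None = None
    formats: tuple[str, ...] = ("graphml", "csv")

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.iterations < 100:
            warnings.warn(
                f"iterations={self.iterations} gives p-value resolution "
                f"{1 / self.iterations:.2g}; at least 100 is recommended",
                stacklevel=2,
            )

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("drop_units", "formats"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_analysis(config: RunConfig, table: EventTable | None = None) -> dict:
    """Run the full workflow and write the report bundle to ``out_dir``.

    Outputs: filtered input table, per-condition test-result CSVs, bipartite
    occurrence and specificity graphs (with community partition of the
    specificity graph), per-condition significance graphs, a metrics table
    (nodes / edges / density / transitivity per condition), the pooled
    co-occurrence graph with its community partition, a JSON summary, and a
    log recording seed and package versions.  Returns the summary dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("load"):
        if table is None:
            if config.input is None:
                from .synthetic import ck_like_spec, generate_dataset

                table = generate_dataset(ck_like_spec(seed=config.seed))
            else:
                table = read_event_table(config.input)
        if table.condition is None or len(table.conditions()) < 2:
            raise ValueError("input table must carry at least two condition labels")

    with _stage("filter"):
        table, filter_report = filter_units(
            table, min_count=config.min_unit_count, drop=config.drop_units
        )
        write_event_table(table, out / "events_filtered.csv")

    conds = table.conditions()
    with _stage("between-condition tests"):
        tests = {}
        for idx, cond in enumerate(conds):
            tests[cond] = test_between_conditions(
                subset_by_condition(table, cond),
                subset_by_condition(table, cond, complement=True),
                max_order=config.max_order,
                iterations=config.iterations,
                seed=config.seed + idx,
                cluster_by=config.cluster_by,
                strata_by=config.strata_by,
            )
            results_to_frame(tests[cond]).to_csv(
                out / f"tests_{cond}.csv", index=False
            )

    with _stage("bipartite graphs"):
        spec_table = specificity(table)
        spec_table.to_frame().to_csv(out / "specificity.csv", index=False)
        bip_occ = build_bipartite_graph(spec_table, tests, "occurrence", config.alpha)
        bip_spec = build_bipartite_graph(spec_table, tests, "specificity", config.alpha)
        for fmt in config.formats:
            export_graph(bip_occ, fmt, str(out / f"bipartite_occurrence.{fmt}"))
            export_graph(bip_spec, fmt, str(out / f"bipartite_specificity.{fmt}"))
        bip_part = detect_communities(bip_spec, weighted=True)

    with _stage("significance graphs"):
        sig_metrics = {}
        for cond in conds:
            g = build_significance_graph(tests[cond], alpha=config.alpha)
            sig_metrics[cond] = graph_metrics(g)
            for fmt in config.formats:
                export_graph(g, fmt, str(out / f"significance_{cond}.{fmt}"))
        mt = metrics_table(sig_metrics)
        mt.to_csv(out / "metrics.csv", index=False)

    with _stage("pooled communities"):
        probs = unconditional_probabilities(table, max_order=2, observed_only=True)
        pooled = build_cooccurrence_graph(probs)
        for fmt in config.formats:
            export_graph(pooled, fmt, str(out / f"cooccurrence_pooled.{fmt}"))
        pooled_part = detect_communities(pooled, weighted=True)

    with _stage("summary"):
        summary = {
            "seed": config.seed,
            "iterations": config.iterations,
            "alpha": config.alpha,
            "n_events": table.n_events,
            "n_units": table.n_units,
            "conditions": {
                c: {
                    "n_events": int(subset_by_condition(table, c).n_events),
                    **{k: round(v, 6) for k, v in sig_metrics[c].to_row().items()},
                    "n_significant_units": sum(
                        1 for r in tests[c] if len(r.element) == 1 and r.p_increase <= config.alpha
                    ),
                }
                for c in conds
            },
            "removed_units": {
                "rare": [[u, c] for u, c in filter_report.removed_rare],
                "explicit": list(filter_report.removed_explicit),
            },
            "bipartite": {
                "modularity": round(bip_part.modularity, 6),
                "n_clusters": len(bip_part.clusters()),
                "clusters": [list(cl) for cl in bip_part.clusters()],
            },
            "pooled": {
                "modularity": round(pooled_part.modularity, 6),
                "n_clusters": len(pooled_part.clusters()),
                "clusters": [list(cl) for cl in pooled_part.clusters()],
            },
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        _write_log(out / "run.log", config)

    return summary


def _write_log(path: Path, config: RunConfig) -> None:
    import networkx
    import numpy
    import pandas

    from . import __version__

    lines = [
        f"aunet {__version__}",
        f"numpy {numpy.__version__}",
        f"pandas {pandas.__version__}",
        f"networkx {networkx.__version__}",
        f"seed {config.seed}",
        f"iterations {config.iterations}",
        f"alpha {config.alpha}",
        f"max_order {config.max_order}",
        f"input {config.input or '<synthetic demo>'}",
    ]
    path.write_text("\n".join(lines) + "\n")
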