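"""End-to-end pipeline: redundancy -> clustering -> fuzzification ->
discretization -> patterns (-> rules when labels are supplied).

Every stage is a pure function of (input, config, seed); artifacts are
JSON (clustering, membership, schemes, patterns, rules) plus a
human-readable report with the cluster table, the top patterns and the
top rules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from .cluster import AttributeClusterer
from .data import MixedModeTable
from .discretize import ClusterEventTable, build_cluster_event_tables
from .fuzzify import FuzzyMembership, fuzzy_memberships
from .patterns import Pattern, discover_patterns, merge_patterns, pattern_confidences
from .rules import Rule, mine_rules

log = logging.getLogger("fuzzpat")

ARTIFACT_SCHEMA_VERSION = 1

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "render_report"]


@dataclass
class PipelineConfig:
    alpha: int = 3
    k: int | None = None
    k_min: int = 2
    k_max: int | None = None
    restarts: int = 10
    max_iter: int = 100
    f: float = 1.5
    tau: float = 0.003
    max_intervals: int = 3
    max_candidates: int | None = 256
    d_threshold: float = 1.96
    min_expected: float = 3.0
    min_order: int = 2
    max_order: int = 4
    rule_max_order: int = 3
    seed: int = 0
    class_column: str | None = None  # evaluation only

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    clusterer: AttributeClusterer
    membership: FuzzyMembership
    event_tables: list[ClusterEventTable]
    patterns: list[Pattern]
    rules: list[Rule] | None
    config: PipelineConfig


def run_pipeline(
    table: MixedModeTable,
    config: PipelineConfig | None = None,
    outdir: str | None = None,
) -> PipelineResult:
    """Run every stage on a table; write artifacts when ``outdir`` given.

    The class labels, when the table carries them, are used only after
    discretization, to mine rules and annotate pattern confidences.
    """
    cfg = config or PipelineConfig()
    log.info("pipeline start: %d samples x %d attributes, seed=%d",
             table.n_samples, table.n_attributes, cfg.seed)
    clusterer = AttributeClusterer(
        alpha=cfg.alpha, k=cfg.k, k_min=cfg.k_min, k_max=cfg.k_max,
        restarts=cfg.restarts, max_iter=cfg.max_iter, random_state=cfg.seed,
    ).fit(table)
    log.info("selected k=%d clusters, SR=%.4f, modes=%s",
             clusterer.k_, clusterer.sr_, clusterer.mode_names_)
    membership = fuzzy_memberships(clusterer.redundancy_, clusterer.clustering_, f=cfg.f)
    event_tables = build_cluster_event_tables(
        table, clusterer.clustering_, membership,
        tau=cfg.tau, max_intervals=cfg.max_intervals, max_candidates=cfg.max_candidates,
    )
    per_cluster = [
        discover_patterns(
            evt, min_order=cfg.min_order, max_order=cfg.max_order,
            d_threshold=cfg.d_threshold, min_expected=cfg.min_expected,
        )
        for evt in event_tables
    ]
    patterns = merge_patterns(per_cluster)
    log.info("discovered %d significant patterns", len(patterns))
    rules = None
    if table.class_labels is not None:
        patterns = pattern_confidences(patterns, event_tables, table.class_labels)
        rules = mine_rules(
            event_tables, table.class_labels,
            max_order=cfg.rule_max_order, d_threshold=cfg.d_threshold,
            min_expected=cfg.min_expected,
        )
        log.info("mined %d rules", len(rules))
    result = PipelineResult(clusterer, membership, event_tables, patterns, rules, cfg)
    if outdir is not None:
        write_artifacts(result, outdir)
    return result


def write_artifacts(result: PipelineResult, outdir: str) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"schema_version": ARTIFACT_SCHEMA_VERSION, "config": asdict(result.config)}

    def dump(name: str, obj) -> None:
        with open(out / name, "w") as fh:
            json.dump({**meta, "data": obj}, fh, indent=1)

    dump("redundancy.json", result.clusterer.redundancy_.to_dict())
    dump("clustering.json", result.clusterer.clustering_.to_dict())
    dump("membership.json", result.membership.to_dict())
    dump("events.json", [evt.to_dict() for evt in result.event_tables])
    dump("patterns.json", [p.to_dict() for p in result.patterns])
    if result.rules is not None:
        dump("rules.json", [r.to_dict() for r in result.rules])
    with open(out / "report.txt", "w") as fh:
        fh.write(render_report(result))


def _format_events(events) -> str:
    return " & ".join(f"{a}={lab}" for a, lab in events)


def render_report(result: PipelineResult, top: int = 10) -> str:
    """Cluster table, top patterns and top rules as plain text."""
    c = result.clusterer.clustering_
    lines = ["Attribute clusters (ranked by member MR)", ""]
    lines.append(f"{'AC':>3}  {'mode':<8}{'MR(mode)':>10}  members")
    R = result.clusterer.redundancy_.values
    for r, members in enumerate(c.clusters):
        mode = c.modes[r]
        ranked = sorted(
            members,
            key=lambda i: -sum(R[i, j] for j in members if j != i),
        )
        names = ", ".join(c.attribute_names[i] for i in ranked)
        lines.append(f"{r + 1:>3}  {c.attribute_names[mode]:<8}{c.per_cluster_mr[r]:>10.4f}  {names}")
    lines += ["", f"SR = {c.sr:.4f} at k = {c.k}", ""]

    lines += [f"Top {top} patterns (by |adjusted residual|)", ""]
    for p in result.patterns[:top]:
        conf = ""
        if p.confidences:
            conf = "  " + "  ".join(f"Conf(P->{cl})={v:.2f}" for cl, v in p.confidences)
        lines.append(
            f"  d={p.residual:+6.2f} o={p.observed:>5} e={p.expected:8.1f}  "
            f"{{{_format_events(p.events)}}} [AC{','.join(str(s + 1) for s in p.source_clusters)}]{conf}"
        )
    if result.rules is not None:
        lines += ["", f"Top {top} rules (by weight of evidence)", ""]
        for r in result.rules[:top]:
            lines.append(
                f"  WofE={r.wofe:+7.4f} conf={r.confidence:.2f} sup={r.support:>4}  "
                f"if {{{_format_events(r.antecedent)}}} then {{{r.consequent}}}"
            )
    return "\n".join(lines) + "\n"
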