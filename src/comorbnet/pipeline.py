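"""End-to-end orchestration: registry -> cohorts -> SVNs -> ego summaries.

The stages mirror the analysis workflow: parse and normalise the records,
reduce to first-diagnosis ages, build 10-year age-gender cohorts, validate
each cohort's comorbidity network, extract the focal ego networks and
write the chapter and cross-cohort summaries.  Every artifact is a plain
text file (CSV / GraphML / JSON) and all iteration orders are sorted, so
a re-run with the same inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .cohorts import build_cohorts, cohort_manifest, first_diagnosis_ages
from .ego_analysis import (
    DEFAULT_FOCAL,
    cross_cohort_presence,
    ego_network,
    summarize_by_chapter,
)
from .records_io import RecordSchema, chapter_of, parse_records
from .svn_core import ValidationConfig, build_svn

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    input_path: str | Path = ""
    output_dir: str | Path = "out"
    schema: RecordSchema = field(default_factory=RecordSchema)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    focal: str = DEFAULT_FOCAL
    ego_mode: str = "induced"
    carry_forward: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["input_path"] = str(self.input_path)
        d["output_dir"] = str(self.output_dir)
        d["validation"]["correction"] = self.validation.correction.value
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    networks: list
    egos: list
    manifest: dict


def _edge_csv(network, path: Path) -> None:
    rows = [
        {
            "code_i": u,
            "code_j": v,
            "n_cooccurrence": d["n_cooccurrence"],
            "p_value": d["p_value"],
            "rank": d["rank"],
            "threshold": d["threshold"],
        }
        for u, v, d in sorted(network.graph.edges(data=True))
    ]
    pd.DataFrame(
        rows,
        columns=["code_i", "code_j", "n_cooccurrence", "p_value", "rank", "threshold"],
    ).to_csv(path, index=False)


def _graphml(graph: nx.Graph, path: Path) -> None:
    tagged = nx.Graph()
    tagged.graph.update(graph.graph)
    for node in sorted(graph.nodes):
        attrs = dict(graph.nodes[node])
        attrs["chapter"] = chapter_of(node).label
        attrs["degree"] = graph.degree(node)
        tagged.add_node(node, **attrs)
    for u, v in sorted(graph.edges):
        tagged.add_edge(u, v, **graph.edges[u, v])
    nx.write_graphml(tagged, path)


def run_pipeline(config: PipelineConfig, stages: str = "all") -> PipelineResult:
    """Run the pipeline and write its artifact set under ``output_dir``.

    ``stages``: ``"build"`` stops after the per-cohort validated networks;
    ``"all"`` (or ``"ego"``) continues through ego extraction and the
    summary tables.  The manifest records per-stage counts; any fatal
    error propagates with its stage context.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": config.to_dict(), "stages": {}}

    events, report = parse_records(config.input_path, config.schema)
    report.to_json(outdir / "parse_report.json")
    manifest["stages"]["parse"] = report.to_dict()
    if not events:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        raise ValueError("no valid records parsed; nothing to analyse")

    first_dx = first_diagnosis_ages(events)
    cohorts = build_cohorts(first_dx, carry_forward=config.carry_forward)
    manifest["stages"]["cohorts"] = {
        "n_first_diagnoses": len(first_dx),
        "n_patients": len({fd.patient_id for fd in first_dx}),
        **cohort_manifest(cohorts),
    }
    # cohort exports: one CSV of (patient_id, icd_code) memberships per cohort
    for cohort in cohorts:
        rows = [
            {"patient_id": pid, "icd_code": code}
            for pid, history in cohort.histories.items()
            for code in sorted(history)
        ]
        name = f"cohort_{cohort.gender.value}_{cohort.decade.label}.csv"
        pd.DataFrame(rows, columns=["patient_id", "icd_code"]).to_csv(
            outdir / name, index=False
        )

    networks = []
    net_counts = []
    for cohort in cohorts:
        net = build_svn(cohort, config.validation)
        networks.append(net)
        g, d = net.cohort_key
        _edge_csv(net, outdir / f"svn_{g}_{d}.csv")
        _graphml(net.graph, outdir / f"svn_{g}_{d}.graphml")
        net_counts.append(
            {
                "gender": g,
                "decade": d,
                "n_tested_pairs": net.n_tested,
                "n_validated_edges": net.graph.number_of_edges(),
                "n_nodes": net.graph.number_of_nodes(),
            }
        )
    manifest["stages"]["svn"] = {"networks": net_counts}

    egos = []
    if stages in ("all", "ego"):
        for net in networks:
            ego = ego_network(net, config.focal, config.ego_mode)
            egos.append(ego)
            g, d = ego.cohort_key
            _edge_csv(
                type(net)(ego.cohort_key, ego.graph), outdir / f"ego_{g}_{d}.csv"
            )
            _graphml(ego.graph, outdir / f"ego_{g}_{d}.graphml")
        table = summarize_by_chapter(egos)
        table.to_dataframe().to_csv(outdir / "chapter_summary.csv", index=False)
        (outdir / "chapter_summary.json").write_text(
            json.dumps(table.to_json_dict(), indent=2, sort_keys=True) + "\n"
        )
        presence, presence_summary = cross_cohort_presence(egos)
        presence.to_csv(outdir / "ego_presence.csv")
        manifest["stages"]["ego"] = {
            "focal": config.focal,
            "mode": config.ego_mode,
            "per_cohort_members": {
                f"{g}:{d}": len(e.neighbors)
                for (g, d), e in ((e.cohort_key, e) for e in egos)
            },
            **presence_summary,
        }

    (outdir / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return PipelineResult(config, networks, egos, manifest)
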