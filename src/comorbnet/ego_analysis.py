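"""Ego networks of a focal ICD code and their chapter-level summaries.

The analysis centres on the ego network of the unruptured intracranial
aneurysm code I67.1: the focal node plus every code holding a validated
link to it in a cohort's comorbidity network.  Summaries stratify ego
members by ICD-10 chapter block (single-letter blocks, eye and ear merged
into H00-H99), decade and gender, reporting per-gender row percentages,
and tabulate which codes recur across cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import networkx as nx
import pandas as pd

from .records_io import Gender, table_block, TABLE_BLOCKS
from .svn_core import ValidatedNetwork

__all__ = [
    "EgoNetwork",
    "ChapterSummaryTable",
    "ego_network",
    "summarize_by_chapter",
    "cross_cohort_presence",
    "round_half_up",
]

DEFAULT_FOCAL = "I67.1"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 73.65 -> 73.7, not banker's 73.6)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EgoNetwork:
    """Focal code + validated neighbors in one cohort."""

    cohort_key: tuple[str, str]
    focal: str
    graph: nx.Graph

    @property
    def members(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def neighbors(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if n != self.focal)


def ego_network(
    network: ValidatedNetwork, focal: str = DEFAULT_FOCAL, mode: str = "induced"
) -> EgoNetwork:
    """Extract the ego network of *focal* from a validated network.

    Members are the focal code plus all codes adjacent to it.  ``induced``
    mode keeps every validated edge among members; ``star`` keeps only the
    edges incident to the focal code.  A focal code absent from the network
    yields the singleton ego network.
    """
    if mode not in ("induced", "star"):
        raise ValueError(f"mode must be 'induced' or 'star': {mode!r}")
    g = network.graph
    if focal not in g:
        ego = nx.Graph()
        ego.add_node(focal)
        return EgoNetwork(network.cohort_key, focal, ego)
    if mode == "induced":
        ego = nx.ego_graph(g, focal, radius=1).copy()
    else:
        ego = nx.Graph()
        ego.add_node(focal, **g.nodes[focal])
        for nbr in g.neighbors(focal):
            ego.add_node(nbr, **g.nodes[nbr])
            ego.add_edge(focal, nbr, **g.edges[focal, nbr])
    return EgoNetwork(network.cohort_key, focal, ego)


@dataclass
class ChapterSummaryTable:
    """Chapter-block counts of ego members per decade, split by gender.

    ``counts[(decade_label, gender, block)]`` is the number of non-focal
    ego members of that cohort falling in the block; percentages are
    relative to the gender's row total, rounded half-up to one decimal.
    """

    focal: str
    blocks: tuple[str, ...]
    decades: list[str] = field(default_factory=list)
    counts: dict[tuple[str, str, str], int] = field(default_factory=dict)

    def row_total(self, decade: str, gender: str) -> int:
        return sum(self.counts.get((decade, gender, b), 0) for b in self.blocks)

    def percentage(self, decade: str, gender: str, block: str) -> float | None:
        total = self.row_total(decade, gender)
        if total == 0:
            return None
        return round_half_up(100.0 * self.counts.get((decade, gender, block), 0) / total)

    def to_dataframe(self) -> pd.DataFrame:
        """Wide layout: one row per decade, (block, gender) count columns
        plus matching percentage columns and per-gender totals."""
        rows = []
        for dec in self.decades:
            row: dict[str, object] = {"decade": dec}
            for block in self.blocks:
                for g in (Gender.M.value, Gender.W.value):
                    row[f"{block}_{g}"] = self.counts.get((dec, g, block), 0)
                    pct = self.percentage(dec, g, block)
                    row[f"{block}_{g}_pct"] = pct if pct is not None else ""
            row["total_M"] = self.row_total(dec, Gender.M.value)
            row["total_W"] = self.row_total(dec, Gender.W.value)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        out: dict = {"focal": self.focal, "rows": []}
        for dec in self.decades:
            cells = {}
            for block in self.blocks:
                for g in (Gender.M.value, Gender.W.value):
                    cells[f"{block}|{g}"] = {
                        "count": self.counts.get((dec, g, block), 0),
                        "pct": self.percentage(dec, g, block),
                    }
            out["rows"].append(
                {
                    "decade": dec,
                    "cells": cells,
                    "total_M": self.row_total(dec, Gender.M.value),
                    "total_W": self.row_total(dec, Gender.W.value),
                }
            )
        return out


_SUMMARY_BLOCKS = TABLE_BLOCKS + ("other",)


def summarize_by_chapter(egos: Iterable[EgoNetwork]) -> ChapterSummaryTable:
    """Tabulate non-focal ego members per (decade, gender, chapter block).

    All egos must share the focal code.  Blocks are the single-letter
    ranges E, F, G, H (merged), I, J, M, Q, R, Z plus ``other``; per-gender
    row percentages are computed from the gender's own row total.
    """
    egos = list(egos)
    focals = {e.focal for e in egos}
    if len(focals) > 1:
        raise ValueError(f"mixed focal codes: {sorted(focals)}")
    focal = focals.pop() if focals else DEFAULT_FOCAL
    table = ChapterSummaryTable(focal=focal, blocks=_SUMMARY_BLOCKS)
    decade_order: dict[str, int] = {}
    for e in egos:
        gender, decade = e.cohort_key
        decade_order.setdefault(decade, int(decade.split("-")[0]))
        for code in e.neighbors:
            key = (decade, gender, table_block(code))
            table.counts[key] = table.counts.get(key, 0) + 1
    table.decades = sorted(decade_order, key=decade_order.get)
    return table


def cross_cohort_presence(
    egos: Iterable[EgoNetwork],
) -> tuple[pd.DataFrame, dict]:
    """Presence matrix (code x cohort) of validated ego neighbors.

    Returns a boolean DataFrame (rows: every distinct non-focal code ever
    validated; columns: ``gender:decade``) and a summary dict with distinct
    counts per gender, the pooled distinct count, and the total number of
    code-cohort incidences (multiplicity).
    """
    egos = list(egos)
    focals = {e.focal for e in egos}
    if len(focals) > 1:
        raise ValueError(f"mixed focal codes: {sorted(focals)}")
    cols = [f"{g}:{d}" for g, d in (e.cohort_key for e in egos)]
    codes = sorted(set().union(*[set(e.neighbors) for e in egos])) if egos else []
    data = {
        col: [code in set(e.neighbors) for code in codes]
        for col, e in zip(cols, egos)
    }
    matrix = pd.DataFrame(data, index=pd.Index(codes, name="icd_code"))
    per_gender = {
        g.value: len(
            set().union(
                *[set(e.neighbors) for e in egos if e.cohort_key[0] == g.value],
                set(),
            )
        )
        for g in Gender
    }
    summary = {
        "distinct_per_gender": per_gender,
        "distinct_total": len(codes),
        "multiplicity_total": int(sum(len(e.neighbors) for e in egos)),
    }
    return matrix, summary
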