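"""The gene matches graph: construction, component classes, ideal filtering.

Vertices are (sample_id, gene_id) pairs; an edge joins two vertices exactly
when their gene pair appears in the match table of their two samples.  With
``s`` samples a connected component is *small* if it has fewer than ``s``
vertices, *large* otherwise, and *ideal* if it is a clique with exactly
``s`` vertices — which forces exactly one gene per sample, since no edge
ever joins two genes of the same sample.  Genes in ideal components are the
orthology units used for multi-sample distance computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

from .exceptions import SampleMismatchError
from .matching import GeneMatchTable

__all__ = [
    "GeneMatchesGraph",
    "ComponentReport",
    "build_graph",
    "classify_components",
    "ideal_gene_pairs",
    "ideal_genes_by_sample",
    "filter_table_to_ideal",
]


@dataclass
class GeneMatchesGraph:
    """Wrapper around an undirected networkx graph of (sample, gene) vertices."""

    graph: nx.Graph
    sample_ids: list

    @property
    def num_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class ComponentReport:
    """Connected components with their small/large/ideal classification."""

    components: list = field(default_factory=list)  # (frozenset vertices, class)
    counts: dict = field(default_factory=dict)

    def to_tsv(self, path) -> Path:
        path = Path(path)
        rows = []
        for cid, (verts, cls) in enumerate(self.components):
            members = ";".join(f"{s}:{g}" for s, g in sorted(verts, key=str))
            rows.append((cid, len(verts), cls, members))
        pd.DataFrame(
            rows, columns=["component_id", "size", "class", "members"]
        ).to_csv(path, sep="\t", index=False)
        return path


def build_graph(tables: list, sample_ids: list) -> GeneMatchesGraph:
    """Build the gene matches graph from one match table per unordered pair."""
    sample_set = set(sample_ids)
    expected = {frozenset(p) for p in combinations(sample_ids, 2)}
    seen = set()
    for t in tables:
        if t.sample1_id not in sample_set or t.sample2_id not in sample_set:
            raise SampleMismatchError(
                f"table for ({t.sample1_id!r}, {t.sample2_id!r}) references a "
                f"sample outside {sorted(map(str, sample_set))}"
            )
        seen.add(frozenset((t.sample1_id, t.sample2_id)))
    missing = expected - seen
    if missing:
        pair = sorted(next(iter(missing)), key=str)
        raise SampleMismatchError(
            f"missing gene match table for sample pair {tuple(pair)!r} "
            f"({len(missing)} pair(s) missing in total)"
        )
    g = nx.Graph()
    for t in tables:
        for s1gene, s2gene in t.gene_pairs():
            u = (t.sample1_id, s1gene)
            v = (t.sample2_id, s2gene)
            g.add_edge(u, v)
    return GeneMatchesGraph(graph=g, sample_ids=list(sample_ids))


def classify_components(g: GeneMatchesGraph) -> ComponentReport:
    """Label each connected component small/large/ideal and count them.

    Completeness of a size-``s`` component is decided by edge-count equality
    (``s(s-1)/2`` edges), which is equivalent to the all-pairs adjacency
    probe because components carry no parallel edges.  ``n_large`` counts
    every component with at least ``s`` vertices, ideal ones included;
    ``n_large_nonideal`` is also reported.
    """
    s = g.num_samples
    components = []
    n_small = n_large = n_ideal = 0
    for verts in nx.connected_components(g.graph):
        size = len(verts)
        if size < s:
            cls = "small"
            n_small += 1
        else:
            cls = "large"
            n_large += 1
            if size == s:
                sub = g.graph.subgraph(verts)
                if sub.number_of_edges() == s * (s - 1) // 2:
                    cls = "ideal"
                    n_ideal += 1
        components.append((frozenset(verts), cls))
    return ComponentReport(
        components=components,
        counts={
            "n_small": n_small,
            "n_large": n_large,
            "n_ideal": n_ideal,
            "n_large_nonideal": n_large - n_ideal,
        },
    )


def ideal_gene_pairs(g: GeneMatchesGraph, report: ComponentReport | None = None) -> set:
    """All unordered vertex pairs lying together in some ideal component."""
    if report is None:
        report = classify_components(g)
    pairs = set()
    for verts, cls in report.components:
        if cls != "ideal":
            continue
        for u, v in combinations(sorted(verts, key=str), 2):
            pairs.add(frozenset((u, v)))
    return pairs


def ideal_genes_by_sample(
    g: GeneMatchesGraph, report: ComponentReport | None = None
) -> dict:
    """Map each sample to the set of its genes lying in ideal components."""
    if report is None:
        report = classify_components(g)
    out = {sid: set() for sid in g.sample_ids}
    for verts, cls in report.components:
        if cls != "ideal":
            continue
        for sample, gene in verts:
            out[sample].add(gene)
    return out


def filter_table_to_ideal(t: GeneMatchTable, pairs: set) -> GeneMatchTable:
    """Keep only match rows whose gene pair lies in an ideal component."""
    df = t.df
    if not len(df):
        return GeneMatchTable(t.sample1_id, t.sample2_id, df.copy())
    mask = [
        frozenset(((t.sample1_id, g1), (t.sample2_id, g2))) in pairs
        for g1, g2 in zip(df["s1gene"], df["s2gene"])
    ]
    return GeneMatchTable(t.sample1_id, t.sample2_id, df[mask].reset_index(drop=True))


def write_edge_list(g: GeneMatchesGraph, path) -> Path:
    path = Path(path)
    rows = [
        (u[0], u[1], v[0], v[1])
        for u, v in sorted(g.graph.edges(), key=lambda e: (str(e[0]), str(e[1])))
    ]
    pd.DataFrame(rows, columns=["sample1", "gene1", "sample2", "gene2"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def write_graphml(g: GeneMatchesGraph, path) -> Path:
    path = Path(path)
    h = nx.relabel_nodes(g.graph, {v: f"{v[0]}:{v[1]}" for v in g.graph.nodes()})
    nx.write_graphml(h, path)
    return path
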