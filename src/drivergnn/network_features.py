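"""Mutation-outlier bipartite graph and the 6 network-derived features.

The bipartite graph links a mutated gene i (left partition) to an outlying
gene j in a patient context (right partition) whenever, in the same patient,
gene i carries a mutation, gene j is a Grubbs expression outlier, and (i, j)
is an edge of the PPI network. Four per-gene features are read off the graph
(edge count, edges to cell-proliferation-related genes, CPRG membership,
patients covered); degree and betweenness centrality complete the block.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import pandas as pd

from drivergnn.features import OutlierMatrix
from drivergnn.io import MutationTable, PPIGraph


@dataclass
class BipartiteGraph:
    """Edges are (mutated gene i, outlying gene j, patient) triples."""

    edges: list[tuple[str, str, str]]

    @property
    def left_nodes(self) -> set[str]:
        return {i for i, _, _ in self.edges}

    @property
    def right_nodes(self) -> set[str]:
        return {j for _, j, _ in self.edges}


def build_bipartite(
    muts: MutationTable, om: OutlierMatrix, ppi: PPIGraph
) -> BipartiteGraph:
    """Exhaustive (mutated gene, outlying gene, patient) triple enumeration.

    The PPI graph is simple (no self-loops), so i never equals j.
    """
    patients = list(om.values.columns)
    rec = muts.records[muts.records["sample"].isin(set(patients))]
    mutated_by_patient: dict[str, set[str]] = {
        p: set(sub["gene"]) for p, sub in rec.groupby("sample")
    }
    outlier_arr = om.values.to_numpy()
    gene_index = list(om.values.index)
    edges: list[tuple[str, str, str]] = []
    for col, p in enumerate(patients):
        mutated = mutated_by_patient.get(p)
        if not mutated:
            continue
        outliers = {gene_index[r] for r in outlier_arr[:, col].nonzero()[0]}
        if not outliers:
            continue
        for i in sorted(mutated):
            hits = ppi.neighbors(i) & outliers
            for j in sorted(hits):
                edges.append((i, j, p))
    return BipartiteGraph(edges=edges)


def bipartite_features(
    bg: BipartiteGraph,
    cprg: list[str],
    tumor_samples: list[str],
    gene_ids: list[str],
) -> pd.DataFrame:
    """The 4 bipartite features per gene.

    bipartite_E: number of bipartite edges of the (mutated) gene;
    bipartite_LCPRG: edges whose right-partition gene is a CPRG;
    bipartite_CPRG: binary CPRG membership of the gene itself;
    NSC: number of distinct patients covered by the gene's edges.
    """
    cprg_set = set(cprg)
    e_count: dict[str, int] = {}
    lcprg: dict[str, int] = {}
    patients: dict[str, set[str]] = {}
    for i, j, p in bg.edges:
        e_count[i] = e_count.get(i, 0) + 1
        if j in cprg_set:
            lcprg[i] = lcprg.get(i, 0) + 1
        patients.setdefault(i, set()).add(p)
    out = pd.DataFrame(
        {
            "bipartite_E": [e_count.get(g, 0) for g in gene_ids],
            "bipartite_LCPRG": [lcprg.get(g, 0) for g in gene_ids],
            "bipartite_CPRG": [int(g in cprg_set) for g in gene_ids],
            "NSC": [len(patients.get(g, ())) for g in gene_ids],
        },
        index=gene_ids,
    )
    assert (out["bipartite_LCPRG"] <= out["bipartite_E"]).all()
    assert (out["NSC"] <= len(tumor_samples)).all()
    return out


def centrality_features(net: PPIGraph, gene_ids: list[str]) -> pd.DataFrame:
    """Degree (incident edge count) and normalized betweenness centrality.

    Betweenness is divided by (n-1)(n-2)/2, the undirected-graph pair count,
    so values lie in [0, 1]. Genes absent from the network get (0, 0).
    """
    nodes = sorted(net.graph.nodes)
    index = {g: k for k, g in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in net.graph.edges]
    g = ig.Graph(n=len(nodes), edges=edges, directed=False)
    degree = g.degree()
    btw = g.betweenness(directed=False)
    n = len(nodes)
    norm = (n - 1) * (n - 2) / 2.0 if n > 2 else 1.0
    deg_map = {gene: degree[k] for gene, k in index.items()}
    btw_map = {gene: btw[k] / norm for gene, k in index.items()}
    return pd.DataFrame(
        {
            "degree": [deg_map.get(gene, 0) for gene in gene_ids],
            "betweenness": [btw_map.get(gene, 0.0) for gene in gene_ids],
        },
        index=gene_ids,
    )
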