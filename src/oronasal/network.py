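"""Genus co-occurrence networks from thresholded Spearman correlations.

Edges connect genus pairs whose rank correlation across the samples of one
stratum satisfies |rho| >= 0.6 and p < 0.05 (two-sided, t approximation with
n-2 df). The absolute-value rule keeps negative edges, whose sign is recorded.
Genera are pre-filtered to those present in at least 20% of the stratum's
samples and with nonzero variance, which avoids all-tied rank vectors. No
multiple-testing correction is applied to edge p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable, RELATIVE, Stratum, select_samples, to_relative

__all__ = ["CorrelationNetwork", "spearman_edges", "centrality", "write_graphml"]


@dataclass
class CorrelationNetwork:
    graph: nx.Graph  # nodes = eligible genera; edge attrs rho, p, sign
    edges: pd.DataFrame  # genus_a, genus_b, rho, p, sign
    nodes: pd.DataFrame  # genus, degree, betweenness
    stratum: Stratum | None

    def write_edges(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")

    def write_nodes(self, path) -> None:
        self.nodes.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def spearman_edges(
    table: AbundanceTable,
    metadata: pd.DataFrame | None = None,
    stratum: Stratum | None = None,
    rho_min: float = 0.6,
    alpha: float = 0.05,
    prevalence_min: float = 0.2,
    signed: bool = False,
) -> CorrelationNetwork:
    """All-pairs Spearman network for one stratum (or the whole table).

    ``signed=True`` keeps only positive correlations rho >= rho_min; the
    default keeps |rho| >= rho_min and records the edge sign.
    """
    if metadata is not None and stratum is not None:
        ids = [
            s
            for s in select_samples(metadata, stratum.group, stratum.niche, stratum.age_class)
            if s in table.data.columns
        ]
    else:
        ids = table.samples
    if len(ids) < 5:
        raise ValueError(f"need >= 5 samples for a correlation network, got {len(ids)}")
    sub = table.subset_samples(ids)
    rel = sub if sub.mode == RELATIVE else to_relative(sub)
    data = rel.data
    prevalence = (data > 0).mean(axis=1)
    variance = data.var(axis=1)
    eligible = data.index[(prevalence >= prevalence_min) & (variance > 0)].tolist()

    graph = nx.Graph()
    graph.add_nodes_from(eligible)
    rows = []
    if len(eligible) == 0:
        warnings.warn("no genera pass the prevalence/variance filter; empty network")
    elif len(eligible) >= 2:
        matrix = data.loc[eligible].to_numpy()
        if len(eligible) == 2:
            rho, p = stats.spearmanr(matrix[0], matrix[1])
            rho_mat = np.array([[1.0, rho], [rho, 1.0]])
            p_mat = np.array([[0.0, p], [p, 0.0]])
        else:
            rho_mat, p_mat = stats.spearmanr(matrix, axis=1)
        for i, a in enumerate(eligible):
            for j in range(i + 1, len(eligible)):
                b = eligible[j]
                rho, p = float(rho_mat[i, j]), float(p_mat[i, j])
                strong = rho >= rho_min if signed else abs(rho) >= rho_min
                if strong and p < alpha:
                    sign = "positive" if rho >= 0 else "negative"
                    graph.add_edge(a, b, rho=rho, p=p, sign=sign)
                    rows.append({"genus_a": a, "genus_b": b, "rho": rho, "p": p, "sign": sign})
    edges = pd.DataFrame(rows, columns=["genus_a", "genus_b", "rho", "p", "sign"])
    return CorrelationNetwork(graph=graph, edges=edges, nodes=centrality(graph), stratum=stratum)


def centrality(graph: nx.Graph) -> pd.DataFrame:
    """Degree and normalized betweenness on the unweighted kept-edge graph."""
    degree = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    return pd.DataFrame(
        {
            "genus": list(graph.nodes),
            "degree": [degree[g] for g in graph.nodes],
            "betweenness": [betweenness[g] for g in graph.nodes],
        }
    )


def write_graphml(network: CorrelationNetwork, path) -> None:
    nx.write_graphml(network.graph, path)
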