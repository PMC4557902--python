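"""Multi-experiment classification and reporting.

Enrichment profiles from many experiments are reduced to a terms x
experiments z-score matrix, then classified by PCA (experiments as points
in term space) and agglomerative hierarchical clustering of the experiment
columns.  Reporting covers the z-vs-z scatter with Jaccard coloring, the
DAG neighbourhood of the top differential terms, and dendrograms with
Newick serialization.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, linkage as scipy_linkage
from scipy.spatial.distance import pdist
from skbio import TreeNode
from sklearn.decomposition import PCA

from diego.comparison import ComparisonResult
from diego.enrichment import EnrichmentProfile
from diego.ontology import OntologyGraph


@dataclass
class ZMatrix:
    """Terms (rows) x experiments (columns) z-score matrix."""

    values: pd.DataFrame
    policy: str = "intersect"

    @property
    def terms(self) -> list[str]:
        return list(self.values.index)

    @property
    def labels(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # experiments x components
    variance_explained: np.ndarray


@dataclass
class ClusterTree:
    linkage: np.ndarray  # scipy linkage matrix over experiment columns
    labels: list[str]
    metric: str = "euclidean"
    linkage_method: str = "average"

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, self.labels)
        buf = io.StringIO()
        tree.write(buf)
        return buf.getvalue().strip()


def build_z_matrix(
    profiles: Sequence[EnrichmentProfile], policy: str = "intersect"
) -> ZMatrix:
    """Assemble per-term z-scores from >= 2 profiles into one matrix.

    Under ``intersect`` only terms scoreable in every profile are kept;
    ``union_zero`` keeps every term scored anywhere, filling absences with
    z = 0.  Rows are sorted by term id; columns follow input order.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("experiment labels must be unique")
    term_sets = [p.defined_terms() for p in profiles]
    if policy == "intersect":
        terms = sorted(set.intersection(*term_sets))
        if not terms:
            raise ValueError(
                "profiles share no scoreable terms; consider policy='union_zero'"
            )
    elif policy == "union_zero":
        terms = sorted(set.union(*term_sets))
    else:
        raise ValueError(f"unknown policy {policy!r}")
    data = np.zeros((len(terms), len(profiles)))
    for j, p in enumerate(profiles):
        for i, t in enumerate(terms):
            s = p.scores.get(t)
            if s is not None and s.defined:
                data[i, j] = s.z
    return ZMatrix(
        values=pd.DataFrame(data, index=terms, columns=labels), policy=policy
    )


def pca(m: ZMatrix, n_components: int | None = None) -> PcaResult:
    """Project experiments onto the principal axes of term space.

    Each experiment is a point in term space; term rows are mean-centered
    across experiments but not variance-scaled (z-scores already share a
    scale).
    """
    x = m.values.to_numpy().T  # experiments x terms
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("PCA needs >= 2 experiments and >= 2 terms")
    if np.allclose(x.std(axis=0), 0):
        raise ValueError("zero-variance z-matrix: experiments are identical")
    k = n_components or min(x.shape[0], x.shape[1])
    k = min(k, x.shape[0], x.shape[1])
    model = PCA(n_components=k)
    coords = model.fit_transform(x)
    return PcaResult(
        coordinates=pd.DataFrame(
            coords,
            index=m.labels,
            columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
        ),
        variance_explained=model.explained_variance_ratio_,
    )


def hierarchical_cluster(
    m: ZMatrix, metric: str = "euclidean", linkage: str = "average"
) -> ClusterTree:
    """Agglomerative clustering of experiment columns.

    ``metric="correlation"`` uses 1 - Pearson correlation between columns.
    """
    x = m.values.to_numpy().T
    if x.shape[0] < 2:
        raise ValueError("need >= 2 experiments to cluster")
    dists = pdist(x, metric=metric)
    z = scipy_linkage(dists, method=linkage)
    return ClusterTree(
        linkage=z, labels=list(m.labels), metric=metric, linkage_method=linkage
    )


def parse_newick(newick: str) -> TreeNode:
    """Parse a Newick string back into a tree (round-trip check helper)."""
    return TreeNode.read(io.StringIO(newick))


def report_scatter(cmp: ComparisonResult, path: str) -> str:
    """z_i vs z_j scatter colored by Jaccard coefficient on a fixed 0-1 scale."""
    zi = np.array([r.z_i for r in cmp.records])
    zj = np.array([r.z_j for r in cmp.records])
    jc = np.array([r.jc for r in cmp.records])
    fig, ax = plt.subplots(figsize=(5.5, 5))
    sc = ax.scatter(zi, zj, c=jc, cmap="viridis", vmin=0.0, vmax=1.0, s=18)
    lims = [min(zi.min(), zj.min()) - 0.5, max(zi.max(), zj.max()) + 0.5]
    ax.plot(lims, lims, color="grey", lw=0.8, zorder=0)
    ax.set_xlabel(f"z ({cmp.labels[0]})")
    ax.set_ylabel(f"z ({cmp.labels[1]})")
    r = cmp.pearson_r
    ax.set_title(f"R = {r:.2f}, mean JC = {cmp.mean_jc:.2f}")
    fig.colorbar(sc, ax=ax, label="Jaccard coefficient")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def _dag_depths(graph: OntologyGraph, nodes: set[str]) -> dict[str, int]:
    depths = {}
    for n in nodes:
        depths[n] = len(graph.ancestors(n) & nodes)
    return depths


def report_dag(
    cmp: ComparisonResult,
    graph: OntologyGraph,
    top_k: int = 10,
    path: str = "dag.svg",
) -> tuple[str, set[str]]:
    """Render the top-|z_k| terms plus all their ancestors as a DAG.

    Scored nodes are colored by the sign of z_k with intensity by |z_k|;
    ancestor nodes outside the comparison stay neutral.  Returns the output
    path and the plotted node set.
    """
    top = cmp.records[: max(1, top_k)]
    for r in top:
        if r.term not in graph:
            raise ValueError(f"term {r.term} missing from the ontology")
    nodes: set[str] = set()
    for r in top:
        nodes.add(r.term)
        nodes |= graph.ancestors(r.term)

    zk = {r.term: r.z_k for r in cmp.records}
    zmax = max((abs(v) for v in zk.values()), default=0.0) or 1.0
    cmap = plt.get_cmap("coolwarm")
    colors = []
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for child, parent, _rel in graph.edges():
        if child in nodes and parent in nodes:
            g.add_edge(child, parent)
    ordered = sorted(nodes)
    for n in ordered:
        if n in zk:
            colors.append(cmap(0.5 + 0.5 * zk[n] / zmax))
        else:
            colors.append((0.85, 0.85, 0.85, 1.0))

    depths = _dag_depths(graph, nodes)
    for n in g.nodes:
        g.nodes[n]["layer"] = depths[n]
    pos = nx.multipartite_layout(g, subset_key="layer", align="horizontal")

    fig, ax = plt.subplots(figsize=(7, 5))
    nx.draw_networkx(
        g, pos=pos, ax=ax, nodelist=ordered, node_color=colors,
        node_size=350, font_size=6, arrows=True,
    )
    ax.set_title(f"top {len(top)} differential terms and ancestors")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path, nodes


def report_dendrogram(tree: ClusterTree, path: str) -> tuple[str, str]:
    """Plot a dendrogram and return (path, newick string)."""
    if any(not lab for lab in tree.labels):
        raise ValueError("empty experiment label")
    fig, ax = plt.subplots(figsize=(6, 4))
    dendrogram(tree.linkage, labels=tree.labels, ax=ax)
    ax.set_ylabel(f"{tree.metric} distance ({tree.linkage_method} linkage)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path, tree.to_newick()
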