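"""Non-redundant reference genome sets via Tanimoto similarity and MCL.

Reference genomes with near-identical complements of query-genome orthologs
carry redundant phylogenetic signal.  Pairs with Tanimoto similarity of their
ortholog sets above a threshold (default 0.9) are linked in a graph, the graph
is partitioned with the Markov Cluster algorithm, and one representative is
retained per cluster.
"""

from __future__ import annotations

import os
import warnings
from itertools import combinations
from typing import IO, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .orthology import OrthologTable

__all__ = [
    "tanimoto",
    "build_similarity_graph",
    "mcl_cluster",
    "select_nonredundant",
    "write_genome_sets",
    "read_genome_list",
]


def tanimoto(n_a: int, n_b: int, n_shared: int) -> float:
    """Intersection-over-union similarity of two ortholog sets.

    ``n_shared / (n_a + n_b - n_shared)`` for set sizes ``n_a``, ``n_b`` with
    ``n_shared`` members in common.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("set sizes must be >= 1")
    if n_shared < 0 or n_shared > min(n_a, n_b):
        raise ValueError(
            f"shared count {n_shared} exceeds min({n_a}, {n_b}) or is negative"
        )
    return n_shared / (n_a + n_b - n_shared)


def build_similarity_graph(table: OrthologTable, threshold: float = 0.9) -> nx.Graph:
    """Graph over reference genomes with edges where similarity >= threshold.

    Similarity between genomes A and B is the Tanimoto coefficient of the sets
    of query proteins they each hold orthologs for.  Every genome in the table
    appears as a node; genomes with no orthologs contribute no edges.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    graph = nx.Graph()
    graph.add_nodes_from(table.genomes)
    if len(table.genomes) < 2:
        return graph
    sets = {genome: table.ortholog_set(genome) for genome in table.genomes}
    for a, b in combinations(table.genomes, 2):
        n_a, n_b = len(sets[a]), len(sets[b])
        if n_a == 0 or n_b == 0:
            continue
        sim = tanimoto(n_a, n_b, len(sets[a] & sets[b]))
        if sim >= threshold:
            graph.add_edge(a, b, weight=sim)
    return graph


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> list[list[str]]:
    """Partition a weighted graph with the Markov Cluster algorithm.

    Iterates column-normalize -> expand (matrix square) -> inflate
    (elementwise power, renormalize) until the matrix changes by less than
    ``tol`` or ``max_iter`` is reached (a warning is issued and the current
    hard clustering returned).  Self-loops of weight 1 are added before
    expansion.  Returns disjoint clusters covering all nodes, each sorted,
    ordered by first member; output is invariant to node insertion order.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes)
    if not nodes:
        return []
    adj = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    np.fill_diagonal(adj, 1.0)
    matrix = adj / adj.sum(axis=0)
    converged = False
    for _ in range(max_iter):
        expanded = matrix @ matrix
        inflated = expanded**inflation
        inflated /= inflated.sum(axis=0)
        change = float(np.abs(inflated - matrix).max())
        matrix = inflated
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge within {max_iter} iterations; "
            "returning current hard clustering",
            RuntimeWarning,
        )
    # Nodes sharing support in the steady-state matrix belong together.
    support = (matrix + matrix.T) > max(tol, 1e-9)
    cluster_graph = nx.from_numpy_array(support)
    clusters = [
        sorted(nodes[i] for i in component)
        for component in nx.connected_components(cluster_graph)
    ]
    return sorted(clusters, key=lambda c: c[0])


def select_nonredundant(
    clusters: Iterable[Sequence[str]], table: OrthologTable
) -> list[str]:
    """Retain one genome per cluster: the one with the most orthologs.

    Ties break to the lexicographically smallest genome id.  Genomes of the
    table not covered by any cluster are retained as-is.  Output is sorted.
    """
    clusters = [list(c) for c in clusters]
    seen: set[str] = set()
    for cluster in clusters:
        overlap = seen & set(cluster)
        if overlap:
            raise ValueError(f"clusters are not disjoint: {sorted(overlap)}")
        seen |= set(cluster)
    counts = {genome: table.ortholog_count(genome) for genome in table.genomes}
    retained: set[str] = set(table.genomes) - seen
    for cluster in clusters:
        best = min(cluster, key=lambda g: (-counts.get(g, 0), g))
        retained.add(best)
    return sorted(retained)


def write_genome_sets(
    sets: dict[str, Sequence[str]], path: str | os.PathLike | IO[str]
) -> None:
    """Write genome sets as TSV with columns set_name, genome_id."""
    rows = [(name, genome) for name, members in sets.items() for genome in members]
    pd.DataFrame(rows, columns=["set_name", "genome_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_genome_list(path: str | os.PathLike | IO[str]) -> list[str]:
    """Read a curated genome list: one genome id per line, or the last TSV column."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return list(frame.iloc[:, -1])
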