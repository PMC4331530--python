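"""Interaction-network container, edge-list loading, and gene-class partitioning.

The network is an undirected, unweighted graph G = (V, L) over opaque,
case-sensitive gene/protein identifiers.  Nodes are partitioned relative to
two annotation sets — disease genes D and essential genes E — into the
classes used throughout the analysis:

    E- = E \\ D   (essential, not disease)
    D- = D \\ E   (disease, not essential)
    E ∩ D        (both)
    O            (network genes in neither)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "AnnotatedNetwork",
    "GenePartition",
    "EdgeListParseError",
    "ConfigurationError",
    "load_edge_list",
    "largest_component",
    "partition_genes",
]


class EdgeListParseError(ValueError):
    """A malformed line in an edge-list file; message names the line number."""


class ConfigurationError(ValueError):
    """Invalid combination of options (e.g. threshold given but no score column)."""


@dataclass(frozen=True)
class AnnotatedNetwork:
    """Undirected unweighted graph with optional disease/essential node labels.

    Parameters
    ----------
    nodes
        Ordered identifiers; index into ``adjacency``.
    adjacency
        Symmetric 0/1 CSR matrix with zero diagonal.
    labels
        Optional mapping identifier -> subset of ``{"disease", "essential"}``.
    """

    nodes: tuple[str, ...]
    adjacency: sp.csr_array
    labels: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.shape[0] != a.shape[1] or a.shape[0] != len(self.nodes):
            raise ValueError("adjacency shape does not match node list")
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(self.nodes)})

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    @property
    def node_index(self) -> dict[str, int]:
        return self._index  # type: ignore[attr-defined]

    @property
    def degrees(self) -> np.ndarray:
        """Per-node integer degree k(x) (number of distinct neighbours)."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    def __contains__(self, gene: str) -> bool:
        return gene in self.node_index

    def degree(self, gene: str) -> int:
        return int(self.degrees[self.node_index[gene]])

    def neighbors(self, gene: str) -> frozenset[str]:
        i = self.node_index[gene]
        row = self.adjacency.indices[self.adjacency.indptr[i] : self.adjacency.indptr[i + 1]]
        return frozenset(self.nodes[j] for j in row)

    def edges(self) -> set[frozenset[str]]:
        coo = self.adjacency.tocoo()
        return {
            frozenset((self.nodes[i], self.nodes[j]))
            for i, j in zip(coo.row, coo.col)
            if i < j
        }

    # -- construction ------------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Sequence[str] | None = None,
        labels: Mapping[str, Iterable[str]] | None = None,
    ) -> "AnnotatedNetwork":
        """Build from an iterable of unordered pairs; self-loops and duplicates dropped."""
        edge_list = [tuple(e) for e in edges]
        seen: dict[str, None] = {}
        for g in nodes or ():
            seen.setdefault(g)
        for a, b in edge_list:
            seen.setdefault(a)
            seen.setdefault(b)
        node_tuple = tuple(seen)
        index = {g: i for i, g in enumerate(node_tuple)}
        pairs = {
            (index[a], index[b])
            for a, b in edge_list
            if a != b
        }
        n = len(node_tuple)
        if pairs:
            rows, cols = zip(*pairs)
            data = np.ones(len(pairs), dtype=np.int8)
            adj = sp.coo_array((data, (rows, cols)), shape=(n, n))
            adj = adj + adj.T
            adj.data[:] = 1  # duplicate (a,b)/(b,a) pairs collapse to 1
            adj = sp.csr_array(adj)
        else:
            adj = sp.csr_array((n, n), dtype=np.int8)
        frozen = {
            g: frozenset(v) for g, v in (labels or {}).items() if g in index
        }
        return cls(nodes=node_tuple, adjacency=adj, labels=frozen)

    def subgraph(self, keep: Iterable[str]) -> "AnnotatedNetwork":
        """Induced subgraph on ``keep`` (order of the original node list preserved)."""
        keep_set = set(keep)
        idx = np.array([i for i, g in enumerate(self.nodes) if g in keep_set], dtype=np.int64)
        sub = sp.csr_array(self.adjacency[np.ix_(idx, idx)])
        nodes = tuple(self.nodes[i] for i in idx)
        labels = {g: v for g, v in self.labels.items() if g in keep_set}
        return AnnotatedNetwork(nodes=nodes, adjacency=sub, labels=labels)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(sorted(e)) for e in self.edges())
        return g


@dataclass(frozen=True)
class GenePartition:
    """Node classes relative to disease set D and essential set E.

    Sets may include identifiers absent from the network; ``off_network``
    records which supplied annotations have no network node.
    """

    D: frozenset[str]
    E: frozenset[str]
    E_minus: frozenset[str]
    D_minus: frozenset[str]
    O: frozenset[str]
    off_network: frozenset[str]

    @property
    def both(self) -> frozenset[str]:
        return self.D & self.E

    def on_network(self, net: AnnotatedNetwork, which: str) -> frozenset[str]:
        """Restrict a class (one of D, E, E-, D-, O, both) to network nodes."""
        sel = self.class_set(which)
        return frozenset(g for g in sel if g in net)

    def class_set(self, which: str) -> frozenset[str]:
        key = which.replace("⁻", "-").replace("^-", "-")
        table = {
            "D": self.D,
            "E": self.E,
            "E-": self.E_minus,
            "D-": self.D_minus,
            "O": self.O,
            "both": self.both,
            "E∩D": self.both,
        }
        try:
            return table[key]
        except KeyError:
            raise KeyError(f"unknown gene class {which!r}; expected one of {sorted(table)}")

    def counts(self, net: AnnotatedNetwork) -> dict[str, int]:
        """Class sizes restricted to the network (the bookkeeping of the class tables)."""
        return {
            w: len(self.on_network(net, w)) for w in ("D", "E", "E-", "D-", "both", "O")
        }


def load_edge_list(path, score_threshold: float | None = None) -> AnnotatedNetwork:
    """Read a 2–3 column whitespace/tab edge list into an :class:`AnnotatedNetwork`.

    Columns are ``idA idB [score]`` with ``#``-comment lines ignored.  When
    ``score_threshold`` is given, edges with score below the threshold are
    dropped (STRING-style confidence filtering); their endpoints remain as
    nodes.  Self-loops are removed and duplicate edges collapsed.
    """
    nodes: dict[str, None] = {}
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise EdgeListParseError(
                    f"line {lineno}: expected at least two columns, got {len(parts)}"
                )
            a, b = parts[0], parts[1]
            nodes.setdefault(a)
            nodes.setdefault(b)
            if score_threshold is not None:
                if len(parts) < 3:
                    raise ConfigurationError(
                        f"line {lineno}: score threshold given but line has no score column"
                    )
                try:
                    score = float(parts[2])
                except ValueError as exc:
                    raise EdgeListParseError(
                        f"line {lineno}: score {parts[2]!r} is not numeric"
                    ) from exc
                if score < score_threshold:
                    continue
            elif len(parts) >= 3:
                try:
                    float(parts[2])
                except ValueError as exc:
                    raise EdgeListParseError(
                        f"line {lineno}: score {parts[2]!r} is not numeric"
                    ) from exc
            edges.append((a, b))
    return AnnotatedNetwork.from_edges(edges, nodes=tuple(nodes))


def largest_component(net: AnnotatedNetwork) -> AnnotatedNetwork:
    """Induced subgraph on the largest connected component.

    Ties on size are broken by the lexicographically smallest member set.
    An empty network is returned unchanged.
    """
    if net.n_nodes == 0:
        return net
    n_comp, membership = connected_components(net.adjacency, directed=False)
    comps: dict[int, list[str]] = {}
    for g, c in zip(net.nodes, membership):
        comps.setdefault(int(c), []).append(g)
    max_size = max(len(m) for m in comps.values())
    ties = [m for m in comps.values() if len(m) == max_size]
    best = min(ties, key=lambda members: sorted(members))
    return net.subgraph(best)


def partition_genes(
    net: AnnotatedNetwork,
    disease_ids: Iterable[str],
    essential_ids: Iterable[str],
) -> GenePartition:
    """Partition nodes into D-, E-, E∩D and O relative to the supplied sets.

    Identifiers absent from the network are kept in D/E and flagged in
    ``off_network``; the O class contains network nodes only.
    """
    D = frozenset(disease_ids)
    E = frozenset(essential_ids)
    on = set(net.nodes)
    off = frozenset((D | E) - on)
    if off:
        warnings.warn(
            f"{len(off)} annotated gene(s) absent from the network", stacklevel=2
        )
    return GenePartition(
        D=D,
        E=E,
        E_minus=E - D,
        D_minus=D - E,
        O=frozenset(on - D - E),
        off_network=off,
    )
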