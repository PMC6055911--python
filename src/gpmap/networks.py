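"""Genotype networks and their internal structure.

A genotype set (sites bound by one phenotype) splits into connected
components inside the genotype space; the largest component is the
dominant genotype network and carries all statistics: diameter,
characteristic path length, clustering coefficient, degree
assortativity, and the route factor toward the highest-affinity site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import graphs
from .pbm_io import DEFAULT_TAU, EScoreTable, GenotypeSet, TFRecord, bound_sites
from .space import GenotypeSpace


class EmptyGenotypeSetError(ValueError):
    pass


@dataclass
class GenotypeNetwork:
    """A connected component of a genotype set within the space graph."""

    phenotype_id: str
    node_indices: np.ndarray  # sorted indices into the GenotypeSpace
    space: GenotypeSpace
    is_dominant: bool = False
    _adj: sp.csr_matrix | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.node_indices)

    @property
    def n(self) -> int:
        return len(self.node_indices)

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Induced adjacency over the network's nodes (local indices)."""
        if self._adj is None:
            self._adj = self.space.induced_adjacency(self.node_indices)
        return self._adj

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    @property
    def sites(self) -> list[str]:
        all_sites = self.space.sites
        return [all_sites[i] for i in self.node_indices]

    def site_set(self) -> frozenset[str]:
        return frozenset(self.sites)

    def local_index(self, site: str) -> int:
        i = self.space.index_of(site)
        pos = int(np.searchsorted(self.node_indices, i))
        if pos >= self.n or self.node_indices[pos] != i:
            raise KeyError(f"site {site!r} not in network {self.phenotype_id!r}")
        return pos

    def to_networkx(self):
        import networkx as nx

        g = nx.from_scipy_sparse_array(self.adjacency)
        return nx.relabel_nodes(g, dict(enumerate(self.sites)))


def genotype_networks(
    genotype_set: GenotypeSet, space: GenotypeSpace
) -> list[GenotypeNetwork]:
    """Connected components of the induced subgraph, largest first.

    The first component is flagged dominant; size ties are broken by the
    lexicographically smallest member site.
    """
    if len(genotype_set) == 0:
        raise EmptyGenotypeSetError(f"genotype set {genotype_set.phenotype_id!r} is empty")
    idx = genotype_set.indices(space)
    sub = space.induced_adjacency(idx)
    n_comp, labels = graphs.connected_components(sub)
    comps = []
    for c in range(n_comp):
        members = idx[labels == c]
        # node indices are sorted, so members[0] is the smallest site code
        comps.append((-len(members), space.codes[members[0]], members))
    comps.sort(key=lambda t: (t[0], t[1]))
    out = [
        GenotypeNetwork(genotype_set.phenotype_id, members, space, is_dominant=(r == 0))
        for r, (_, _, members) in enumerate(comps)
    ]
    return out


def dominant_network(genotype_set: GenotypeSet, space: GenotypeSpace) -> GenotypeNetwork:
    return genotype_networks(genotype_set, space)[0]


def clustering_coefficient(network: GenotypeNetwork | sp.csr_matrix) -> float:
    """Mean local clustering; nodes with degree < 2 contribute zero."""
    adj = network.adjacency if isinstance(network, GenotypeNetwork) else network
    return graphs.clustering_eq1(adj)


def degree_assortativity(network: GenotypeNetwork | sp.csr_matrix) -> float:
    """Pearson correlation of endpoint degrees over edges; NaN if regular."""
    adj = network.adjacency if isinstance(network, GenotypeNetwork) else network
    return graphs.assortativity_eq2(adj)


def path_metrics(network: GenotypeNetwork | sp.csr_matrix) -> tuple[int, float]:
    """(diameter, characteristic path length) of a connected graph.

    The characteristic path length averages over unordered distinct
    pairs; a single-node graph reports (0, 0.0).
    """
    adj = network.adjacency if isinstance(network, GenotypeNetwork) else network
    return graphs.path_stats(adj)


def route_factor(network: GenotypeNetwork, target_site: str) -> float:
    """Mean ratio of in-network to in-space shortest paths to the target.

    Always >= 1; NaN for single-node networks.
    """
    if network.n < 2:
        return float("nan")
    t_local = network.local_index(target_site)
    t_global = int(network.node_indices[t_local])
    l_dist = graphs.bfs_distances(network.adjacency, t_local)
    d_dist = network.space.bfs_from(t_global)[network.node_indices]
    mask = np.ones(network.n, dtype=bool)
    mask[t_local] = False
    return float(np.mean(l_dist[mask] / d_dist[mask]))


def target_site(table: EScoreTable, network: GenotypeNetwork) -> str:
    """Highest-affinity site of the network; lexicographic tie-break."""
    scores = table.scores.loc[network.sites, network.phenotype_id]
    best = scores.max()
    return min(scores.index[scores == best])


@dataclass(frozen=True)
class IntraMetrics:
    phenotype_id: str
    set_size: int
    n_components: int
    dominant_size: int
    dominant_fraction: float
    n_edges: int
    diameter: int
    char_path_length: float
    clustering: float
    assortativity: float
    route_factor: float
    target_site: str
    degenerate: bool


def network_metrics(
    network: GenotypeNetwork,
    target: str,
    set_size: int | None = None,
    n_components: int = 1,
) -> IntraMetrics:
    set_size = set_size if set_size is not None else network.n
    degenerate = network.n < 2
    diameter, cpl = path_metrics(network)
    return IntraMetrics(
        phenotype_id=network.phenotype_id,
        set_size=set_size,
        n_components=n_components,
        dominant_size=network.n,
        dominant_fraction=network.n / set_size,
        n_edges=network.n_edges,
        diameter=diameter,
        char_path_length=cpl,
        clustering=clustering_coefficient(network),
        assortativity=degree_assortativity(network),
        route_factor=route_factor(network, target),
        target_site=target,
        degenerate=degenerate,
    )


def intranetwork_report(
    table: EScoreTable,
    space: GenotypeSpace,
    meta: Mapping[str, TFRecord] | None = None,
    tau: float = DEFAULT_TAU,
    tf_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-TF metrics of the dominant genotype network, one row per TF.

    TFs binding no site at the threshold are skipped (they have no
    genotype network).
    """
    rows = []
    for tf in tf_ids if tf_ids is not None else table.tf_ids:
        gset = bound_sites(table, tf, tau)
        if len(gset) == 0:
            continue
        comps = genotype_networks(gset, space)
        dom = comps[0]
        m = network_metrics(
            dom, target_site(table, dom), set_size=len(gset), n_components=len(comps)
        )
        record = {
            "tf_id": tf,
            "species": meta[tf].species if meta and tf in meta else "",
            "domain": meta[tf].domain if meta and tf in meta else "",
            "set_size": m.set_size,
            "n_components": m.n_components,
            "dominant_size": m.dominant_size,
            "dominant_fraction": m.dominant_fraction,
            "n_edges": m.n_edges,
            "diameter": m.diameter,
            "char_path_length": m.char_path_length,
            "clustering": m.clustering,
            "assortativity": m.assortativity,
            "route_factor": m.route_factor,
            "target_site": m.target_site,
            "degenerate": m.degenerate,
        }
        rows.append(record)
    return pd.DataFrame(rows)


def dominant_networks(
    table: EScoreTable,
    space: GenotypeSpace,
    tau: float = DEFAULT_TAU,
    tf_ids: Sequence[str] | None = None,
) -> dict[str, GenotypeNetwork]:
    """Dominant genotype network per TF (TFs with empty sets skipped)."""
    out: dict[str, GenotypeNetwork] = {}
    for tf in tf_ids if tf_ids is not None else table.tf_ids:
        gset = bound_sites(table, tf, tau)
        if len(gset) == 0:
            continue
        out[tf] = dominant_network(gset, space)
    return out
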