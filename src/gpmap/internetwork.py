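"""How genotype networks overlap and interface within genotype space.

All measures operate on the *dominant* genotype networks of the
phenotypes under study (TFs or DNA-binding domains):

* overlap ``O_qp``: shared sites as a fraction of network p's size;
* local spectrum ``phi_q_local(i)``: fraction of site i's space
  neighbors that lie in network q, and its network mean ``phi_qp``;
* global mutational connectivity ``Phi_q``: sum of ``phi_qp`` over
  source phenotypes p != q;
* accessibility ``A_qp``: fraction of network p's external one-mutant
  boundary that lies in network q;
* Bhattacharyya coefficients of local spectra and the neutral-neighbor
  similarity ratio;
* the interface with unbound sites, phenotype space covering curves,
  the phenotype network, and DNA-binding-domain coarse-graining.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import graphs
from .networks import GenotypeNetwork, dominant_network, genotype_networks
from .pbm_io import DEFAULT_TAU, EScoreTable, GenotypeSet, TFRecord, bound_sites
from .space import GenotypeSpace

logger = logging.getLogger(__name__)


def _membership(networks: Sequence[GenotypeNetwork], space: GenotypeSpace) -> np.ndarray:
    """Boolean (n_sites, n_phenotypes) indicator of dominant-network membership."""
    B = np.zeros((space.n_sites, len(networks)), dtype=bool)
    for j, net in enumerate(networks):
        B[net.node_indices, j] = True
    return B


def _ids(networks: Sequence[GenotypeNetwork]) -> list[str]:
    return [net.phenotype_id for net in networks]


def overlap_matrix(networks: Sequence[GenotypeNetwork]) -> pd.DataFrame:
    """O_qp = |S(G_q) ∩ S(G_p)| / |S(G_p)| with q as rows, p as columns."""
    ids = _ids(networks)
    sets = [set(net.node_indices.tolist()) for net in networks]
    out = np.empty((len(ids), len(ids)))
    for qi, sq in enumerate(sets):
        for pi, sp_ in enumerate(sets):
            out[qi, pi] = len(sq & sp_) / len(sp_) if sp_ else np.nan
    return pd.DataFrame(out, index=ids, columns=ids)


@dataclass(frozen=True)
class LocalSpectrum:
    """Phenotype composition of one genotype's mutational neighborhood."""

    site: str
    k_i: int
    counts: dict[str, int]  # phenotype -> neighbors in that network

    def fractions(self) -> dict[str, float]:
        return {q: n / self.k_i for q, n in self.counts.items()}


def local_spectrum(
    site: str, networks: Sequence[GenotypeNetwork], space: GenotypeSpace
) -> LocalSpectrum:
    i = space.index_of(site)
    adj = space.adjacency
    nbrs = adj.indices[adj.indptr[i] : adj.indptr[i + 1]]
    counts = {}
    for net in networks:
        inside = np.isin(nbrs, net.node_indices, assume_unique=True)
        counts[net.phenotype_id] = int(inside.sum())
    return LocalSpectrum(site=space.sites[i], k_i=len(nbrs), counts=counts)


def phi_matrix(
    networks: Sequence[GenotypeNetwork],
    space: GenotypeSpace,
    unbound: GenotypeSet | None = None,
) -> pd.DataFrame:
    """phi_qp: mean over sites of network p of the local fraction of
    neighbors in network q.  Rows q, columns p; includes the diagonal
    (within-network neutral fraction).  If ``unbound`` is given, an
    extra ``unbound`` row holds phi_{unbound,p}.
    """
    ids = _ids(networks)
    B = _membership(networks, space).astype(np.float64)
    if unbound is not None:
        col = np.zeros((space.n_sites, 1))
        col[unbound.indices(space), 0] = 1.0
        B = np.hstack([B, col])
    counts = space.adjacency @ B  # n_iq for every site
    k = space.degrees.astype(np.float64)
    phi_local = counts / k[:, None]
    row_ids = ids + (["unbound"] if unbound is not None else [])
    out = np.empty((len(row_ids), len(ids)))
    for pi, net in enumerate(networks):
        out[:, pi] = phi_local[net.node_indices].mean(axis=0)
    return pd.DataFrame(out, index=row_ids, columns=ids)


def global_connectivity(phi: pd.DataFrame) -> pd.Series:
    """Phi_q: sum of phi_qp over source phenotypes p != q."""
    phenos = [q for q in phi.index if q in phi.columns]
    out = {}
    for q in phenos:
        cols = [p for p in phi.columns if p != q]
        out[q] = float(phi.loc[q, cols].sum()) if cols else 0.0
    return pd.Series(out, name="Phi")


def accessibility_matrix(
    networks: Sequence[GenotypeNetwork], space: GenotypeSpace
) -> pd.DataFrame:
    """A_qp: fraction of network p's external boundary inside network q.

    The boundary is the set of one-mutant neighbors of S(G_p) excluding
    S(G_p) itself; NaN column if the boundary is empty.
    """
    ids = _ids(networks)
    out = np.empty((len(ids), len(ids)))
    member_sets = [net.node_indices for net in networks]
    for pi, net in enumerate(networks):
        bnd = space.boundary(net.node_indices)
        if bnd.size == 0:
            out[:, pi] = np.nan
            continue
        for qi, members in enumerate(member_sets):
            out[qi, pi] = np.isin(bnd, members, assume_unique=True).mean()
    return pd.DataFrame(out, index=ids, columns=ids)


def _spectrum_counts(
    i: int,
    networks: Sequence[GenotypeNetwork],
    space: GenotypeSpace,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    adj = space.adjacency
    nbrs = adj.indices[adj.indptr[i] : adj.indptr[i + 1]]
    if exclude is not None and exclude.size:
        nbrs = nbrs[~np.isin(nbrs, exclude, assume_unique=True)]
    return np.array(
        [np.isin(nbrs, net.node_indices, assume_unique=True).sum() for net in networks],
        dtype=np.float64,
    )


def bhattacharyya(
    site_i: str,
    site_j: str,
    networks: Sequence[GenotypeNetwork],
    space: GenotypeSpace,
    exclude_shared: bool = True,
    sqrt_form: bool = True,
) -> float:
    """Bhattacharyya coefficient of the two sites' local phenotype spectra.

    Spectra are normalized to sum to one before the coefficient
    ``sum_q sqrt(p_q(i) p_q(j))`` is taken, so the result lies in [0, 1]
    (1 for identical spectra, 0 for disjoint support).  With
    ``exclude_shared`` the neighbors common to both sites are removed
    before counting, a more conservative comparison.  ``sqrt_form=False``
    computes the literal product-sum instead.  NaN when either spectrum
    has zero mass.
    """
    ii, jj = space.index_of(site_i), space.index_of(site_j)
    if ii == jj:
        raise ValueError("sites must be distinct")
    exclude = None
    if exclude_shared:
        adj = space.adjacency
        ni = adj.indices[adj.indptr[ii] : adj.indptr[ii + 1]]
        nj = adj.indices[adj.indptr[jj] : adj.indptr[jj + 1]]
        exclude = np.intersect1d(ni, nj, assume_unique=True)
    ci = _spectrum_counts(ii, networks, space, exclude)
    cj = _spectrum_counts(jj, networks, space, exclude)
    si, sj = ci.sum(), cj.sum()
    if si == 0 or sj == 0:
        return float("nan")
    pi_, pj_ = ci / si, cj / sj
    if sqrt_form:
        return float(np.sqrt(pi_ * pj_).sum())
    return float((pi_ * pj_).sum())


@dataclass(frozen=True)
class SimilarityRatioResult:
    ratios: np.ndarray
    mean: float
    sem: float
    n_pairs: int
    n_skipped: int


def similarity_ratio(
    network: GenotypeNetwork,
    networks: Sequence[GenotypeNetwork],
    space: GenotypeSpace,
    seed: int | np.random.Generator = 0,
    exclude_shared: bool = True,
    max_pairs: int | None = None,
) -> SimilarityRatioResult:
    """BC(i, j) / BC(i, k) over neutral-neighbor pairs (i, j).

    For each edge (i, j) of the network a non-neighbor k from the same
    network is sampled uniformly; a ratio above one means neighboring
    genotypes have more similar mutational neighborhoods than
    non-neighboring ones.  Pairs with undefined coefficients, or where
    no non-neighbor exists, are skipped and counted.
    """
    if network.n < 3:
        raise ValueError("network needs at least 3 sites")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sub = network.adjacency
    u, v = graphs.edge_endpoints(sub)
    order = np.arange(len(u))
    if max_pairs is not None and len(u) > max_pairs:
        order = rng.choice(len(u), size=max_pairs, replace=False)
    sites = network.sites
    ratios = []
    n_skipped = 0
    for e in order:
        i, j = int(u[e]), int(v[e])
        nbrs_i = sub.indices[sub.indptr[i] : sub.indptr[i + 1]]
        candidates = np.setdiff1d(
            np.arange(network.n), np.concatenate([nbrs_i, [i]]), assume_unique=False
        )
        if candidates.size == 0:
            n_skipped += 1
            logger.debug("no non-neighbor for pair (%s, %s)", sites[i], sites[j])
            continue
        kk = int(rng.choice(candidates))
        bc_ij = bhattacharyya(sites[i], sites[j], networks, space, exclude_shared)
        bc_ik = bhattacharyya(sites[i], sites[kk], networks, space, exclude_shared)
        if not (math.isfinite(bc_ij) and math.isfinite(bc_ik)) or bc_ik == 0:
            n_skipped += 1
            continue
        ratios.append(bc_ij / bc_ik)
    arr = np.array(ratios)
    mean = float(arr.mean()) if len(arr) else float("nan")
    sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else float("nan")
    return SimilarityRatioResult(arr, mean, sem, len(arr), n_skipped)


def unbound_interface(
    networks: Sequence[GenotypeNetwork],
    unbound: GenotypeSet,
    space: GenotypeSpace,
) -> pd.Series:
    """phi_{unbound,p} / f_unbound per phenotype; 1 means null-consistent.

    NaN everywhere when there are no unbound sites.
    """
    f_unbound = len(unbound) / space.n_sites
    phi = phi_matrix(networks, space, unbound=unbound)
    row = phi.loc["unbound"]
    if f_unbound == 0:
        return pd.Series(np.nan, index=row.index, name="unbound_ratio")
    return (row / f_unbound).rename("unbound_ratio")


def phenotype_space_covering(
    network: GenotypeNetwork,
    networks: Sequence[GenotypeNetwork],
    space: GenotypeSpace,
    variant: str = "neutral",
    max_radius: int = 8,
    include_self: bool = True,
) -> pd.DataFrame:
    """Mean fraction of phenotypes found within radius n of each site.

    ``variant='neutral'`` expands breadth-first along the network's own
    edges; ``variant='non-neutral'`` expands through the space graph
    along steps that land outside the network.  Covered means at least
    one visited genotype (radius <= n, source included when
    ``include_self``) lies in the phenotype's dominant network.  Returns
    columns (n, mean, sd), non-decreasing in n.
    """
    if variant not in ("neutral", "non-neutral"):
        raise ValueError(f"unknown variant {variant!r}")
    P = len(networks)
    B = _membership(networks, space)
    frac = np.zeros((network.n, max_radius + 1))
    if variant == "neutral":
        sub = network.adjacency
        glob = network.node_indices
        for s in range(network.n):
            dist = graphs.bfs_distances(sub, s)
            covered = np.zeros(P, dtype=bool)
            if include_self:
                covered |= B[glob[s]]
            for n_r in range(max_radius + 1):
                shell = glob[(dist >= (0 if include_self else 1)) & (dist <= n_r) & (dist >= 0)]
                covered |= B[shell].any(axis=0) if shell.size else False
                frac[s, n_r] = covered.sum() / P
    else:
        inside = np.zeros(space.n_sites, dtype=bool)
        inside[network.node_indices] = True
        for s in range(network.n):
            src = int(network.node_indices[s])
            dist = _restricted_bfs(space, src, inside)
            covered = np.zeros(P, dtype=bool)
            if include_self:
                covered |= B[src]
            for n_r in range(max_radius + 1):
                shell = np.flatnonzero((dist >= 1) & (dist <= n_r))
                if shell.size:
                    covered |= B[shell].any(axis=0)
                frac[s, n_r] = covered.sum() / P
    return pd.DataFrame(
        {
            "n": np.arange(max_radius + 1),
            "mean": frac.mean(axis=0),
            "sd": frac.std(axis=0, ddof=0),
        }
    )


def _restricted_bfs(space: GenotypeSpace, source: int, forbidden: np.ndarray) -> np.ndarray:
    """BFS from ``source`` where every step lands outside ``forbidden``.

    The source itself may be inside; all subsequent nodes must be
    outside, which makes every traversed mutation non-neutral with
    respect to the focal network.
    """
    adj = space.adjacency
    n = space.n_sites
    dist = np.full(n, -1, dtype=np.int32)
    dist[source] = 0
    seen = np.zeros(n, dtype=bool)
    seen[source] = True
    frontier = np.array([source], dtype=np.int64)
    d = 0
    while frontier.size:
        d += 1
        chunks = [adj.indices[adj.indptr[i] : adj.indptr[i + 1]] for i in frontier]
        nbrs = np.concatenate(chunks)
        new = nbrs[~seen[nbrs]]
        new = new[~forbidden[new]]
        if new.size == 0:
            break
        seen[new] = True
        frontier = np.unique(new)
        dist[frontier] = d
    return dist


def phenotype_network(
    networks: Sequence[GenotypeNetwork], space: GenotypeSpace
) -> pd.DataFrame:
    """Edge list over phenotypes: ``overlap`` when dominant networks
    share a genotype, else ``adjacent-by-mutation`` when a single
    mutation connects them; no row for unrelated pairs.
    """
    ids = _ids(networks)
    B = _membership(networks, space).astype(np.int8)
    cross = B.T @ (space.adjacency @ B)  # mutational contacts (incl. via overlap)
    shared = B.T.astype(np.int64) @ B.astype(np.int64)
    rows = []
    for qi in range(len(ids)):
        for pi in range(qi + 1, len(ids)):
            if shared[qi, pi] > 0:
                rows.append((ids[qi], ids[pi], "overlap"))
            elif cross[qi, pi] > 0:
                rows.append((ids[qi], ids[pi], "adjacent-by-mutation"))
    return pd.DataFrame(rows, columns=["phenotype_q", "phenotype_p", "relation"])


def domain_genotype_sets(
    table: EScoreTable,
    meta: Mapping[str, TFRecord],
    tau: float = DEFAULT_TAU,
) -> dict[str, GenotypeSet]:
    """Coarse-grained phenotypes: union of bound sites over each
    DNA-binding-domain's member TFs.  TFs missing from the metadata are
    excluded with a warning.
    """
    by_domain: dict[str, set[str]] = {}
    for tf in table.tf_ids:
        if tf not in meta or not meta[tf].domain:
            logger.warning("TF %s has no domain label; excluded from coarse-graining", tf)
            continue
        by_domain.setdefault(meta[tf].domain, set()).update(
            bound_sites(table, tf, tau).sites
        )
    return {
        dom: GenotypeSet(dom, frozenset(sites))
        for dom, sites in sorted(by_domain.items())
        if sites
    }


def dominant_domain_networks(
    table: EScoreTable,
    meta: Mapping[str, TFRecord],
    space: GenotypeSpace,
    tau: float = DEFAULT_TAU,
) -> dict[str, GenotypeNetwork]:
    return {
        dom: dominant_network(gset, space)
        for dom, gset in domain_genotype_sets(table, meta, tau).items()
    }


def matrix_for_export(m: pd.DataFrame, na_diagonal: bool = True) -> pd.DataFrame:
    """Copy with the diagonal blanked to NA, matching heatmap exports."""
    out = m.copy().astype(float)
    if na_diagonal:
        for q in out.index:
            if q in out.columns:
                out.loc[q, q] = np.nan
    return out


def order_phenotypes(
    ids: Iterable[str],
    meta: Mapping[str, TFRecord],
    sizes: Mapping[str, int],
) -> list[str]:
    """Export ordering: domain alphabetically, then dominant size ascending."""
    return sorted(ids, key=lambda t: (meta[t].domain if t in meta else "", sizes[t], t))
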