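"""Canonical double-stranded k-mer genotype space and its mutation model.

A genotype is a double-stranded DNA site of length ``k`` (default 8),
identified with its reverse complement.  The space of all such genotypes
forms a graph in which two sites are adjacent if they differ by a single
point mutation or by a one-base shift (an indel that slides the whole
site by one position).  For ``k = 8`` this graph has
``(4**8 - 4**4) / 2 + 4**4 == 32,896`` nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from . import graphs

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")

__all__ = [
    "InvalidAlphabetError",
    "revcomp",
    "canonical",
    "is_self_revcomp",
    "enumerate_space",
    "point_mutants",
    "shift_mutants",
    "neighbors",
    "mutational_distance",
    "GenotypeSpace",
    "SpaceStats",
    "build_omega",
]


class InvalidAlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A, C, G, T}."""


def _validate(s: str, k: int | None = None) -> str:
    seq = s.upper()
    if any(c not in BASES for c in seq):
        bad = sorted(set(seq) - set(BASES))
        raise InvalidAlphabetError(f"non-ACGT characters in {s!r}: {bad}")
    if k is not None and len(seq) != k:
        raise ValueError(f"expected length-{k} sequence, got {s!r}")
    return seq


def revcomp(s: str) -> str:
    """Reverse complement of ``s``.  Involution: ``revcomp(revcomp(s)) == s``."""
    return _validate(s).translate(_COMPLEMENT)[::-1]


def canonical(s: str) -> str:
    """Canonical representative of the pair ``{s, revcomp(s)}``.

    The representative is the lexicographically smaller of the two
    strands, so the function is idempotent and strand-symmetric:
    ``canonical(s) == canonical(revcomp(s))``.
    """
    seq = _validate(s)
    return min(seq, seq.translate(_COMPLEMENT)[::-1])


def is_self_revcomp(s: str) -> bool:
    seq = _validate(s)
    return seq == seq.translate(_COMPLEMENT)[::-1]


def enumerate_space(k: int = 8) -> list[str]:
    """All canonical double-stranded k-mers, lexicographically sorted.

    The count is ``(4**k - 4**(k//2)) / 2 + 4**(k//2)`` for even ``k``
    (self-reverse-complementary sites cannot be merged).
    """
    codes = _canonical_codes(k)
    return [_decode(int(c), k) for c in codes]


def point_mutants(s: str) -> set[str]:
    """Canonical forms of the 24 (``3*k``) single-base substitutions of ``s``.

    The result excludes ``s`` itself; canonical merging may collapse
    distinct raw substitutions, so the size can be below ``3*k``.
    """
    seq = canonical(s)
    out = set()
    for i, cur in enumerate(seq):
        for b in BASES:
            if b != cur:
                out.add(canonical(seq[:i] + b + seq[i + 1 :]))
    out.discard(seq)
    return out


def shift_mutants(s: str) -> set[str]:
    """Canonical forms of the 8 one-base shifts of ``s``.

    A shift slides the whole site one base in the 5' or 3' direction,
    with each of the four bases entering at the exposed end; the raw
    count is ``4 * 2 == 8`` before canonical merging.
    """
    seq = canonical(s)
    out = set()
    for b in BASES:
        out.add(canonical(b + seq[:-1]))
        out.add(canonical(seq[1:] + b))
    out.discard(seq)
    return out


def neighbors(s: str) -> set[str]:
    """All single-mutation neighbors of ``s``: substitutions plus shifts.

    At most ``3*k + 8`` (32 for ``k = 8``) distinct canonical neighbors.
    """
    return point_mutants(s) | shift_mutants(s)


def mutational_distance(s1: str, s2: str) -> int:
    """Gapless alignment distance between two sites.

    The number of mismatches of ``s1`` against ``s2`` and against the
    reverse complement of ``s2`` at zero offset, minimized over the two
    strands.  Symmetric; zero iff the two sites canonicalize identically.
    """
    a = canonical(s1)
    b = _validate(s2)
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    b_rc = b.translate(_COMPLEMENT)[::-1]
    m = sum(x != y for x, y in zip(a, b))
    m_rc = sum(x != y for x, y in zip(a, b_rc))
    return min(m, m_rc)


# ---------------------------------------------------------------------------
# Vectorized integer machinery.  A k-mer is encoded in 2k bits with A=0,
# C=1, G=2, T=3 and the first character in the most significant position,
# so numeric order on codes equals lexicographic order on strings.
# ---------------------------------------------------------------------------


def _encode(s: str) -> int:
    code = 0
    for c in s:
        code = (code << 2) | BASES.index(c)
    return code


def _decode(code: int, k: int) -> str:
    return "".join(BASES[(code >> (2 * (k - 1 - j))) & 3] for j in range(k))


def _rc_codes(k: int) -> np.ndarray:
    """Reverse-complement lookup table over all ``4**k`` codes."""
    codes = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(codes)
    for i in range(k):
        digit = (codes >> (2 * i)) & 3
        rc |= (3 - digit) << (2 * (k - 1 - i))
    return rc


def _canonical_codes(k: int) -> np.ndarray:
    rc = _rc_codes(k)
    return np.unique(np.minimum(np.arange(4**k, dtype=np.int64), rc))


def _neighbor_candidates(codes: np.ndarray, k: int) -> np.ndarray:
    """Raw mutation products, shape ``(n, 3k + 8)``, not canonicalized."""
    n = len(codes)
    cands = np.empty((n, 3 * k + 8), dtype=np.int64)
    col = 0
    for j in range(k):
        shift = 2 * (k - 1 - j)
        digit = (codes >> shift) & 3
        for delta in (1, 2, 3):
            nd = (digit + delta) % 4
            cands[:, col] = codes - (digit << shift) + (nd << shift)
            col += 1
    low_mask = (1 << (2 * (k - 1))) - 1
    left = (codes & low_mask) << 2  # shift 5'-ward: drop first base
    right = codes >> 2  # shift 3'-ward: drop last base
    for b in range(4):
        cands[:, col] = left + b
        col += 1
    for b in range(4):
        cands[:, col] = right + (b << (2 * (k - 1)))
        col += 1
    return cands


@dataclass(frozen=True)
class SpaceStats:
    n_nodes: int
    n_edges: int
    diameter: int
    char_path_length: float
    clustering: float
    assortativity: float
    max_degree: int
    frac_max_degree: float


@dataclass
class GenotypeSpace:
    """The full genotype space graph (the network of all genotypes).

    Nodes are canonical k-mers in sorted order; ``adjacency`` is a
    symmetric CSR boolean matrix over node indices.
    """

    k: int
    codes: np.ndarray  # sorted canonical codes, shape (n,)
    adjacency: sp.csr_matrix
    _sites: list[str] | None = field(default=None, repr=False)
    _site_index: dict[str, int] | None = field(default=None, repr=False)

    @property
    def n_sites(self) -> int:
        return len(self.codes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    @property
    def sites(self) -> list[str]:
        if self._sites is None:
            self._sites = [_decode(int(c), self.k) for c in self.codes]
        return self._sites

    @property
    def site_index(self) -> dict[str, int]:
        if self._site_index is None:
            self._site_index = {s: i for i, s in enumerate(self.sites)}
        return self._site_index

    @property
    def degrees(self) -> np.ndarray:
        return np.diff(self.adjacency.indptr)

    def index_of(self, site: str) -> int:
        """Node index of a site (canonicalized first)."""
        code = _encode(canonical(site))
        i = int(np.searchsorted(self.codes, code))
        if i >= len(self.codes) or self.codes[i] != code:
            raise KeyError(f"site {site!r} not in space (k={self.k})")
        return i

    def indices_of(self, sites: Iterable[str]) -> np.ndarray:
        return np.array(sorted(self.index_of(s) for s in sites), dtype=np.int64)

    def site(self, i: int) -> str:
        return self.sites[i]

    def neighbors_of(self, site: str) -> set[str]:
        i = self.index_of(site)
        row = self.adjacency.indices[
            self.adjacency.indptr[i] : self.adjacency.indptr[i + 1]
        ]
        return {self.sites[j] for j in row}

    def bfs_from(self, i: int) -> np.ndarray:
        """Graph distances from node ``i`` to every node (−1 unreachable)."""
        return graphs.bfs_distances(self.adjacency, i)

    def induced_adjacency(self, node_indices: np.ndarray) -> sp.csr_matrix:
        idx = np.asarray(node_indices, dtype=np.int64)
        return self.adjacency[idx][:, idx].tocsr()

    def boundary(self, node_indices: np.ndarray) -> np.ndarray:
        """External one-mutant boundary of a node set (indices)."""
        idx = np.asarray(node_indices, dtype=np.int64)
        reach = np.unique(
            np.concatenate(
                [
                    self.adjacency.indices[
                        self.adjacency.indptr[i] : self.adjacency.indptr[i + 1]
                    ]
                    for i in idx
                ]
            )
            if len(idx)
            else np.empty(0, dtype=np.int64)
        )
        return np.setdiff1d(reach, idx, assume_unique=True)

    def stats(self, progress: bool = False) -> SpaceStats:
        """Exact whole-graph statistics (all-pairs BFS; minutes for k=8)."""
        deg = self.degrees
        diameter, cpl = graphs.path_stats(self.adjacency, progress=progress)
        return SpaceStats(
            n_nodes=self.n_sites,
            n_edges=self.n_edges,
            diameter=diameter,
            char_path_length=cpl,
            clustering=graphs.clustering_eq1(self.adjacency),
            assortativity=graphs.assortativity_eq2(self.adjacency),
            max_degree=int(deg.max()),
            frac_max_degree=float(np.mean(deg == deg.max())),
        )

    def edge_list(self) -> Iterable[tuple[str, str]]:
        coo = sp.triu(self.adjacency).tocoo()
        sites = self.sites
        for i, j in zip(coo.row, coo.col):
            yield sites[i], sites[j]


def build_omega(k: int = 8) -> GenotypeSpace:
    """Construct the full genotype space graph for site length ``k``.

    Edges connect canonical sites that differ by a single point mutation
    or by a one-base shift, after canonical merging; self-loops are
    dropped and parallel candidates collapse, so degrees are at most
    ``3*k + 8``.
    """
    if k < 2:
        raise ValueError("site length must be at least 2")
    rc = _rc_codes(k)
    canon = np.unique(np.minimum(np.arange(4**k, dtype=np.int64), rc))
    cands = _neighbor_candidates(canon, k)
    cands = np.minimum(cands, rc[cands])

    src = np.repeat(canon, cands.shape[1])
    dst = cands.ravel()
    keep = src != dst
    a = np.minimum(src[keep], dst[keep])
    b = np.maximum(src[keep], dst[keep])
    pair_key = np.unique((a << (2 * k)) | b)
    a = pair_key >> (2 * k)
    b = pair_key & ((1 << (2 * k)) - 1)

    ia = np.searchsorted(canon, a)
    ib = np.searchsorted(canon, b)
    n = len(canon)
    data = np.ones(len(ia), dtype=np.int8)
    adj = sp.coo_matrix(
        (np.concatenate([data, data]), (np.concatenate([ia, ib]), np.concatenate([ib, ia]))),
        shape=(n, n),
    ).tocsr()
    adj.data[:] = 1
    return GenotypeSpace(k=k, codes=canon, adjacency=adj)
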