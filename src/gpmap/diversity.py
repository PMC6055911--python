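"""In-vivo analysis: footprints, putative binding sites, and diversity.

DNase footprints (BED + sequence) are filtered to promoter-overlapping
intervals of at least site length, scanned for high-affinity windows
(both strands via canonicalization), and one window per footprint is
assigned to each qualifying TF.  Per-site nucleotide diversity is the
position-averaged Shannon entropy of allele frequencies (0 for
monomorphic sites, 2 when all four bases are equally frequent), and
per-TF diversity is related to genotype-network structure through
Spearman and size-controlled partial Spearman correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pbm_io import DEFAULT_TAU, EScoreTable
from .space import BASES, canonical

logger = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 500
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class IntervalFormatError(ValueError):
    pass


class FrequencyValidationError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class Footprint:
    """A protein-protected genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    sequence: str | None = None
    name: str = ""

    def __post_init__(self):
        if self.end < self.start:
            raise IntervalFormatError(
                f"negative-length interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.sequence is not None and len(self.sequence) != self.end - self.start:
            raise IntervalFormatError(
                f"sequence length {len(self.sequence)} != interval length "
                f"{self.end - self.start} for {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SiteAssignment:
    """One putative binding site for a TF within a footprint."""

    tf_id: str
    footprint: Footprint
    offset: int  # window start relative to footprint start
    window_seq: str  # genomic-strand sequence of the window
    site: str  # canonical form

    @property
    def chrom(self) -> str:
        return self.footprint.chrom

    @property
    def start(self) -> int:
        return self.footprint.start + self.offset


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Minimal BED reader: (chrom, start, end, name)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise IntervalFormatError(f"{path}:{ln}: expected >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end < start:
                raise IntervalFormatError(f"{path}:{ln}: end < start")
            out.append((chrom, start, end, parts[3] if len(parts) > 3 else ""))
    return out


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def footprints_from_bed(
    bed: Iterable[tuple[str, int, int, str]], genome: Mapping[str, str] | None = None
) -> list[Footprint]:
    out = []
    for chrom, start, end, name in bed:
        seq = genome[chrom][start:end] if genome is not None else None
        out.append(Footprint(chrom, start, end, sequence=seq, name=name))
    return out


def promoter_intervals(
    genes: Iterable[tuple[str, int, str]], upstream: int = PROMOTER_UPSTREAM
) -> list[tuple[str, int, int]]:
    """Promoters as the ``upstream`` bp 5' of each (chrom, tss, strand)."""
    out = []
    for chrom, tss, strand in genes:
        if strand == "-":
            out.append((chrom, tss, tss + upstream))
        else:
            out.append((chrom, max(0, tss - upstream), tss))
    return out


def _overlap_index(intervals: Sequence[tuple[str, int, int]]):
    """Per-chromosome sorted starts with prefix-max ends, for overlap tests."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        chrom, start, end = iv[0], iv[1], iv[2]
        by_chrom.setdefault(chrom, []).append((start, end))
    index = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs])
        ends = np.maximum.accumulate(np.array([e for _, e in ivs]))
        index[chrom] = (starts, ends)
    return index


def filter_footprints(
    footprints: Iterable[Footprint],
    promoters: Sequence[tuple[str, int, int]] | Sequence[tuple[str, int, int, str]],
    min_length: int = 8,
) -> list[Footprint]:
    """Keep footprints of length >= ``min_length`` with >= 1 bp of
    promoter overlap."""
    index = _overlap_index([p[:3] for p in promoters])
    kept = []
    for fp in footprints:
        if len(fp) < min_length:
            continue
        if fp.chrom not in index:
            continue
        starts, ends = index[fp.chrom]
        i = int(np.searchsorted(starts, fp.end, side="left"))
        if i > 0 and ends[i - 1] > fp.start:
            kept.append(fp)
    return kept


def assign_sites(
    footprints: Sequence[Footprint],
    table: EScoreTable,
    tau: float = DEFAULT_TAU,
    seed: int | np.random.Generator = 0,
    tf_ids: Sequence[str] | None = None,
) -> dict[str, list[SiteAssignment]]:
    """Per TF, one putative binding site per qualifying footprint.

    Every length-k window of a footprint is canonicalized (covering both
    strands) and scored; windows with E > tau qualify, and one is chosen
    uniformly at random per (footprint, TF) when several do.
    Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = table.k
    tfs = list(tf_ids) if tf_ids is not None else table.tf_ids
    score_cols = table.scores[tfs]
    out: dict[str, list[SiteAssignment]] = {tf: [] for tf in tfs}
    for fp in footprints:
        if fp.sequence is None:
            raise ValueError(f"footprint {fp.chrom}:{fp.start}-{fp.end} has no sequence")
        windows = [
            (off, fp.sequence[off : off + k]) for off in range(len(fp) - k + 1)
        ]
        canons = [canonical(w) for _, w in windows]
        vals = score_cols.loc[canons].to_numpy()  # (n_windows, n_tfs)
        qualifies = vals > tau
        for t, tf in enumerate(tfs):
            hits = np.flatnonzero(qualifies[:, t])
            if hits.size == 0:
                continue
            choice = int(hits[0]) if hits.size == 1 else int(rng.choice(hits))
            off, wseq = windows[choice]
            out[tf].append(SiteAssignment(tf, fp, off, wseq, canons[choice]))
    return out


# ---------------------------------------------------------------------------
# Allele frequencies and Shannon diversity
# ---------------------------------------------------------------------------


class AlleleFrequencyTable:
    """Per-position allele frequencies; positions without a record are
    monomorphic for the reference base."""

    def __init__(self, freqs: Mapping[tuple[str, int], np.ndarray] | None = None):
        self.freqs = dict(freqs or {})

    def set(self, chrom: str, pos: int, freq: Sequence[float]) -> None:
        arr = np.asarray(freq, dtype=float)
        if arr.shape != (4,) or not np.isclose(arr.sum(), 1.0, atol=1e-6):
            raise FrequencyValidationError(
                f"allele frequencies at {chrom}:{pos} must be 4 values summing to 1"
            )
        self.freqs[(chrom, pos)] = arr

    def site_frequencies(self, chrom: str, start: int, ref_seq: str) -> np.ndarray:
        """(len, 4) frequency matrix for positions [start, start+len)."""
        mat = np.zeros((len(ref_seq), 4))
        for i, base in enumerate(ref_seq):
            rec = self.freqs.get((chrom, start + i))
            if rec is not None:
                mat[i] = rec
            else:
                mat[i, _BASE_INDEX[base]] = 1.0
        return mat


def allele_frequencies_from_vcf(path, biallelic_only: bool = True) -> AlleleFrequencyTable:
    """Allele frequencies of SNPs in a VCF.

    Frequencies come from called genotypes when present, falling back to
    the ``AF`` INFO field.  Multiallelic records are skipped by default;
    non-SNP records are always skipped.
    """
    from cyvcf2 import VCF

    table = AlleleFrequencyTable()
    for var in VCF(str(path)):
        if not var.is_snp:
            continue
        if biallelic_only and len(var.ALT) != 1:
            continue
        alts = [a for a in var.ALT if a in _BASE_INDEX]
        if var.REF not in _BASE_INDEX or len(alts) != len(var.ALT):
            continue
        freq = np.zeros(4)
        gts = var.gt_types
        if gts is not None and len(gts) > 0:
            aaf = var.aaf  # alternate allele frequency from genotypes
            alt_freqs = [aaf] if len(alts) == 1 else None
        else:
            alt_freqs = None
        if alt_freqs is None:
            info_af = var.INFO.get("AF")
            if info_af is None:
                continue
            alt_freqs = list(np.atleast_1d(info_af).astype(float))
        for alt, af in zip(alts, alt_freqs):
            freq[_BASE_INDEX[alt]] = af
        freq[_BASE_INDEX[var.REF]] = 1.0 - sum(alt_freqs)
        table.set(var.CHROM, var.POS - 1, freq)  # VCF is 1-based
    return table


def shannon_diversity(freqs: np.ndarray) -> float:
    """Position-averaged Shannon entropy of allele frequencies (bits).

    ``freqs`` is a (site_length, 4) matrix whose rows sum to one;
    0 * log2(0) counts as zero.  Ranges from 0 (monomorphic) to 2
    (uniform frequencies at every position).
    """
    mat = np.asarray(freqs, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != 4:
        raise FrequencyValidationError("expected a (site_length, 4) frequency matrix")
    if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-6):
        raise FrequencyValidationError("each position's frequencies must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(mat > 0, mat * np.log2(np.where(mat > 0, mat, 1.0)), 0.0)
    return float(-terms.sum() / mat.shape[0])


def is_polymorphic(freqs: np.ndarray) -> bool:
    return bool((np.asarray(freqs).max(axis=1) < 1.0).any())


def diversity_records(
    assignments: Mapping[str, Sequence[SiteAssignment]],
    freq_table: AlleleFrequencyTable,
) -> pd.DataFrame:
    """One row per assigned site: tf_id, site, D, polymorphic."""
    rows = []
    for tf, sites in assignments.items():
        for a in sites:
            mat = freq_table.site_frequencies(a.chrom, a.start, a.window_seq)
            rows.append(
                {
                    "tf_id": tf,
                    "site": a.site,
                    "chrom": a.chrom,
                    "start": a.start,
                    "diversity": shannon_diversity(mat),
                    "polymorphic": is_polymorphic(mat),
                }
            )
    return pd.DataFrame(rows, columns=["tf_id", "site", "chrom", "start", "diversity", "polymorphic"])


def per_tf_diversity(records: pd.DataFrame, summary: str = "mean") -> pd.DataFrame:
    """Per-TF diversity of polymorphic binding sites (mean by default)."""
    poly = records[records["polymorphic"]]
    agg = poly.groupby("tf_id")["diversity"].agg(summary).rename("diversity")
    counts = records.groupby("tf_id").size().rename("n_sites")
    n_poly = poly.groupby("tf_id").size().rename("n_polymorphic")
    return pd.concat([agg, n_poly, counts], axis=1).reset_index().dropna(subset=["diversity"])


# ---------------------------------------------------------------------------
# Correlations between network structure and diversity
# ---------------------------------------------------------------------------


def partial_spearman(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> tuple[float, float]:
    """Partial Spearman correlation of x and y controlling for z.

    Computed as the Pearson partial correlation of rank-transformed
    variables; the p-value is two-sided from a t distribution with
    n − 3 degrees of freedom.  Equals the plain Spearman correlation
    when z is constant.
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    n = len(x)
    if n < 4:
        raise InsufficientDataError("need at least 4 observations")
    rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))

    def _pearson(a, b):
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    rxy, rxz, ryz = _pearson(rx, ry), _pearson(rx, rz), _pearson(ry, rz)
    if rz.std() == 0:  # constant control -> plain Spearman
        r = rxy
        dof = n - 2
    else:
        den = np.sqrt((1 - rxz**2) * (1 - ryz**2))
        r = (rxy - rxz * ryz) / den if den > 0 else np.nan
        dof = n - 3
    if not np.isfinite(r) or abs(r) >= 1:
        p = 0.0 if np.isfinite(r) else np.nan
    else:
        t = r * np.sqrt(dof / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), dof))
    return float(r), p


def structure_diversity_correlations(
    intra: pd.DataFrame, diversity: pd.DataFrame
) -> pd.DataFrame:
    """Rank correlations of per-TF diversity with network structure.

    Diversity vs dominant-network size (plain Spearman), and vs
    characteristic path length, route factor, and assortativity as
    partial Spearman correlations controlling for size.
    """
    merged = intra.merge(diversity, on="tf_id")
    merged = merged.dropna(subset=["diversity", "dominant_size"])
    if len(merged) < 4:
        raise InsufficientDataError(f"only {len(merged)} TFs with data; need >= 4")
    d = merged["diversity"].to_numpy()
    size = merged["dominant_size"].to_numpy(dtype=float)
    rows = []
    rho, p = stats.spearmanr(d, size)
    rows.append({"metric": "dominant_size", "controlled_for": "", "rho": float(rho), "p": float(p), "n": len(merged)})
    for col in ("char_path_length", "route_factor", "assortativity"):
        sub = merged.dropna(subset=[col])
        if len(sub) < 4:
            continue
        rho, p = partial_spearman(
            sub["diversity"].to_numpy(), sub[col].to_numpy(dtype=float), sub["dominant_size"].to_numpy(dtype=float)
        )
        rows.append({"metric": col, "controlled_for": "dominant_size", "rho": rho, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)
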