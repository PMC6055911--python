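"""Synthetic inputs with the statistical structure the pipeline assumes.

The E-score generator plants, for each TF, a motif-centered affinity
landscape that decays with *graph distance* in the genotype space (so
shift-indel structure is exercised, not just Hamming shells):

    E(tf, s) = clip(base - decay * d(s, consensus_tf) + noise, -0.5, 0.5)

With zero noise the bound set at threshold tau is exactly a
graph-distance ball (or an exact-size prefix of one), hence connected.
The in-vivo generator emits promoter-overlapping footprints containing
planted bound sites and SNP allele frequencies whose per-TF diversity
follows a configurable function of genotype-network structure; truth
records carry everything needed for closed-form downstream checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .diversity import AlleleFrequencyTable, Footprint
from .networks import dominant_network, path_metrics
from .pbm_io import DEFAULT_TAU, EScoreTable, GenotypeSet, TFRecord, bound_sites
from .space import BASES, GenotypeSpace, canonical

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class SpecError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic E-score landscape."""

    n_tfs: int
    seed: int = 0
    k: int = 8
    domains: Sequence[str] | None = None  # cycled over TFs when shorter
    species: str = "synthetica"
    consensus_sites: Sequence[str | tuple[str, ...]] | None = None
    base_score: float = 0.45
    decay: float | Sequence[float] = 0.03
    noise_sd: float = 0.0
    target_set_sizes: Sequence[int] | None = None
    tau: float = DEFAULT_TAU

    def __post_init__(self):
        if self.n_tfs < 1:
            raise SpecError("n_tfs must be >= 1")
        decays = np.atleast_1d(np.asarray(self.decay, dtype=float))
        if (decays <= 0).any():
            raise SpecError("decay must be positive")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")

    def tf_ids(self) -> list[str]:
        width = len(str(self.n_tfs))
        return [f"TF{i + 1:0{width}d}" for i in range(self.n_tfs)]

    def decay_for(self, t: int) -> float:
        decays = np.atleast_1d(np.asarray(self.decay, dtype=float))
        return float(decays[t % len(decays)])


def decay_for_radius(radius: int, base: float = 0.45, tau: float = DEFAULT_TAU) -> float:
    """Decay at which the noise-free bound set is the radius-``radius`` ball."""
    return (base - tau) / (radius + 0.5)


def generate_metadata(spec: SyntheticSpec) -> dict[str, TFRecord]:
    domains = list(spec.domains) if spec.domains else ["DomA", "DomB", "DomC"]
    return {
        tf: TFRecord(tf, spec.species, domains[i % len(domains)])
        for i, tf in enumerate(spec.tf_ids())
    }


def _random_consensus(rng: np.random.Generator, space: GenotypeSpace) -> str:
    return space.sites[int(rng.integers(space.n_sites))]


def generate_escore_table(
    spec: SyntheticSpec, space: GenotypeSpace
) -> tuple[EScoreTable, dict]:
    """Planted motif-centered E-score table plus its truth record.

    A consensus entry may be a tuple of sites, in which case the
    distance is the minimum over them (planting a multi-cluster set).
    With ``target_set_sizes`` the noise-free bound set is exactly the
    requested number of sites closest to the consensus (distance then
    lexicographic order); a ``SpecError`` is raised when the needed
    distance cannot clear the threshold at the given decay.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.k != space.k:
        raise SpecError(f"spec k={spec.k} does not match space k={space.k}")
    tf_ids = spec.tf_ids()
    consensuses: list[tuple[str, ...]] = []
    for t in range(spec.n_tfs):
        if spec.consensus_sites is not None:
            c = spec.consensus_sites[t]
            consensuses.append((canonical(c),) if isinstance(c, str) else tuple(canonical(x) for x in c))
        else:
            consensuses.append((_random_consensus(rng, space),))
    scores = np.empty((space.n_sites, spec.n_tfs))
    truth_tfs = {}
    dist_arrays = []
    for t, tf in enumerate(tf_ids):
        decay = spec.decay_for(t)
        dists = np.minimum.reduce(
            [space.bfs_from(space.index_of(c)) for c in consensuses[t]]
        ).astype(float)
        dist_arrays.append(dists)
        col = spec.base_score - decay * dists
        planted_size = None
        if spec.target_set_sizes is not None:
            target = int(spec.target_set_sizes[t])
            if not 1 <= target <= space.n_sites:
                raise SpecError(f"target set size {target} out of range for {tf}")
            order = np.lexsort((space.codes, dists))  # by distance then site
            chosen = order[:target]
            dmax = dists[chosen[-1]]
            if spec.base_score - decay * dmax <= spec.tau:
                raise SpecError(
                    f"{tf}: target size {target} needs distance {int(dmax)} "
                    f"but base - decay * d <= tau there"
                )
            excluded = np.ones(space.n_sites, dtype=bool)
            excluded[chosen] = False
            col[excluded] = np.minimum(col[excluded], spec.tau)
            planted_size = target
        elif spec.noise_sd == 0:
            planted_size = int((col > spec.tau).sum())
        if spec.noise_sd > 0:
            col = col + rng.normal(0.0, spec.noise_sd, size=space.n_sites)
        scores[:, t] = np.clip(col, -0.5, 0.5)
        truth_tfs[tf] = {
            "consensus": list(consensuses[t]),
            "decay": decay,
            "planted_size": planted_size,
        }
    frame = pd.DataFrame(scores, index=pd.Index(space.sites, name="8mer"), columns=tf_ids)
    consensus_distances = {}
    for a in range(spec.n_tfs):
        for b in range(a + 1, spec.n_tfs):
            # reuse TF a's min-distance field instead of per-pair BFS
            d = min(int(dist_arrays[a][space.index_of(cb)]) for cb in consensuses[b])
            consensus_distances[f"{tf_ids[a]}|{tf_ids[b]}"] = d
    truth = {
        "seed": spec.seed,
        "base_score": spec.base_score,
        "noise_sd": spec.noise_sd,
        "tau": spec.tau,
        "tfs": truth_tfs,
        "consensus_distances": consensus_distances,
    }
    return EScoreTable(frame, k=spec.k), truth


@dataclass
class InVivoSpec:
    """Parameters of the synthetic in-vivo data."""

    seed: int = 0
    footprints_per_tf: int = 6
    footprint_length: int = 20
    planted_site_prob: float = 1.0
    diversity_intercept: float = 0.45
    diversity_effect_path_length: float = 0.0  # slope on z-scored network L
    diversity_effect_size: float = 0.0  # slope on z-scored network size
    diversity_noise_sd: float = 0.05
    n_short_decoys: int = 0
    n_nonpromoter_decoys: int = 0
    chrom: str = "synth1"
    gap: int = 10

    def __post_init__(self):
        if self.footprints_per_tf < 1 or self.footprint_length < 8:
            raise SpecError("need >= 1 footprint per TF of length >= 8")
        if not 0.0 <= self.planted_site_prob <= 1.0:
            raise SpecError("planted_site_prob must be in [0, 1]")


@dataclass
class InVivoData:
    footprints: list[Footprint]
    promoters: list[tuple[str, int, int]]
    genome: dict[str, str]
    freqs: AlleleFrequencyTable
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "footprints": outdir / "footprints.bed",
            "promoters": outdir / "promoters.bed",
            "genome": outdir / "genome.fa",
            "vcf": outdir / "snps.vcf",
            "truth": outdir / "truth.json",
        }
        with open(paths["footprints"], "w") as fh:
            for fp in self.footprints:
                fh.write(f"{fp.chrom}\t{fp.start}\t{fp.end}\t{fp.name}\n")
        with open(paths["promoters"], "w") as fh:
            for chrom, start, end in self.promoters:
                fh.write(f"{chrom}\t{start}\t{end}\n")
        with open(paths["genome"], "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        write_vcf(self.freqs, self.genome, paths["vcf"])
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return paths


def write_vcf(freqs: AlleleFrequencyTable, genome: Mapping[str, str], path: str | Path) -> None:
    """Minimal sites-only VCF 4.2 with biallelic SNPs and AF INFO tags."""
    records = []
    for (chrom, pos), freq in sorted(freqs.freqs.items()):
        ref = genome[chrom][pos]
        ref_i = _BASE_INDEX[ref]
        alt_is = [i for i in range(4) if i != ref_i and freq[i] > 0]
        if not alt_is:
            continue
        alts = ",".join(BASES[i] for i in alt_is)
        afs = ",".join(f"{freq[i]:.6f}" for i in alt_is)
        records.append((chrom, pos + 1, ref, alts, afs))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, seq in genome.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alts, afs in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alts}\t.\tPASS\tAF={afs}\n")


def _binary_entropy_freq(h: float) -> float:
    """Minor-allele frequency whose binary entropy is ``h`` bits."""
    if not 0.0 < h <= 1.0:
        raise SpecError(f"per-position entropy target {h} outside (0, 1]")
    if h == 1.0:
        return 0.5
    f = lambda p: -p * np.log2(p) - (1 - p) * np.log2(1 - p) - h
    return float(brentq(f, 1e-12, 0.5))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_invivo(
    ivspec: InVivoSpec,
    table: EScoreTable,
    space: GenotypeSpace,
    tau: float = DEFAULT_TAU,
) -> InVivoData:
    """Footprints with planted bound sites plus matched SNP frequencies.

    Per-TF target diversity is
    ``intercept + b_L * z(L) + b_size * z(size) + noise`` (clipped to
    (0, 1)); every position of a planted site is made biallelic with the
    minor-allele frequency whose entropy equals the target, so the
    site's diversity equals the target exactly at zero frequency noise.
    """
    rng = np.random.default_rng(ivspec.seed)
    tf_ids = table.tf_ids
    bound = {}
    net_size = np.empty(len(tf_ids))
    net_L = np.empty(len(tf_ids))
    for t, tf in enumerate(tf_ids):
        gset = bound_sites(table, tf, tau)
        if len(gset) == 0:
            raise SpecError(f"{tf} binds nothing at tau={tau}; cannot plant footprints")
        net = dominant_network(gset, space)
        bound[tf] = net.sites
        net_size[t] = net.n
        net_L[t] = path_metrics(net)[1]
    # the path-length effect is planted on the rank-scale component of L
    # orthogonal to network size, so the planted quantity is a *partial*
    # effect and stays recoverable after controlling for size
    from scipy.stats import rankdata

    z_L = _zscore(rankdata(net_L))
    z_size = _zscore(rankdata(net_size))
    r_ls = float(np.mean(z_L * z_size))
    z_L_resid = _zscore(z_L - r_ls * z_size)
    target_d = np.clip(
        ivspec.diversity_intercept
        + ivspec.diversity_effect_path_length * z_L_resid
        + ivspec.diversity_effect_size * z_size
        + rng.normal(0.0, ivspec.diversity_noise_sd, size=len(tf_ids)),
        0.02,
        0.98,
    )

    footprints: list[Footprint] = []
    freqs = AlleleFrequencyTable()
    chrom_parts: list[str] = []
    cursor = 0
    planted: dict[str, list[dict]] = {tf: [] for tf in tf_ids}

    def _emit(seq: str, name: str) -> Footprint:
        nonlocal cursor
        start = cursor
        chrom_parts.append(seq)
        cursor += len(seq)
        gap = "".join(rng.choice(list(BASES), size=ivspec.gap))
        chrom_parts.append(gap)
        cursor += ivspec.gap
        return Footprint(ivspec.chrom, start, start + len(seq), sequence=seq, name=name)

    for t, tf in enumerate(tf_ids):
        for j in range(ivspec.footprints_per_tf):
            seq = "".join(rng.choice(list(BASES), size=ivspec.footprint_length))
            rec = {"tf": tf, "planted": False}
            if rng.random() < ivspec.planted_site_prob:
                site = bound[tf][int(rng.integers(len(bound[tf])))]
                strand_seq = site if rng.random() < 0.5 else _revcomp(site)
                off = int(rng.integers(ivspec.footprint_length - space.k + 1))
                seq = seq[:off] + strand_seq + seq[off + space.k :]
                rec.update(planted=True, site=site, offset=off)
            fp = _emit(seq, f"{tf}_fp{j}")
            footprints.append(fp)
            if rec["planted"]:
                rec["start"] = fp.start + rec["offset"]
                minor = _binary_entropy_freq(float(target_d[t]))
                for i in range(space.k):
                    pos = rec["start"] + i
                    if (ivspec.chrom, pos) in freqs.freqs:
                        continue  # overlapping plants keep the first frequencies
                    ref = seq[rec["offset"] + i]
                    alt = BASES[(_BASE_INDEX[ref] + int(rng.integers(1, 4))) % 4]
                    vec = np.zeros(4)
                    vec[_BASE_INDEX[ref]] = 1.0 - minor
                    vec[_BASE_INDEX[alt]] = minor
                    freqs.set(ivspec.chrom, pos, vec)
            planted[tf].append(rec)

    for j in range(ivspec.n_short_decoys):
        seq = "".join(rng.choice(list(BASES), size=space.k - 1))
        footprints.append(_emit(seq, f"short_decoy{j}"))
    promoter_end = cursor
    for j in range(ivspec.n_nonpromoter_decoys):
        seq = "".join(rng.choice(list(BASES), size=ivspec.footprint_length))
        footprints.append(_emit(seq, f"nonpromoter_decoy{j}"))

    genome = {ivspec.chrom: "".join(chrom_parts)}
    promoters = [(ivspec.chrom, 0, promoter_end)]
    truth = {
        "seed": ivspec.seed,
        "per_tf": {
            tf: {
                "target_diversity": float(target_d[t]),
                "network_size": float(net_size[t]),
                "char_path_length": float(net_L[t]),
                "footprints": planted[tf],
            }
            for t, tf in enumerate(tf_ids)
        },
        "effects": {
            "path_length": ivspec.diversity_effect_path_length,
            "size": ivspec.diversity_effect_size,
            "noise_sd": ivspec.diversity_noise_sd,
        },
    }
    return InVivoData(footprints, promoters, genome, freqs, truth)


def _revcomp(s: str) -> str:
    from .space import revcomp

    return revcomp(s)
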