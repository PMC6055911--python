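"""Size-preserving randomization of site-to-phenotype assignments.

Each replicate reassigns every phenotype a uniform random sample of
sites (without replacement within a phenotype, independently across
phenotypes), keeping genotype-set sizes exactly.  Statistics computed
on the replicates form null distributions against which the empirical
values are ranked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .pbm_io import GenotypeSet
from .space import GenotypeSpace

DEFAULT_REPS = 1000


class ImpossibleSizeError(ValueError):
    pass


def randomize_assignment(
    sets: Sequence[GenotypeSet],
    space: GenotypeSpace,
    rng: int | np.random.Generator = 0,
    universe: str = "space",
) -> list[GenotypeSet]:
    """One null replicate: same phenotype ids and sizes, random sites.

    ``universe='space'`` samples from all genotypes (the default, which
    makes the null expectation of phi equal the phenotype frequency
    f_q); ``universe='bound'`` permutes within the pool of empirically
    bound sites instead.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if universe == "space":
        pool = np.arange(space.n_sites)
        pool_sites = space.sites
    elif universe == "bound":
        union: set[str] = set()
        for s in sets:
            union |= s.sites
        pool_sites = sorted(union)
        pool = np.arange(len(pool_sites))
    else:
        raise ValueError(f"unknown universe {universe!r}")
    out = []
    for s in sets:
        if len(s) > len(pool):
            raise ImpossibleSizeError(
                f"set {s.phenotype_id!r} has {len(s)} sites but universe has {len(pool)}"
            )
        chosen = rng.choice(pool, size=len(s), replace=False)
        out.append(GenotypeSet(s.phenotype_id, frozenset(pool_sites[i] for i in chosen)))
    return out


def null_ensemble(
    sets: Sequence[GenotypeSet],
    space: GenotypeSpace,
    n_reps: int = DEFAULT_REPS,
    seed: int = 0,
    universe: str = "space",
) -> Iterator[list[GenotypeSet]]:
    """Lazy stream of ``n_reps`` independent randomized replicates."""
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        yield randomize_assignment(sets, space, rng, universe=universe)


@dataclass(frozen=True)
class NullSummary:
    metric: str
    empirical: float
    null_mean: float
    null_sd: float
    q05: float
    q95: float
    percentile: float  # empirical value's percentile within the null
    n_reps: int
    n_excluded: int


def null_distribution(
    metric_fn: Callable[[list[GenotypeSet]], float],
    ensemble: Iterable[list[GenotypeSet]],
    empirical: float,
    metric_name: str = "metric",
) -> NullSummary:
    """Summarize ``metric_fn`` over the replicates and rank the empirical
    value; replicates where the metric is NaN are excluded and counted.
    """
    values = []
    n_excluded = 0
    for rep_sets in ensemble:
        v = metric_fn(rep_sets)
        if v is None or not np.isfinite(v):
            n_excluded += 1
        else:
            values.append(float(v))
    arr = np.array(values)
    if len(arr) == 0:
        return NullSummary(metric_name, empirical, np.nan, np.nan, np.nan, np.nan, np.nan, 0, n_excluded)
    percentile = float(np.mean(arr <= empirical) * 100.0)
    return NullSummary(
        metric=metric_name,
        empirical=empirical,
        null_mean=float(arr.mean()),
        null_sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        q05=float(np.quantile(arr, 0.05)),
        q95=float(np.quantile(arr, 0.95)),
        percentile=percentile,
        n_reps=len(arr),
        n_excluded=n_excluded,
    )


def null_phi_expectation(
    sets: Sequence[GenotypeSet] | Mapping[str, Iterable[str]],
    space: GenotypeSpace,
) -> pd.Series:
    """Phenotype frequencies f_q = |S(G_q)| / |space|, the null value of
    phi_qp (and of phi_unbound for the unbound set)."""
    if isinstance(sets, Mapping):
        items = [(q, len(set(v))) for q, v in sets.items()]
    else:
        items = [(s.phenotype_id, len(s)) for s in sets]
    return pd.Series({q: n / space.n_sites for q, n in items}, name="f_q")


def summaries_to_frame(summaries: Iterable[NullSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
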