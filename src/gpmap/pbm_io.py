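"""Protein-binding-microarray E-score tables and TF metadata.

E-scores are rank-based binding statistics in [−0.5, 0.5], one per
canonical double-stranded 8-mer per TF.  A threshold ``tau`` (default
0.35, strict inequality) turns a TF column into a genotype set: the
sites the TF binds specifically.

Two tab-separated dialects are accepted and auto-detected:

* per-TF files with columns ``8mer  8mer_rc  E-score`` (reverse
  complement column optional), one TF per file;
* a wide matrix with header ``8mer  TF1  TF2 ...``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import space as space_mod
from .space import GenotypeSpace, canonical

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.35
ESCORE_MIN, ESCORE_MAX = -0.5, 0.5


class EScoreRangeError(ValueError):
    """A score lies outside [−0.5, 0.5]."""


class EScoreConsistencyError(ValueError):
    """A site and its reverse complement carry conflicting scores."""


class EScoreParseError(ValueError):
    """Malformed row or unreadable layout."""


class IncompleteTableError(ValueError):
    """A TF column does not cover every canonical k-mer."""


@dataclass(frozen=True)
class TFRecord:
    tf_id: str
    species: str
    domain: str


@dataclass(frozen=True)
class GenotypeSet:
    """The set of genotypes with a given phenotype (TF or domain)."""

    phenotype_id: str
    sites: frozenset[str]

    def __len__(self) -> int:
        return len(self.sites)

    def indices(self, space: GenotypeSpace) -> np.ndarray:
        return space.indices_of(self.sites)


class EScoreTable:
    """TF × canonical-site affinity matrix.

    ``scores`` is a DataFrame indexed by canonical k-mer (sorted), one
    column per TF.  NaN entries are allowed only for tables loaded with
    ``allow_missing`` and are treated as unbound.
    """

    def __init__(self, scores: pd.DataFrame, k: int = 8, allow_missing: bool = False):
        scores = scores.sort_index()
        scores.index.name = "8mer"
        bad = scores.stack(future_stack=True).dropna()
        bad = bad[(bad < ESCORE_MIN) | (bad > ESCORE_MAX)]
        if len(bad):
            site, tf = bad.index[0]
            raise EScoreRangeError(
                f"E-score {bad.iloc[0]} for ({tf}, {site}) "
                f"outside [{ESCORE_MIN}, {ESCORE_MAX}]"
            )
        n_expected = len(space_mod.enumerate_space(k))
        if not allow_missing:
            missing = scores.isna().any(axis=0)
            if len(scores) != n_expected or missing.any():
                raise IncompleteTableError(
                    f"table covers {len(scores)} sites with NaNs in "
                    f"{list(scores.columns[missing])}; expected {n_expected} "
                    "complete sites (use allow_missing to treat gaps as unbound)"
                )
        elif len(scores) != n_expected or scores.isna().any().any():
            logger.warning("incomplete E-score table: missing entries treated as unbound")
        self.scores = scores
        self.k = k

    @property
    def tf_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def sites(self) -> list[str]:
        return list(self.scores.index)

    def score(self, tf_id: str, site: str) -> float:
        return float(self.scores.at[canonical(site), tf_id])

    def write(self, path: str | os.PathLike) -> None:
        """Write the wide-matrix dialect (round-trips exactly)."""
        out = self.scores.copy()
        out.index.name = "8mer"
        out.to_csv(path, sep="\t", float_format="%.17g")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EScoreTable) and self.scores.equals(other.scores)


def _canonicalize_frame(df: pd.DataFrame, k: int, path: str) -> pd.DataFrame:
    """Map site index to canonical form, checking RC-pair score agreement."""
    try:
        canon = [canonical(s) for s in df.index]
    except Exception as exc:  # invalid k-mer in the site column
        raise EScoreParseError(f"{path}: bad site column: {exc}") from exc
    if any(len(s) != k for s in canon):
        raise EScoreParseError(f"{path}: sites are not length-{k}")
    df = df.set_axis(canon, axis=0)
    dup = df.index.duplicated(keep=False)
    if dup.any():
        grouped = df[dup].groupby(level=0)
        spread = grouped.max() - grouped.min()
        conflict = spread.max(axis=1) > 1e-9
        if conflict.any():
            site = conflict.idxmax()
            raise EScoreConsistencyError(
                f"{path}: conflicting scores for reverse-complement pair of {site}"
            )
        df = df[~df.index.duplicated(keep="first")]
    return df


def read_escore_table(
    path: str | os.PathLike,
    dialect: str = "auto",
    tf_id: str | None = None,
    k: int = 8,
    allow_missing: bool = False,
) -> EScoreTable:
    """Read one E-score file in either dialect.

    ``dialect`` is one of ``auto``, ``wide`` or ``uniprobe``.  For the
    per-TF dialect the TF identifier defaults to the file stem.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    except Exception as exc:
        raise EScoreParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise EScoreParseError(f"{path}: expected at least two tab-separated columns")
    if dialect == "auto":
        second = df.iloc[:, 1].astype(str)
        looks_rc = second.str.fullmatch("[ACGTacgt]+").all()
        dialect = "uniprobe" if (looks_rc or df.shape[1] <= 3 and "score" in df.columns[-1].lower()) else "wide"
        if not looks_rc and df.shape[1] > 2:
            dialect = "wide"
    if dialect == "uniprobe":
        name = tf_id or path.stem
        score_col = df.columns[-1]
        sub = df.set_index(df.columns[0])[[score_col]].rename(columns={score_col: name})
        sub[name] = pd.to_numeric(sub[name], errors="raise")
        frame = _canonicalize_frame(sub, k, str(path))
    elif dialect == "wide":
        frame = df.set_index(df.columns[0]).apply(pd.to_numeric, errors="raise")
        frame = _canonicalize_frame(frame, k, str(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return EScoreTable(frame, k=k, allow_missing=allow_missing)


def read_escore_dir(
    directory: str | os.PathLike, k: int = 8, allow_missing: bool = False
) -> EScoreTable:
    """Read a directory of per-TF E-score files into one table."""
    paths = sorted(Path(directory).glob("*.t*sv")) or sorted(Path(directory).glob("*.txt"))
    if not paths:
        raise EScoreParseError(f"no E-score files found in {directory}")
    frames = [
        read_escore_table(p, dialect="uniprobe", k=k, allow_missing=True).scores
        for p in paths
    ]
    merged = pd.concat(frames, axis=1)
    return EScoreTable(merged, k=k, allow_missing=allow_missing)


def read_tf_metadata(path: str | os.PathLike) -> dict[str, TFRecord]:
    """TSV with columns tf_id, species, domain."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"tf_id", "species", "domain"}
    if not required.issubset(df.columns):
        raise EScoreParseError(f"{path}: metadata needs columns {sorted(required)}")
    if df["tf_id"].duplicated().any():
        dupes = df.loc[df["tf_id"].duplicated(), "tf_id"].tolist()
        raise EScoreParseError(f"{path}: duplicate tf_id entries {dupes}")
    return {
        row.tf_id: TFRecord(row.tf_id, row.species, row.domain)
        for row in df.itertuples()
    }


def write_tf_metadata(meta: Mapping[str, TFRecord], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [(r.tf_id, r.species, r.domain) for r in meta.values()],
        columns=["tf_id", "species", "domain"],
    ).to_csv(path, sep="\t", index=False)


def bound_sites(table: EScoreTable, tf_id: str, tau: float = DEFAULT_TAU) -> GenotypeSet:
    """Sites the TF binds specifically: strict ``E > tau``."""
    if tf_id not in table.scores.columns:
        raise KeyError(f"unknown TF {tf_id!r}")
    col = table.scores[tf_id]
    return GenotypeSet(tf_id, frozenset(col.index[col > tau]))


def unbound_sites(
    table: EScoreTable, tf_ids: Iterable[str] | None = None, tau: float = DEFAULT_TAU
) -> GenotypeSet:
    """Sites bound by no TF in ``tf_ids`` (default: all TFs in the table)."""
    tf_ids = list(tf_ids) if tf_ids is not None else table.tf_ids
    if not tf_ids:
        raise ValueError("tf_ids must be non-empty")
    any_bound = (table.scores[tf_ids] > tau).any(axis=1)
    return GenotypeSet("unbound", frozenset(any_bound.index[~any_bound]))


def unbound_fraction(table: EScoreTable, tau: float = DEFAULT_TAU) -> float:
    return len(unbound_sites(table, tau=tau)) / len(table.sites)
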