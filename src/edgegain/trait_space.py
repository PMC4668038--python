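"""Trait matrices, Gower dissimilarity with missing data, and NJ trait trees.

Trait diversity (TD) is measured exactly like phylogenetic diversity, but on
a dendrogram built from species' ecological/life-history traits instead of a
phylogeny: mixed continuous/categorical traits -> Gower distance matrix ->
neighbour-joining tree -> sum of (persistence-weighted) branch lengths.

Missing data are the norm in trait compilations, so Gower distances are
computed by pairwise deletion (only traits observed in both species enter a
pair's distance), and pairs sharing no observed trait fall back to the mean
distance over all computable pairs.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .trees import PhyloTree, read_newick

logger = logging.getLogger(__name__)

__all__ = ["TraitMatrix", "filter_by_completeness", "select_orthogonal_traits",
           "trait_association_matrix", "gower_distance", "nj_tree",
           "aggregate_records"]

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class TraitMatrix:
    """Species x trait table with per-column type (continuous | categorical).

    ``data`` holds one row per species (index = species id); continuous
    columns are float with NaN for missing, categorical columns are strings
    with NaN/None for missing.
    """

    data: pd.DataFrame
    kinds: Mapping[str, str]

    def __post_init__(self):
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("need at least one species and one trait")
        if set(self.data.columns) != set(self.kinds):
            raise ValueError("kinds must cover exactly the trait columns")
        bad = {c: k for c, k in self.kinds.items() if k not in (CONTINUOUS, CATEGORICAL)}
        if bad:
            raise ValueError(f"unknown trait kinds: {bad}")
        for c, k in self.kinds.items():
            if k == CONTINUOUS:
                col = pd.to_numeric(self.data[c], errors="raise")
                if np.isinf(col.dropna()).any():
                    raise ValueError(f"continuous trait {c!r} contains infinities")

    # ------------------------------------------------------------------ views
    @property
    def species(self) -> list[str]:
        return self.data.index.astype(str).tolist()

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_observed(self) -> pd.Series:
        """Observed trait count per species."""
        return self.data.notna().sum(axis=1)

    @property
    def completeness(self) -> float:
        """Fraction of non-missing cells."""
        return float(self.data.notna().values.mean())

    def subset_traits(self, traits: Sequence[str]) -> "TraitMatrix":
        return TraitMatrix(self.data[list(traits)],
                           {t: self.kinds[t] for t in traits})

    def subset_species(self, species: Sequence[str]) -> "TraitMatrix":
        return TraitMatrix(self.data.loc[list(species)], dict(self.kinds))

    # -------------------------------------------------------------------- io
    @classmethod
    def read_tsv(cls, path: str | Path) -> "TraitMatrix":
        raw = pd.read_csv(path, sep="\t", dtype=str)
        if raw.iloc[0, 0] != "!type":
            raise ValueError("second line must be a '!type' row naming each "
                             "column continuous or categorical")
        kinds = dict(zip(raw.columns[1:], raw.iloc[0, 1:]))
        df = raw.iloc[1:].set_index(raw.columns[0])
        df.index.name = "species"
        for c, k in kinds.items():
            if k == CONTINUOUS:
                df[c] = pd.to_numeric(df[c])
        return cls(df, kinds)

    def write_tsv(self, path: str | Path) -> None:
        df = self.data.copy()
        type_row = pd.DataFrame([self.kinds], index=pd.Index(["!type"], name="species"))
        out = pd.concat([type_row, df.astype(object)])
        out.index.name = "species"
        out.to_csv(path, sep="\t")


def filter_by_completeness(matrix: TraitMatrix, min_present: int) -> TraitMatrix:
    """Keep species with at least ``min_present`` observed traits."""
    if not 0 <= min_present <= len(matrix.traits):
        raise ValueError(f"min_present must be in [0, {len(matrix.traits)}]")
    keep = matrix.n_observed >= min_present
    if not keep.any():
        raise ValueError("completeness filter removed every species")
    return TraitMatrix(matrix.data.loc[keep], dict(matrix.kinds))


def _pair_association(x: pd.Series, y: pd.Series, kx: str, ky: str) -> float:
    """|Pearson r| for continuous pairs; Cramer's V when a categorical is
    involved (continuous partners quartile-binned).  Pairwise-complete."""
    ok = x.notna() & y.notna()
    if ok.sum() < 3:
        return 0.0
    x, y = x[ok], y[ok]
    if kx == CONTINUOUS and ky == CONTINUOUS:
        if x.astype(float).std() == 0 or y.astype(float).std() == 0:
            return 0.0
        r = np.corrcoef(x.astype(float), y.astype(float))[0, 1]
        return float(abs(r))

    def as_levels(v: pd.Series, kind: str) -> pd.Series:
        if kind == CATEGORICAL:
            return v.astype(str)
        nbins = min(4, v.nunique())
        return pd.qcut(v.astype(float), nbins, duplicates="drop").astype(str)

    a, b = as_levels(x, kx), as_levels(y, ky)
    tab = pd.crosstab(a, b)
    if min(tab.shape) < 2:
        return 0.0
    chi2 = stats.chi2_contingency(tab.values, correction=False)[0]
    n = tab.values.sum()
    v = np.sqrt(chi2 / (n * (min(tab.shape) - 1)))
    return float(min(v, 1.0))


def trait_association_matrix(matrix: TraitMatrix) -> pd.DataFrame:
    """Symmetric trait x trait association strengths in [0, 1]."""
    traits = matrix.traits
    out = pd.DataFrame(0.0, index=traits, columns=traits)
    for a, b in combinations(traits, 2):
        v = _pair_association(matrix.data[a], matrix.data[b],
                              matrix.kinds[a], matrix.kinds[b])
        out.loc[a, b] = out.loc[b, a] = v
    return out


def select_orthogonal_traits(matrix: TraitMatrix, k: int) -> TraitMatrix:
    """Keep the ``k`` mutually least-associated traits.

    Backward greedy elimination: repeatedly drop the trait with the largest
    mean absolute association to the remaining traits until ``k`` are left.
    Ties drop the earlier column.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(matrix.traits):
        raise ValueError(f"k={k} exceeds the {len(matrix.traits)} available traits")
    assoc = trait_association_matrix(matrix)
    remaining = list(matrix.traits)
    while len(remaining) > k:
        sub = assoc.loc[remaining, remaining]
        mean_assoc = sub.sum(axis=1) / (len(remaining) - 1)
        remaining.remove(mean_assoc.idxmax())
    return matrix.subset_traits(remaining)


def gower_distance(matrix: TraitMatrix,
                   no_overlap_policy: str = "mean") -> DistanceMatrix:
    """Gower dissimilarity with pairwise deletion of missing traits.

    Per trait: continuous dissimilarity |x_i - x_j| / observed range,
    categorical 0/1 mismatch.  A pair's distance is the mean over the traits
    observed in both species.  Pairs sharing zero observed traits receive
    the mean of all computable pair distances (``no_overlap_policy='mean'``,
    the default) or NaN is an error (``'error'``).
    """
    sp = matrix.species
    n = len(sp)
    num = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for t in matrix.traits:
        col = matrix.data[t]
        obs = col.notna().values
        both = np.outer(obs, obs)
        if matrix.kinds[t] == CONTINUOUS:
            x = col.astype(float).values
            rng = np.nanmax(x) - np.nanmin(x) if obs.any() else 0.0
            if rng == 0:
                logger.warning("continuous trait %r has zero range; "
                               "it contributes 0 to all distances", t)
                d = np.zeros((n, n))
            else:
                xi = np.where(obs, x, 0.0)
                d = np.abs(xi[:, None] - xi[None, :]) / rng
        else:
            levels, codes = np.unique(col.astype(object).fillna("\0NA").values,
                                      return_inverse=True)
            d = (codes[:, None] != codes[None, :]).astype(float)
        num += np.where(both, d, 0.0)
        cnt += both
    with np.errstate(invalid="ignore"):
        dist = num / cnt
    np.fill_diagonal(dist, 0.0)
    no_overlap = (cnt == 0)
    np.fill_diagonal(no_overlap, False)
    if no_overlap.any():
        defined = dist[np.triu(~no_overlap, k=1)]
        if defined.size == 0:
            raise ValueError("no species pair shares any observed trait")
        if no_overlap_policy == "mean":
            dist[no_overlap] = defined.mean()
        else:
            raise ValueError(f"{int(no_overlap.sum() // 2)} pairs share no "
                             "observed trait and no_overlap_policy='error'")
    return DistanceMatrix(dist, ids=sp)


def nj_tree(d: DistanceMatrix | pd.DataFrame | np.ndarray,
            ids: Sequence[str] | None = None) -> PhyloTree:
    """Neighbour-joining (Saitou-Nei) tree from a distance matrix.

    Returns an unrooted tree (stored with an arbitrary internal anchor).
    Negative estimated branch lengths are clamped to zero.  On an additive
    matrix the generating tree is recovered exactly.
    """
    if not isinstance(d, DistanceMatrix):
        if isinstance(d, pd.DataFrame):
            values, labels = d.values, list(d.index)
        else:
            values, labels = np.asarray(d, float), list(ids) if ids else None
        if np.isnan(values).any():
            raise ValueError("distance matrix contains NaN")
        try:
            d = DistanceMatrix(values, ids=labels)
        except Exception as exc:
            raise ValueError(f"invalid distance matrix: {exc}") from exc
    if d.shape[0] < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if np.isnan(d.data).any():
        raise ValueError("distance matrix contains NaN")
    tnode = _skbio_nj(d)
    buf = io.StringIO()
    tnode.write(buf)
    tree = read_newick(buf.getvalue(), rooted=False)
    return tree


def aggregate_records(records: pd.DataFrame, kinds: Mapping[str, str],
                      by: str = "species") -> TraitMatrix:
    """Collapse multiple records per species: mean for continuous traits,
    mode for categorical (modal ties broken by first-sorted level)."""

    def modal(s: pd.Series):
        s = s.dropna()
        if s.empty:
            return np.nan
        counts = s.value_counts()
        top = counts[counts == counts.iloc[0]]
        return sorted(top.index)[0]

    agg = {}
    for c, k in kinds.items():
        agg[c] = "mean" if k == CONTINUOUS else modal
    df = records.groupby(by).agg(agg)
    df.index = df.index.astype(str)
    df.index.name = "species"
    return TraitMatrix(df, dict(kinds))
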