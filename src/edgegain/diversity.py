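"""Expected (future) diversity under extinction risk, and per-species scores.

The model: each species *i* carries a 100-year extinction probability
``p_i`` determined by its IUCN category.  A branch *b* of the tree persists
iff at least one tip descending from it survives, so, treating tip fates as
independent,

    P(b persists) = 1 - prod_{tips i under b} p_i

Expected diversity (future PD, or future TD on a trait dendrogram) is the
sum of branch lengths weighted by their persistence probabilities:

    E[PD] = sum_b  l_b * (1 - prod_{i under b} p_i)

Per-species scores follow the EDGE framework: evolutionary distinctiveness
(ED) is the fair-proportion apportionment of branch lengths, GE the ordinal
category score, and EDGE = ln(1 + ED) + GE * w with w = ln 2 by default.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import sparse

from .threat import (DD, DEFAULT_DD_PEXT, DEFAULT_PEXT, GE_SCORES,
                     ThreatTable, UnknownCategoryError)
from .trees import PhyloTree

__all__ = [
    "extinction_probability", "branch_persistence", "persistence_weighted_tree",
    "expected_diversity", "fair_proportion_ed", "ge_score", "edge_score",
    "threat_ed", "species_scores", "PersistenceEngine",
]

DEFAULT_EDGE_WEIGHT = math.log(2.0)


def extinction_probability(category: str,
                           pext_map: Mapping[str, float] = DEFAULT_PEXT) -> float:
    """Extinction probability for an ordinal IUCN category.

    DD has no place on the ordinal scale; callers must decide a DD policy
    (see ``ThreatTable.pext_vector``) before reaching this function.
    """
    if category == DD:
        raise UnknownCategoryError(
            "DD species have no default p(extinction); resolve DD explicitly")
    if category not in pext_map:
        raise UnknownCategoryError(f"unknown category {category!r}")
    return float(pext_map[category])


def ge_score(category: str) -> int:
    """Global endangerment ordinal: LC=0, NT=1, VU=2, EN=3, CR=4."""
    if category not in GE_SCORES:
        raise UnknownCategoryError(f"no GE ordinal for category {category!r}")
    return GE_SCORES[category]


def edge_score(ed: float, ge: int, weight: float = DEFAULT_EDGE_WEIGHT) -> float:
    """EDGE = ln(1 + ED) + GE * weight  (default weight ln 2)."""
    if ed < 0:
        raise ValueError(f"ED must be non-negative, got {ed}")
    return math.log1p(ed) + ge * weight


def branch_persistence(descendant_tip_pexts: Iterable[float]) -> float:
    """P(branch persists) = 1 - product of descendant tips' p(extinction)."""
    p = np.asarray(list(descendant_tip_pexts), dtype=float)
    if p.size == 0:
        raise ValueError("a branch must have at least one descendant tip")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("extinction probabilities must lie in [0, 1]")
    return float(1.0 - np.prod(p))


class PersistenceEngine:
    """Vectorised persistence weighting for repeated evaluation on one tree.

    Precomputes a sparse edge x tip incidence matrix so that, for any vector
    of tip extinction probabilities, per-edge log survival-failure products
    are a single sparse mat-vec.  All Monte-Carlo machinery funnels through
    this class; the scalar helpers above are the readable specification of
    what it computes.
    """

    def __init__(self, tree: PhyloTree):
        self.tree = tree
        self.tip_labels = tree.tip_labels
        n = tree.n_nodes
        tip_node = tree.tip_indices
        rows, cols = [], []
        for j, t in enumerate(tip_node):
            i = int(t)
            while i != 0:
                rows.append(i)
                cols.append(j)
                i = int(tree.parent[i])
        data = np.ones(len(rows))
        # rows: every non-root node; row i collects the tips under edge i
        self.incidence = sparse.csr_matrix(
            (data, (rows, cols)), shape=(n, len(tip_node)))
        self.lengths = tree.length
        # per-tip edge paths (node indices, tipward last), for greedy updates
        self._paths = [np.array(p, dtype=np.int64) for p in tree.tip_paths()]

    # ------------------------------------------------------------ evaluation
    def _validate_pext(self, pext: np.ndarray) -> np.ndarray:
        p = np.asarray(pext, dtype=float)
        if p.shape[0] != len(self.tip_labels):
            raise ValueError("pext vector length != number of tips")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("extinction probabilities must lie in [0, 1]")
        return p

    def edge_persistence(self, pext: np.ndarray) -> np.ndarray:
        """P(persist) per node's parent edge (root entry = 0, unused)."""
        p = self._validate_pext(pext)
        with np.errstate(divide="ignore"):
            logp = np.log(p)  # p=0 -> -inf -> product 0 -> persistence 1
        log_prod = self.incidence @ logp
        out = -np.expm1(log_prod)
        out[0] = 0.0
        return out

    def expected_diversity(self, pext: np.ndarray) -> float:
        return float(self.lengths @ self.edge_persistence(pext))

    # -------------------------------------------------- greedy-update support
    def make_state(self, pext: np.ndarray):
        """Per-edge (sum of finite log p, count of p=0 tips) for fast updates."""
        p = self._validate_pext(pext)
        zero = p == 0.0
        with np.errstate(divide="ignore"):
            logp = np.where(zero, 0.0, np.log(np.where(zero, 1.0, p)))
        log_sum = self.incidence @ logp
        n_zero = (self.incidence @ zero.astype(float)).round().astype(np.int64)
        return [p.copy(), log_sum, n_zero]

    @staticmethod
    def _prod(log_sum: float, n_zero: int) -> float:
        return 0.0 if n_zero > 0 else math.exp(log_sum)

    def state_expected_diversity(self, state) -> float:
        _, log_sum, n_zero = state
        prod = np.where(n_zero > 0, 0.0, np.exp(log_sum))
        pers = 1.0 - prod
        pers[0] = 0.0
        return float(self.lengths @ pers)

    def protect_gain(self, state, tip_j: int, p_new: float) -> float:
        """Increase in expected diversity if tip ``tip_j``'s p becomes ``p_new``."""
        p, log_sum, n_zero = state
        p_old = p[tip_j]
        if p_old == p_new:
            return 0.0
        gain = 0.0
        for i in self._paths[tip_j]:
            ls, nz = log_sum[i], n_zero[i]
            prod_old = self._prod(ls, nz)
            if p_old == 0.0:
                nz -= 1
            else:
                ls -= math.log(p_old)
            if p_new == 0.0:
                nz += 1
            else:
                ls += math.log(p_new)
            gain += self.lengths[i] * (prod_old - self._prod(ls, nz))
        return gain

    def apply_protection(self, state, tip_j: int, p_new: float) -> None:
        p, log_sum, n_zero = state
        p_old = p[tip_j]
        if p_old == p_new:
            return
        for i in self._paths[tip_j]:
            if p_old == 0.0:
                n_zero[i] -= 1
            else:
                log_sum[i] -= math.log(p_old)
            if p_new == 0.0:
                n_zero[i] += 1
            else:
                log_sum[i] += math.log(p_new)
        p[tip_j] = p_new


def _tip_pext(tree: PhyloTree, threat: ThreatTable,
              pext_map: Mapping[str, float], dd_pext: float) -> np.ndarray:
    return threat.pext_vector(tree.tip_labels, pext_map, dd_pext)


def persistence_weighted_tree(tree: PhyloTree, threat: ThreatTable,
                              pext_map: Mapping[str, float] = DEFAULT_PEXT,
                              dd_pext: float = DEFAULT_DD_PEXT) -> PhyloTree:
    """Rescale every branch by its persistence probability.

    Tip branches shrink toward zero for highly threatened species; interior
    branches by the probability that *all* descendant tips are lost.
    Topology and labels are unchanged.
    """
    engine = PersistenceEngine(tree)
    pers = engine.edge_persistence(_tip_pext(tree, threat, pext_map, dd_pext))
    return tree.with_lengths(tree.length * pers)


def expected_diversity(tree: PhyloTree, threat: ThreatTable,
                       pext_map: Mapping[str, float] = DEFAULT_PEXT,
                       dd_pext: float = DEFAULT_DD_PEXT) -> float:
    """Expected future diversity: total length of the persistence-weighted tree."""
    engine = PersistenceEngine(tree)
    return engine.expected_diversity(_tip_pext(tree, threat, pext_map, dd_pext))


def fair_proportion_ed(tree: PhyloTree) -> pd.Series:
    """Fair-proportion evolutionary distinctiveness per species.

    Each edge's length is split equally among the tips descending from it;
    a species' ED is the sum of its shares along the root-to-tip path.  The
    ED values over all species sum exactly to the tree's total branch length.
    """
    if not tree.rooted:
        raise ValueError("fair-proportion ED requires a rooted tree")
    counts = tree.subtree_tip_counts
    share = np.zeros(tree.n_nodes)
    share[1:] = tree.length[1:] / counts[1:]
    acc = np.zeros(tree.n_nodes)
    for i in range(1, tree.n_nodes):
        acc[i] = acc[tree.parent[i]] + share[i]
    ed = acc[tree.tip_indices]
    return pd.Series(ed, index=pd.Index(tree.tip_labels, name="species"), name="ED")


def threat_ed(tree: PhyloTree, threat: ThreatTable,
              pext_map: Mapping[str, float] = DEFAULT_PEXT,
              dd_pext: float = DEFAULT_DD_PEXT) -> pd.Series:
    """ED on the persistence-weighted tree: distinctiveness at risk of loss."""
    wtree = persistence_weighted_tree(tree, threat, pext_map, dd_pext)
    return fair_proportion_ed(wtree).rename("ThreatED")


def species_scores(tree: PhyloTree, threat: ThreatTable,
                   pext_map: Mapping[str, float] = DEFAULT_PEXT,
                   ge_weight: float = DEFAULT_EDGE_WEIGHT,
                   dd_pext: float = DEFAULT_DD_PEXT) -> pd.DataFrame:
    """Per-species score table: category, ED, GE, EDGE, ThreatED.

    DD species keep their ED/ThreatED (they sit in the tree) but get no GE
    or EDGE score and are excluded from ranking downstream.
    """
    ed = fair_proportion_ed(tree)
    ted = threat_ed(tree, threat, pext_map, dd_pext)
    cats = pd.Series({sp: threat.category(sp) for sp in ed.index}, name="category")
    ge = cats.map(GE_SCORES).astype("Float64")
    edge = pd.Series(np.log1p(ed) + ge.astype(float) * ge_weight,
                     index=ed.index, name="EDGE")
    df = pd.DataFrame({"category": cats, "ED": ed, "GE": ge,
                       "EDGE": edge, "ThreatED": ted})
    df.index.name = "species"
    return df
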