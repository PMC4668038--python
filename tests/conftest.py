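"""Shared fixtures and independent oracle implementations.

The oracles here recompute quantities by brute force (explicit tip-set
enumeration, exhaustive subset search, hand apportionment) and must stay
independent of the vectorised code paths they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

import edgegain as eg
from edgegain.threat import DEFAULT_PEXT


# --------------------------------------------------------------- tree oracles
def descendant_tips(tree: eg.PhyloTree, node: int) -> list[int]:
    """Tip node indices under ``node`` (inclusive), by explicit traversal."""
    kids: dict[int, list[int]] = {}
    for i in range(1, tree.n_nodes):
        kids.setdefault(int(tree.parent[i]), []).append(i)
    out, stack = [], [node]
    while stack:
        j = stack.pop()
        if tree.is_tip[j]:
            out.append(j)
        else:
            stack.extend(kids.get(j, []))
    return out


def naive_expected_diversity(tree: eg.PhyloTree, pext_by_label: dict[str, float]) -> float:
    """Per-edge tip-set enumeration: sum l_b * (1 - prod p_i under b)."""
    total = 0.0
    for node in range(1, tree.n_nodes):
        prod = 1.0
        for t in descendant_tips(tree, node):
            prod *= pext_by_label[tree.labels[t]]
        total += tree.length[node] * (1.0 - prod)
    return total


def naive_fair_proportion(tree: eg.PhyloTree) -> dict[str, float]:
    """Brute-force apportionment: each edge's length split over its tips."""
    ed = {lab: 0.0 for lab in tree.tip_labels}
    for node in range(1, tree.n_nodes):
        tips = descendant_tips(tree, node)
        share = tree.length[node] / len(tips)
        for t in tips:
            ed[tree.labels[t]] += share
    return ed


def exhaustive_best_protection(tree: eg.PhyloTree, threat: eg.ThreatTable,
                               n: int, protect_pext: float) -> float:
    """Exact optimum of expected diversity over all n-subsets of threatened
    species, each protected subset evaluated by the naive oracle."""
    pool = sorted(threat.threatened_species())
    best = -np.inf
    for subset in combinations(pool, n):
        pext = {}
        for sp in tree.tip_labels:
            cat = threat.category(sp)
            pext[sp] = protect_pext if sp in subset else DEFAULT_PEXT[cat]
        best = max(best, naive_expected_diversity(tree, pext))
    return best


# ------------------------------------------------------------------- fixtures
@pytest.fixture
def rng():
    return np.random.default_rng(20250921)


@pytest.fixture
def cherry():
    """Two-tip tree with a unit interior edge below the root."""
    return eg.read_newick("((A:1,B:1):1);")


@pytest.fixture
def three_tip():
    return eg.read_newick("((A:1,B:1):1,C:3);")


def random_tree(n_tips: int, seed: int) -> eg.PhyloTree:
    cfg = eg.SyntheticConfig(n_species=n_tips, seed=seed)
    return eg.simulate_tree(cfg, np.random.default_rng(seed))


def random_threat(tree: eg.PhyloTree, seed: int, dd_fraction: float = 0.0) -> eg.ThreatTable:
    cfg = eg.SyntheticConfig(n_species=tree.n_tips, seed=seed,
                             dd_fraction=dd_fraction)
    return eg.assign_threat(tree, cfg, np.random.default_rng(seed))


def assert_gain_ordering(results, ordered_schemes, alpha=0.01):
    """Assert mean gains are in the given (non-increasing) scheme order.

    Stochastic ordering: each adjacent pair must either have means in order,
    or the lower-ranked scheme must not significantly exceed the higher one
    in a one-sided paired t-test across replicates.
    """
    from edgegain.future_sim import paired_gain_test
    means = {s: np.mean([r.gain[s] for r in results]) for s in ordered_schemes}
    for hi, lo in zip(ordered_schemes, ordered_schemes[1:]):
        if means[hi] >= means[lo]:
            continue
        _, p = paired_gain_test(results, lo, hi)
        assert p > alpha, (f"{lo} significantly exceeds {hi} "
                           f"(means {means[lo]:.4g} > {means[hi]:.4g}, p={p:.2g})")


@pytest.fixture(scope="session")
def small_bundle():
    """A 150-species community reused across scheme/simulation tests."""
    return eg.generate(eg.SyntheticConfig(n_species=150, seed=11))
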