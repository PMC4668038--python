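"""Synthetic mammal-like study systems: trees, threat tables, trait matrices.

The generator emulates the statistical shape of a desk-scale mammal dataset:
an ultrametric pure-birth (Yule) phylogeny of ~4920 species, Red List
category margins calibrated so that ~1350 species are threatened
(NT/VU/EN/CR), and a 10-trait matrix (7 continuous Brownian-motion traits,
3 categorical Markov-switch traits) with ~25% of cells missing completely at
random.  Continuous traits evolve along the tree, so trait distance
correlates with phylogenetic distance - the regime in which evolutionarily
distinct species tend to be trait-distinct.  An iid trait mode and a
phylogenetically clumped threat mode are included to probe those contrasts.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .threat import CATEGORIES, DD, THREATENED, ThreatTable
from .trait_space import CATEGORICAL, CONTINUOUS, TraitMatrix
from .trees import PhyloTree

__all__ = ["SyntheticConfig", "simulate_tree", "assign_threat",
           "simulate_traits", "generate", "make_fixture_bundle", "Bundle"]

#: Category frequencies calibrated so threatened (NT+VU+EN+CR) ~ 1350/4920.
DEFAULT_FREQS: dict[str, float] = {
    "LC": 0.7256, "NT": 0.0800, "VU": 0.0900, "EN": 0.0650, "CR": 0.0394,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic study system (defaults = mammal-like)."""

    n_species: int = 4920
    birth_rate: float = 1.0
    crown_age: float = 170.0          # tree depth; "million years" scale
    category_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FREQS))
    dd_fraction: float = 0.0
    clumped_threat: bool = False
    n_traits: int = 10
    n_categorical: int = 3
    n_levels: int = 3
    bm_rate: float = 1.0              # Brownian variance per unit time
    cat_switch_rate: float = 0.01     # Markov switch rate per unit time
    phylo_traits: bool = True         # False -> iid traits, no tree signal
    missingness: float = 0.25
    seed: int = 0

    def __post_init__(self):
        freqs = self.category_freqs
        if set(freqs) != set(CATEGORIES):
            raise ValueError(f"category_freqs must cover exactly {CATEGORIES}")
        vals = np.array(list(freqs.values()))
        if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("category frequencies must be >= 0 and sum to 1")
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.birth_rate <= 0 or self.crown_age <= 0 or self.bm_rate <= 0 \
                or self.cat_switch_rate <= 0:
            raise ValueError("rates and ages must be positive")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must lie in [0, 1)")
        if not 0 <= self.dd_fraction < 1:
            raise ValueError("dd_fraction must lie in [0, 1)")
        if not 0 <= self.n_categorical <= self.n_traits:
            raise ValueError("n_categorical must lie in [0, n_traits]")

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        return cls(**json.loads(Path(path).read_text()))


def _tip_name(i: int, width: int) -> str:
    return f"S{i + 1:0{width}d}"


def simulate_tree(config: SyntheticConfig, rng: np.random.Generator) -> PhyloTree:
    """Ultrametric pure-birth tree with ``n_species`` tips, rescaled so the
    root-to-tip depth equals ``crown_age``."""
    if config.n_species == 2:
        half = config.crown_age
        return PhyloTree([-1, 0, 0], [0.0, half, half], [None, "S1", "S2"])
    dseed = int(rng.integers(2 ** 31))
    dtree = treesim.birth_death_tree(
        birth_rate=config.birth_rate, death_rate=0.0,
        num_extant_tips=config.n_species, rng=random.Random(dseed))
    tree = PhyloTree.from_dendropy(dtree)
    depth = tree.node_depths()[tree.tip_indices].max()
    scaled = tree.with_lengths(tree.length * (config.crown_age / depth))
    width = len(str(config.n_species))
    labels = list(scaled.labels)
    for k, i in enumerate(scaled.tip_indices):
        labels[i] = _tip_name(k, width)
    return PhyloTree(scaled.parent, scaled.length, labels)


def assign_threat(tree: PhyloTree, config: SyntheticConfig,
                  rng: np.random.Generator) -> ThreatTable:
    """Red List categories per tip.

    Default: iid multinomial draw from ``category_freqs`` (after sprinkling
    DD at ``dd_fraction``).  Clumped mode concentrates threatened statuses
    inside randomly chosen clades until the same expected margins are met,
    emulating the taxonomic clustering of real-world threat.
    """
    labels = tree.tip_labels
    n = len(labels)
    cats = np.empty(n, dtype=object)
    dd_mask = rng.random(n) < config.dd_fraction
    free = np.flatnonzero(~dd_mask)
    freqs = config.category_freqs
    if not config.clumped_threat:
        probs = np.array([freqs[c] for c in CATEGORIES])
        draws = rng.choice(len(CATEGORIES), size=free.size, p=probs)
        cats[free] = [CATEGORIES[d] for d in draws]
    else:
        p_threat = sum(freqs[c] for c in CATEGORIES if c in THREATENED)
        target = int(round(p_threat * free.size))
        free_set = set(free.tolist())
        tip_row = {int(t): k for k, t in enumerate(tree.tip_indices)}
        # collect tips clade by clade until the threatened pool is full
        internal = [i for i in range(1, tree.n_nodes) if not tree.is_tip[i]
                    and 2 <= tree.subtree_tip_counts[i] <= max(2, target // 2)]
        rng.shuffle(internal)
        children: dict[int, list[int]] = {}
        for i in range(1, tree.n_nodes):
            children.setdefault(int(tree.parent[i]), []).append(i)
        pool: list[int] = []
        pooled: set[int] = set()
        for node in internal:
            if len(pool) >= target:
                break
            stack = [node]
            while stack:
                j = stack.pop()
                if tree.is_tip[j]:
                    if j in free_set and j not in pooled:
                        pooled.add(j)
                        pool.append(j)
                else:
                    stack.extend(children.get(j, []))
        if len(pool) < target:  # top up with random singletons
            rest = [i for i in free if i not in pooled]
            rng.shuffle(rest)
            pool.extend(rest[:target - len(pool)])
        pool = pool[:target]
        thr_cats = [c for c in CATEGORIES if c in THREATENED]
        p_thr = np.array([freqs[c] for c in thr_cats])
        p_thr = p_thr / p_thr.sum()
        draws = rng.choice(len(thr_cats), size=len(pool), p=p_thr)
        cats[:] = "LC"
        for j, d in zip(pool, draws):
            cats[j] = thr_cats[d]
    cats[dd_mask] = DD
    return ThreatTable(pd.Series(cats, index=labels))


def simulate_traits(tree: PhyloTree, config: SyntheticConfig,
                    rng: np.random.Generator) -> TraitMatrix:
    """Trait matrix: Brownian continuous traits and Markov-switch categorical
    traits evolved along the tree (or iid draws when ``phylo_traits=False``),
    then MCAR missingness."""
    labels = tree.tip_labels
    n_tips = len(labels)
    n_cont = config.n_traits - config.n_categorical
    levels = [chr(ord("A") + i) for i in range(config.n_levels)]

    if config.phylo_traits:
        n_nodes = tree.n_nodes
        x = np.zeros((n_nodes, n_cont))
        eps = rng.standard_normal((n_nodes, n_cont)) * np.sqrt(
            config.bm_rate * tree.length)[:, None]
        state = np.zeros((n_nodes, config.n_categorical), dtype=np.int64)
        p_switch = -np.expm1(-config.cat_switch_rate * tree.length)
        switch = rng.random((n_nodes, config.n_categorical)) < p_switch[:, None]
        new_state = rng.integers(0, config.n_levels,
                                 size=(n_nodes, config.n_categorical))
        state[0] = rng.integers(0, config.n_levels, size=config.n_categorical)
        for i in range(1, n_nodes):
            p = tree.parent[i]
            x[i] = x[p] + eps[i]
            state[i] = np.where(switch[i], new_state[i], state[p])
        cont = x[tree.tip_indices]
        cat = state[tree.tip_indices]
    else:
        cont = rng.standard_normal((n_tips, n_cont)) * np.sqrt(
            config.bm_rate * config.crown_age)
        cat = rng.integers(0, config.n_levels, size=(n_tips, config.n_categorical))

    data: dict[str, object] = {}
    kinds: dict[str, str] = {}
    for j in range(n_cont):
        name = f"ct{j + 1:02d}"
        data[name] = cont[:, j]
        kinds[name] = CONTINUOUS
    for j in range(config.n_categorical):
        name = f"cc{j + 1:02d}"
        data[name] = [levels[s] for s in cat[:, j]]
        kinds[name] = CATEGORICAL
    df = pd.DataFrame(data, index=pd.Index(labels, name="species"))
    miss = rng.random(df.shape) < config.missingness
    df = df.mask(miss)
    return TraitMatrix(df, kinds)


@dataclass(frozen=True)
class Bundle:
    """A generated study system plus (optionally) its on-disk files."""

    config: SyntheticConfig
    tree: PhyloTree
    threat: ThreatTable
    traits: TraitMatrix
    paths: dict[str, Path] | None = None


def generate(config: SyntheticConfig) -> Bundle:
    """Deterministically generate tree, threat table and traits from the seed."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    threat = assign_threat(tree, config, rng)
    traits = simulate_traits(tree, config, rng)
    return Bundle(config, tree, threat, traits)


def make_fixture_bundle(config: SyntheticConfig, out_dir: str | Path) -> Bundle:
    """Generate and write tree.nwk, threat.tsv, traits.tsv and config.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate(config)
    paths = {
        "tree": out / "tree.nwk",
        "threat": out / "threat.tsv",
        "traits": out / "traits.tsv",
        "config": out / "config.json",
    }
    paths["tree"].write_text(bundle.tree.to_newick() + "\n")
    bundle.threat.write_tsv(paths["threat"])
    bundle.traits.write_tsv(paths["traits"])
    config.to_json(paths["config"])
    return Bundle(config, bundle.tree, bundle.threat, bundle.traits, paths)
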