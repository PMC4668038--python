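"""Species-selection schemes for conservation, and a crude cost index.

Six ways to pick ``n`` species for protection:

* ``RANDOM`` - uniform draw from the threatened pool (the conservative null);
* ``THREAT`` - most threatened first, random resolution of within-category ties;
* ``ED`` / ``EDGE`` / ``THREAT_ED`` - top-ranked by the corresponding score,
  exact ties resolved at random;
* ``MAX`` - greedy set maximising expected diversity (one of the many
  near-optimal sets; deterministic tie-breaking for reproducibility).

"Protected" means the species' category is reset to LC (p_ext 0.001);
``protect_pext=0.0`` gives the stricter cannot-go-extinct reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diversity import PersistenceEngine
from .threat import (CATEGORIES, DD, DEFAULT_DD_PEXT, DEFAULT_PEXT,
                     ThreatTable)
from .trees import PhyloTree

__all__ = ["ProtectionScenario", "random_threatened_set", "rank_by_threat",
           "rank_by_score", "greedy_max_set", "cost_index", "SCHEMES",
           "DEFAULT_COST_LADDER"]

SCHEMES = ("RANDOM", "ED", "THREAT", "EDGE", "MAX", "THREAT_ED", "NONE")

#: Threat categories a species must traverse to reach LC.
DEFAULT_COST_LADDER: dict[str, int] = {"CR": 4, "EN": 3, "VU": 2, "NT": 1, "LC": 0}


@dataclass(frozen=True)
class ProtectionScenario:
    """A chosen protected set: which scheme produced it, and from what seed."""

    scheme: str
    species: tuple[str, ...]
    seed: int | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if len(set(self.species)) != len(self.species):
            raise ValueError("protected set contains duplicates")

    def __len__(self) -> int:
        return len(self.species)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def random_threatened_set(threat: ThreatTable, n: int, rng) -> ProtectionScenario:
    """Uniform sample of ``n`` threatened species, without replacement."""
    rng = _as_rng(rng)
    pool = sorted(threat.threatened_species())
    if n > len(pool):
        raise ValueError(f"n={n} exceeds the {len(pool)} threatened species")
    chosen = rng.choice(len(pool), size=n, replace=False) if n else []
    return ProtectionScenario("RANDOM", tuple(pool[i] for i in sorted(chosen)))


def rank_by_threat(threat: ThreatTable, n: int, rng) -> ProtectionScenario:
    """Most-threatened-first (CR down to NT); random ties at the boundary."""
    rng = _as_rng(rng)
    chosen: list[str] = []
    cats = threat.series
    for cat in reversed(CATEGORIES[1:]):  # CR, EN, VU, NT
        members = sorted(cats.index[cats == cat])
        need = n - len(chosen)
        if need <= 0:
            break
        if len(members) <= need:
            chosen.extend(members)
        else:
            idx = rng.choice(len(members), size=need, replace=False)
            chosen.extend(members[i] for i in sorted(idx))
    if len(chosen) < n:
        raise ValueError(f"only {len(chosen)} threatened species for n={n}")
    return ProtectionScenario("THREAT", tuple(chosen))


def rank_by_score(scores: pd.DataFrame, score_field: str, n: int, rng,
                  candidates: str = "all") -> ProtectionScenario:
    """Top-``n`` by a score column; exact ties broken uniformly at random.

    ``candidates`` is ``'all'`` (every scored non-DD species, matching how
    published EDGE lists are drawn) or ``'threatened'``.
    """
    if score_field not in ("ED", "EDGE", "ThreatED"):
        raise ValueError(f"cannot rank by {score_field!r}")
    rng = _as_rng(rng)
    df = scores[scores["category"] != DD]
    if candidates == "threatened":
        df = df[df["category"].isin(("NT", "VU", "EN", "CR"))]
    elif candidates != "all":
        raise ValueError(f"unknown candidate pool {candidates!r}")
    s = df[score_field].dropna().sort_index()
    if n > len(s):
        raise ValueError(f"n={n} exceeds the {len(s)} candidates")
    # random tie-breaks: shuffle first, then stable sort on the score
    perm = rng.permutation(len(s))
    shuffled = s.iloc[perm]
    ranked = shuffled.sort_values(ascending=False, kind="stable")
    scheme = {"ED": "ED", "EDGE": "EDGE", "ThreatED": "THREAT_ED"}[score_field]
    return ProtectionScenario(scheme, tuple(ranked.index[:n]))


def greedy_max_set(tree: PhyloTree, threat: ThreatTable, n: int,
                   pext_map: Mapping[str, float] = DEFAULT_PEXT,
                   protect_pext: float | None = None,
                   dd_pext: float = DEFAULT_DD_PEXT,
                   engine: PersistenceEngine | None = None) -> ProtectionScenario:
    """Greedy MAX set: repeatedly protect the threatened species whose
    protection most increases expected diversity.

    Marginal gains are recomputed after every addition; exact ties pick the
    first species id, so the result is deterministic.  Also records the
    per-step marginal gains (non-increasing, by submodularity) in ``meta``.
    """
    if engine is None:
        engine = PersistenceEngine(tree)
    if protect_pext is None:
        protect_pext = pext_map["LC"]
    pool = sorted(set(threat.threatened_species()) & set(engine.tip_labels))
    if n > len(pool):
        raise ValueError(f"n={n} exceeds the {len(pool)} threatened tips")
    tip_of = {lab: j for j, lab in enumerate(engine.tip_labels)}
    pext = threat.pext_vector(engine.tip_labels, pext_map, dd_pext)
    state = engine.make_state(pext)
    chosen: list[str] = []
    gains: list[float] = []
    remaining = list(pool)
    for _ in range(n):
        best_sp, best_gain = None, -np.inf
        for sp in remaining:
            g = engine.protect_gain(state, tip_of[sp], protect_pext)
            if g > best_gain:
                best_sp, best_gain = sp, g
        engine.apply_protection(state, tip_of[best_sp], protect_pext)
        chosen.append(best_sp)
        gains.append(best_gain)
        remaining.remove(best_sp)
    return ProtectionScenario("MAX", tuple(chosen),
                              meta={"marginal_gains": gains,
                                    "protect_pext": protect_pext})


def cost_index(scenario: ProtectionScenario | Sequence[str], threat: ThreatTable,
               ladder: Mapping[str, int] = DEFAULT_COST_LADDER) -> int:
    """Summed number of threat categories the protected species must
    traverse before none is considered under threat (CR counts 4 ... LC 0)."""
    species = scenario.species if isinstance(scenario, ProtectionScenario) else scenario
    total = 0
    for sp in species:
        cat = threat.category(sp)
        if cat == DD:
            raise ValueError(f"{sp} is Data Deficient; cost undefined")
        total += ladder[cat]
    return total


def export_scenario(scenario: ProtectionScenario, path) -> None:
    """Write a scenario as delimited text (scheme, seed, species list)."""
    df = pd.DataFrame({"species": list(scenario.species)})
    df.insert(0, "scheme", scenario.scheme)
    df.insert(1, "seed", scenario.seed if scenario.seed is not None else "")
    df.to_csv(path, sep="\t", index=False)
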