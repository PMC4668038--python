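"""IUCN Red List categories and the species threat table.

Categories run LC < NT < VU < EN < CR on an ordinal scale (GE score 0-4).
Following standard usage in forward projections, NT, VU, EN and CR species
are collectively called "threatened".  Data Deficient (DD) species carry no
ordinal position: they stay in trees (removing them would distort other
species' evolutionary distinctiveness) but are excluded from rankings and
protection candidate lists, and their extinction probability must be set
explicitly by the caller.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CATEGORIES: tuple[str, ...] = ("LC", "NT", "VU", "EN", "CR")
DD = "DD"
THREATENED: frozenset[str] = frozenset({"NT", "VU", "EN", "CR"})

#: Ordinal global-endangerment encoding, LC=0 ... CR=4.
GE_SCORES: dict[str, int] = {c: i for i, c in enumerate(CATEGORIES)}

#: Default 100-year extinction probabilities per category.
DEFAULT_PEXT: dict[str, float] = {
    "LC": 0.001, "NT": 0.01, "VU": 0.1, "EN": 0.786, "CR": 0.999,
}

#: Extinction probability given to DD species when a value is required.
DEFAULT_DD_PEXT: float = DEFAULT_PEXT["LC"]


class UnknownCategoryError(KeyError):
    """A category outside {LC, NT, VU, EN, CR} where an ordinal one is required."""


class ThreatTable:
    """Immutable mapping species id -> IUCN category (incl. DD).

    Backed by a pandas Series of strings; construction validates categories
    and id uniqueness.
    """

    def __init__(self, categories: Mapping[str, str] | pd.Series):
        s = pd.Series(categories, dtype=object)
        s.index = s.index.astype(str)
        if s.index.has_duplicates:
            dupes = s.index[s.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species ids: {dupes[:5]}")
        bad = sorted(set(s) - set(CATEGORIES) - {DD})
        if bad:
            raise UnknownCategoryError(f"unknown categories: {bad}")
        self._s = s
        self._s.index.name = "species"
        self._s.name = "category"

    # ------------------------------------------------------------------ views
    @property
    def series(self) -> pd.Series:
        return self._s.copy()

    @property
    def species(self) -> list[str]:
        return self._s.index.tolist()

    def __len__(self) -> int:
        return len(self._s)

    def __contains__(self, sp: str) -> bool:
        return sp in self._s.index

    def category(self, sp: str) -> str:
        return self._s[sp]

    def threatened_species(self) -> list[str]:
        return self._s.index[self._s.isin(THREATENED)].tolist()

    def non_dd_species(self) -> list[str]:
        return self._s.index[self._s != DD].tolist()

    def counts(self) -> pd.Series:
        return self._s.value_counts()

    # ------------------------------------------------------------ derivations
    def ge(self, sp: str) -> int:
        cat = self._s[sp]
        if cat == DD:
            raise UnknownCategoryError(f"{sp} is Data Deficient; no GE ordinal")
        return GE_SCORES[cat]

    def pext_vector(self, species: Iterable[str],
                    pext_map: Mapping[str, float] = DEFAULT_PEXT,
                    dd_pext: float = DEFAULT_DD_PEXT) -> np.ndarray:
        """Extinction probabilities for the given species, in order.

        Raises ``KeyError`` listing every species absent from the table.
        """
        species = list(species)
        missing = [sp for sp in species if sp not in self._s.index]
        if missing:
            raise KeyError(f"{len(missing)} species missing from threat table: "
                           f"{missing[:10]}")
        out = np.empty(len(species))
        for i, sp in enumerate(species):
            cat = self._s[sp]
            out[i] = dd_pext if cat == DD else pext_map[cat]
        return out

    def with_categories(self, updates: Mapping[str, str]) -> "ThreatTable":
        """New table with the given species reassigned."""
        s = self._s.copy()
        unknown = [sp for sp in updates if sp not in s.index]
        if unknown:
            raise KeyError(f"cannot update unlisted species: {unknown[:10]}")
        for sp, cat in updates.items():
            s[sp] = cat
        return ThreatTable(s)

    def protect(self, species: Iterable[str], as_category: str = "LC") -> "ThreatTable":
        """Mark species as successfully protected (category reset, default LC)."""
        return self.with_categories({sp: as_category for sp in species})

    # -------------------------------------------------------------------- io
    @classmethod
    def read_tsv(cls, path: str | Path) -> "ThreatTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(pd.Series(df["category"].values, index=df["species"].values))

    def write_tsv(self, path: str | Path) -> None:
        self._s.rename_axis("species").to_frame("category").to_csv(path, sep="\t")

    def __repr__(self) -> str:
        n_thr = len(self.threatened_species())
        return f"<ThreatTable {len(self)} species, {n_thr} threatened>"
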