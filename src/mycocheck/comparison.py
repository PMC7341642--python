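"""Reconciling a checklist with external species lists (database extracts).

Two species lists are compared after both have been normalized through the
same synonymy backbone, so that differences reflect genuinely different taxa
rather than nomenclatural variants.  Comparison is two-level: per country
(each dataset's own country attribution) and for the whole region (union over
countries), so a species attributed to different countries by the two
datasets counts as unique on both sides at country scope but shared at
regional scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .checklist import Checklist, clean_name
from .errors import MycocheckError
from .util import round_half_up

ALL_SCOPE = "ALL"


@dataclass
class DatasetOverlap:
    """Shared/unique species counts between two datasets in one scope."""

    scope: str
    n_a: int
    n_b: int
    shared: int
    pct_added_threshold: float = 25.0

    @property
    def only_a(self) -> int:
        return self.n_a - self.shared

    @property
    def only_b(self) -> int:
        return self.n_b - self.shared

    @property
    def union(self) -> int:
        return self.n_a + self.n_b - self.shared

    @property
    def pct_added_by_b(self) -> float:
        """Species known only to B, as % of A's richness (B's net addition)."""
        if self.n_a == 0:
            return float("inf") if self.only_b else 0.0
        return 100.0 * self.only_b / self.n_a

    @property
    def substantial_addition(self) -> bool:
        return self.pct_added_by_b >= self.pct_added_threshold

    def as_dict(self) -> dict:
        return {
            "scope": self.scope, "n_a": self.n_a, "n_b": self.n_b,
            "shared": self.shared, "only_a": self.only_a, "only_b": self.only_b,
            "pct_added_by_b": round_half_up(self.pct_added_by_b, 1)
            if self.n_a else None,
            "substantial_addition": self.substantial_addition,
        }


SpeciesLists = Mapping[str, set]


def _as_species_lists(data: "Checklist | SpeciesLists") -> dict[str, set]:
    if isinstance(data, Checklist):
        if not data.normalized:
            raise MycocheckError(
                "compare_datasets requires normalized input; run normalize_names first")
        return data.species_by_country()
    return {c: set(s) for c, s in data.items()}


def read_species_lists(path: str | Path) -> dict[str, set]:
    """Read a flat species-list CSV (columns species_name, country)."""
    df = pd.read_csv(path)
    if not {"species_name", "country"}.issubset(df.columns):
        raise MycocheckError(
            f"{Path(path).name}: species list needs columns species_name, country")
    out: dict[str, set] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["country"]), set()).add(clean_name(str(row["species_name"])))
    return out


def compare_datasets(
    list_a: "Checklist | SpeciesLists",
    list_b: "Checklist | SpeciesLists",
    threshold: float = 25.0,
) -> dict[str, DatasetOverlap]:
    """Shared/unique species per scope between two normalized datasets.

    Returns one :class:`DatasetOverlap` per country present in either dataset
    plus one for scope ``ALL`` (the union over countries).  The operation is
    symmetric up to argument order.
    """
    a = _as_species_lists(list_a)
    b = _as_species_lists(list_b)
    scopes = sorted(set(a) | set(b))
    out: dict[str, DatasetOverlap] = {}
    for scope in scopes:
        sa, sb = a.get(scope, set()), b.get(scope, set())
        out[scope] = DatasetOverlap(scope, len(sa), len(sb), len(sa & sb), threshold)
    ua = set().union(*a.values()) if a else set()
    ub = set().union(*b.values()) if b else set()
    out[ALL_SCOPE] = DatasetOverlap(ALL_SCOPE, len(ua), len(ub), len(ua & ub), threshold)
    return out


def overlap_table(overlaps: Mapping[str, DatasetOverlap]) -> pd.DataFrame:
    """Per-scope overlap summary, one row per scope."""
    return pd.DataFrame([o.as_dict() for o in overlaps.values()])


def overlap_long_format(overlaps: Mapping[str, DatasetOverlap]) -> pd.DataFrame:
    """Stacked-bar-ready long format: scope, segment, species count.

    Segments: ``only_a`` (e.g. checklist only), ``shared``, ``only_b``
    (e.g. database only).
    """
    rows = []
    for o in overlaps.values():
        rows += [
            {"scope": o.scope, "segment": "only_a", "species": o.only_a},
            {"scope": o.scope, "segment": "shared", "species": o.shared},
            {"scope": o.scope, "segment": "only_b", "species": o.only_b},
        ]
    return pd.DataFrame(rows)
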