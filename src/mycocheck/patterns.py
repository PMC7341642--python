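"""Descriptive diversity patterns of a compiled checklist.

These summaries describe the state of documentation — how often and where
species have been recorded, and which higher groups are well or poorly
represented — not ecological reality: record counts reflect collection
activity, so all outputs here are explicitly about sampling.

Percentages are rounded half-up to one decimal for display; raw values are
retained in the exported tables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .checklist import Checklist
from .errors import ConfigurationError, MycocheckError
from .util import pct as _pct

#: Life-form combinations reported as a single category of their own.
#: Species carrying exactly this set of forms are assigned the combined
#: label instead of being multi-counted.
DEFAULT_COMBINED_LIFE_FORMS = {
    frozenset({"saprotroph", "plant-parasite"}): "saprotroph+plant-parasite",
}


@dataclass
class FrequencyDistribution:
    """How many species have exactly k records (rank-abundance of records)."""

    histogram: dict[int, int]  # k records -> number of species
    s_obs: int
    total_records: int
    ranked: list[tuple[str, int]] = field(default_factory=list)

    @classmethod
    def from_histogram(cls, histogram: Mapping[int, int]) -> "FrequencyDistribution":
        """Build directly from a frequency table (no per-species detail)."""
        hist = {int(k): int(v) for k, v in histogram.items()}
        s_obs = sum(hist.values())
        total = sum(k * v for k, v in hist.items())
        return cls(hist, s_obs, total)

    def pct(self, k: int, ndigits: int = 1) -> float:
        """Percentage of species with exactly k records, display-rounded."""
        return _pct(self.histogram.get(k, 0), self.s_obs, ndigits)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"records": k, "species": v,
                 "pct_species": _pct(v, self.s_obs)}
                for k, v in sorted(self.histogram.items())]
        return pd.DataFrame(rows)

    def rank_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranked, columns=["species", "records"])


def record_frequency_distribution(cl: Checklist) -> FrequencyDistribution:
    """Per-species record counts, their histogram, and the ranked list.

    Ranking is by record count descending with alphabetical tie-break, so the
    rank-abundance output is deterministic.
    """
    if not cl.records:
        raise MycocheckError("empty checklist")
    counts = Counter(r.species_name for r in cl.records)
    histogram = dict(Counter(counts.values()))
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return FrequencyDistribution(histogram, len(counts), len(cl.records), ranked)


@dataclass
class OccupancyDistribution:
    """How many species occur in exactly k countries."""

    histogram: dict[int, int]  # k countries -> number of species
    s_obs: int
    threshold_counts: dict[int, int] = field(default_factory=dict)

    @classmethod
    def from_histogram(cls, histogram: Mapping[int, int],
                       thresholds: Iterable[int] = ()) -> "OccupancyDistribution":
        hist = {int(k): int(v) for k, v in histogram.items()}
        s_obs = sum(hist.values())
        tc = {t: sum(v for k, v in hist.items() if k > t) for t in thresholds}
        return cls(hist, s_obs, tc)

    def pct(self, k: int, ndigits: int = 1) -> float:
        return _pct(self.histogram.get(k, 0), self.s_obs, ndigits)

    def count_above(self, t: int) -> int:
        """Species reported for more than t countries."""
        return sum(v for k, v in self.histogram.items() if k > t)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"countries": k, "species": v, "pct_species": _pct(v, self.s_obs)}
                for k, v in sorted(self.histogram.items())]
        return pd.DataFrame(rows)


def country_occupancy_distribution(
    cl: Checklist, thresholds: Iterable[int] = (7,)
) -> OccupancyDistribution:
    """Distinct-country counts per species, with above-threshold summaries."""
    if not cl.records:
        raise MycocheckError("empty checklist")
    by_species: dict[str, set] = {}
    for r in cl.records:
        by_species.setdefault(r.species_name, set()).add(r.country)
    occ = Counter(len(v) for v in by_species.values())
    dist = OccupancyDistribution(dict(occ), len(by_species))
    dist.threshold_counts = {t: dist.count_above(t) for t in thresholds}
    return dist


def representation_classification(
    group_counts: Mapping[str, Mapping[str, int]],
    world_counts: Mapping[str, int],
    world_total: int,
    min_species: int = 200,
    factor: float = 2.0,
) -> pd.DataFrame:
    """Classify taxon groups as over/under-represented per scope.

    For each scope (country or region) with at least ``min_species`` species,
    a group's local share c_g = 100 * S_g / S_scope is compared with its
    worldwide share w_g = 100 * W_g / world_total:

    * ``overrepresented``  when c_g > factor * w_g
    * ``underrepresented`` when c_g < w_g / factor
    * ``typical`` otherwise

    Scopes below ``min_species`` get ``not_evaluated`` for every group.
    ``group_counts`` maps scope -> {group: species count, "_total": S_scope};
    without an explicit ``_total`` the group sum is used (groups need not
    cover all species, so an explicit total is preferred).
    """
    if world_total <= 0:
        raise ConfigurationError("world_total must be positive")
    rows = []
    for scope, counts in group_counts.items():
        counts = dict(counts)
        s_scope = int(counts.pop("_total", sum(counts.values())))
        for group, s_g in sorted(counts.items()):
            if group not in world_counts:
                raise ConfigurationError(
                    f"group {group!r} has no worldwide species count")
            if s_g < 0:
                raise ConfigurationError(f"negative count for {group!r}")
            w_g = 100.0 * world_counts[group] / world_total
            if s_scope < min_species:
                status, c_g = "not_evaluated", None
            else:
                c_g = 100.0 * s_g / s_scope
                if c_g > factor * w_g:
                    status = "overrepresented"
                elif c_g < w_g / factor:
                    status = "underrepresented"
                else:
                    status = "typical"
            rows.append({"scope": scope, "group": group, "S_g": int(s_g),
                         "S_scope": s_scope,
                         "c_g": None if c_g is None else round(c_g, 4),
                         "w_g": round(w_g, 4), "status": status})
    return pd.DataFrame(rows)


def categorical_summary(
    cl: Checklist,
    field_name: str,
    combined_categories: Mapping[frozenset, str] | None = None,
) -> pd.DataFrame:
    """Per-species life-form or substrate composition of the checklist.

    Categories are aggregated at species level (a species' categories are
    the union over its records).  For ``substrate``, a species counts once
    per distinct substrate and percentages are over category assignments —
    a leaf-and-bark lichen contributes to both foliicolous and corticolous.
    For ``life_form``, a species whose category set matches a configured
    combination (default: saprotroph + plant-parasite) is assigned that
    combined category; any other multi-form species is counted once per
    form; percentages are over species, so they may sum above 100.
    """
    if field_name not in ("life_form", "substrate"):
        raise MycocheckError(f"unknown categorical field {field_name!r}")
    if not cl.records:
        raise MycocheckError("empty checklist")
    if combined_categories is None and field_name == "life_form":
        combined_categories = DEFAULT_COMBINED_LIFE_FORMS

    by_species: dict[str, set] = {}
    for r in cl.records:
        value = getattr(r, field_name)
        by_species.setdefault(r.species_name, set())
        if value:
            by_species[r.species_name].add(value)

    assignments: Counter = Counter()
    for cats in by_species.values():
        if not cats:
            assignments["unknown"] += 1
            continue
        if combined_categories and frozenset(cats) in combined_categories:
            assignments[combined_categories[frozenset(cats)]] += 1
            continue
        for c in cats:
            assignments[c] += 1

    s_obs = len(by_species)
    denom = s_obs if field_name == "life_form" else sum(assignments.values())
    rows = [{"category": c, "species": n, "pct": _pct(n, denom)}
            for c, n in assignments.most_common()]
    return pd.DataFrame(rows)
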