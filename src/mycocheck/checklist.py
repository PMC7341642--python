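"""Occurrence-record checklists: data model, validated I/O, name normalization.

A checklist is an ordered collection of occurrence records, each one citation
of a fungal name for a country in one publication.  Duplicate
(species, country, publication) rows are deliberately retained — published
records are often cited repeatedly and the record counts of a compiled
checklist include those repeats — with an optional dedup switch.

Name handling: names are compared after trimming, whitespace squeezing,
stripping hybrid signs, and capitalising the genus epithet only.  Names
containing "cf." or "aff." are treated as not determined to species rank.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import ChecklistSchemaError, RankError, SynonymResolutionError

#: The 14 West African countries covered by the regional checklist,
#: ISO 3166-1 alpha-2 codes.  Any other configured set may be passed to
#: ``read_checklist`` / ``Checklist``.
WEST_AFRICA = {
    "BJ": "Benin",
    "BF": "Burkina Faso",
    "GM": "Gambia",
    "GH": "Ghana",
    "GN": "Guinea",
    "GW": "Guinea-Bissau",
    "CI": "Ivory Coast",
    "LR": "Liberia",
    "ML": "Mali",
    "NE": "Niger",
    "NG": "Nigeria",
    "SN": "Senegal",
    "SL": "Sierra Leone",
    "TG": "Togo",
}

#: Default column map: Darwin Core terms -> record fields.
DEFAULT_COLUMNS = {
    "species_name": "scientificName",
    "country": "country",
    "publication_id": "bibliographicCitation",
    "year": "year",
    "higher_taxon": "higherClassification",
    "life_form": "lifeForm",
    "substrate": "substrate",
}

MANDATORY_FIELDS = ("species_name", "country", "publication_id")

INFRASPECIFIC_MARKERS = {"var.", "var", "subsp.", "subsp", "ssp.", "ssp",
                         "f.", "forma"}
#: Open nomenclature qualifiers: identification is not confidently at species
#: rank, so such names are treated as supraspecific for normalization.
UNCERTAIN_MARKERS = {"cf.", "cf", "aff.", "aff"}

_WS = re.compile(r"\s+")
_HYBRID = re.compile(r"(^|\s)[x×]\s+", re.IGNORECASE)

YEAR_MIN = 1700


def clean_name(name: str) -> str:
    """Canonicalise a scientific name string for comparison.

    Trims, squeezes whitespace, removes hybrid signs, capitalises the genus
    and nothing else.  Epithet case and any trailing author string are left
    alone (author parsing beyond this is out of scope).
    """
    s = _WS.sub(" ", name.strip())
    s = _HYBRID.sub(r"\1", s).strip()
    if not s:
        return s
    parts = s.split(" ")
    parts[0] = parts[0][0].upper() + parts[0][1:].lower()
    return " ".join(parts)


def infer_rank(name: str) -> str:
    """Classify a cleaned name as species / infraspecific / supraspecific."""
    parts = clean_name(name).split(" ")
    if len(parts) < 2:
        return "supraspecific"
    lowered = [p.lower() for p in parts]
    if any(p in UNCERTAIN_MARKERS for p in lowered):
        return "supraspecific"
    # genus + "sp."/"spp." is an undetermined species
    if lowered[1] in {"sp.", "sp", "spp.", "spp"}:
        return "supraspecific"
    if any(p in INFRASPECIFIC_MARKERS for p in lowered[2:]):
        return "infraspecific"
    return "species"


def collapse_to_species(name: str) -> str:
    """Reduce a name to its binomial, dropping infraspecific markers.

    "Puccinia graminis var. tritici" -> "Puccinia graminis"; a bare binomial
    is returned unchanged.  Raises :class:`RankError` for genus-only names.
    """
    cleaned = clean_name(name)
    if infer_rank(cleaned) == "supraspecific":
        raise RankError(f"not a species-rank name: {name!r}")
    return " ".join(cleaned.split(" ")[:2])


@dataclass(frozen=True)
class OccurrenceRecord:
    """One citation of a species for a country from one publication."""

    species_name: str
    country: str
    publication_id: str
    year: int | None = None
    higher_taxon: str | None = None
    life_form: str | None = None
    substrate: str | None = None

    @property
    def rank(self) -> str:
        return infer_rank(self.species_name)

    def validate(self, countries: Iterable[str]) -> list[str]:
        """Return a list of problems (empty when clean)."""
        problems = []
        if not self.country:
            problems.append("empty country")
        elif self.country not in set(countries):
            problems.append(f"unknown country {self.country!r}")
        if self.year is not None and not (YEAR_MIN <= self.year <= date.today().year):
            problems.append(f"year {self.year} outside [{YEAR_MIN}, current]")
        return problems


class SynonymTable:
    """Mapping of names to nomenclatural status and accepted name.

    Accepted entries map to themselves; synonym chains must resolve to an
    accepted name within ``max_depth`` steps and be cycle-free.
    """

    def __init__(self, entries: Mapping[str, tuple[str, str]], max_depth: int = 5):
        #: name -> (status, accepted_name); status in {accepted, synonym, unknown}
        self.entries = {clean_name(k): (s, clean_name(a)) for k, (s, a) in entries.items()}
        self.max_depth = max_depth
        for name, (status, accepted) in self.entries.items():
            if status == "accepted" and accepted != name:
                raise SynonymResolutionError(
                    f"accepted entry {name!r} must map to itself, not {accepted!r}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, max_depth: int = 5) -> "SynonymTable":
        required = {"name", "status", "accepted_name"}
        if not required.issubset(df.columns):
            raise ChecklistSchemaError(
                f"synonym table needs columns {sorted(required)}")
        entries = {r["name"]: (r["status"], r["accepted_name"]) for _, r in df.iterrows()}
        return cls(entries, max_depth=max_depth)

    @classmethod
    def read_csv(cls, path: str | Path, max_depth: int = 5) -> "SynonymTable":
        return cls.from_frame(pd.read_csv(path), max_depth=max_depth)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"name": n, "status": s, "accepted_name": a}
                for n, (s, a) in sorted(self.entries.items())]
        return pd.DataFrame(rows, columns=["name", "status", "accepted_name"])

    def __contains__(self, name: str) -> bool:
        return clean_name(name) in self.entries

    def resolve(self, name: str) -> tuple[str, str]:
        """Return (status, accepted_name) for ``name``.

        Unknown names return ("unknown", name) unchanged.  Chains are
        followed up to ``max_depth``; a cycle or over-deep chain raises
        :class:`SynonymResolutionError`.
        """
        key = clean_name(name)
        if key not in self.entries:
            return "unknown", key
        seen = [key]
        current = key
        for _ in range(self.max_depth):
            status, accepted = self.entries[current]
            if status != "synonym" or accepted == current:
                return ("synonym" if current != key else status), accepted
            if accepted in seen:
                raise SynonymResolutionError(
                    f"cyclic synonym chain: {' -> '.join(seen + [accepted])}")
            seen.append(accepted)
            if accepted not in self.entries:
                # chain ends at a name with no entry: treat end as accepted
                return "synonym", accepted
            current = accepted
        raise SynonymResolutionError(
            f"synonym chain deeper than {self.max_depth}: {' -> '.join(seen)}")


@dataclass
class ValidationReport:
    """Soft problems found while loading a checklist (nothing is dropped)."""

    unknown_countries: list[tuple[int, str]] = field(default_factory=list)
    bad_years: list[tuple[int, int]] = field(default_factory=list)
    missing_optional: dict[str, int] = field(default_factory=dict)

    @property
    def clean(self) -> bool:
        return not (self.unknown_countries or self.bad_years)


@dataclass
class Checklist:
    """An ordered collection of occurrence records with provenance."""

    records: list[OccurrenceRecord]
    provenance: str = ""
    normalized: bool = False
    countries: Mapping[str, str] = field(default_factory=lambda: dict(WEST_AFRICA))
    validation: ValidationReport | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[OccurrenceRecord]:
        return iter(self.records)

    def species_set(self, country: str | None = None) -> set[str]:
        recs = self.records if country is None else [
            r for r in self.records if r.country == country]
        return {r.species_name for r in recs}

    def species_by_country(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for r in self.records:
            out.setdefault(r.country, set()).add(r.species_name)
        return out

    def publications(self) -> set[str]:
        return {r.publication_id for r in self.records}

    def filter_countries(self, scope: Iterable[str]) -> "Checklist":
        scope = set(scope)
        recs = [r for r in self.records if r.country in scope]
        return replace(self, records=recs, validation=None)

    def deduplicate(self) -> "Checklist":
        """Optional: keep one record per (species, country, publication)."""
        seen: set[tuple[str, str, str]] = set()
        recs = []
        for r in self.records:
            key = (r.species_name, r.country, r.publication_id)
            if key not in seen:
                seen.add(key)
                recs.append(r)
        return replace(self, records=recs, validation=None)

    def to_frame(self) -> pd.DataFrame:
        cols = ["species_name", "country", "publication_id", "year",
                "higher_taxon", "life_form", "substrate"]
        return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in self.records],
                            columns=cols)

    def write_csv(self, path: str | Path, columns: Mapping[str, str] | None = None) -> None:
        columns = dict(DEFAULT_COLUMNS if columns is None else columns)
        df = self.to_frame().rename(columns=columns)
        df.to_csv(path, index=False)


def read_checklist(
    path: str | Path,
    delimiter: str = ",",
    columns: Mapping[str, str] | None = None,
    countries: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> Checklist:
    """Load a checklist CSV/TSV into a validated :class:`Checklist`.

    ``columns`` maps record fields to file column names (Darwin Core defaults).
    Rows with unknown countries or out-of-range years are loaded and flagged
    in the attached validation report, never silently dropped.
    """
    path = Path(path)
    columns = dict(DEFAULT_COLUMNS if columns is None else columns)
    countries = dict(WEST_AFRICA if countries is None else countries)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for fld in MANDATORY_FIELDS:
        col = columns[fld]
        if col not in df.columns:
            raise ChecklistSchemaError(
                f"{path.name}: mandatory column {col!r} (field {fld}) is missing")

    report = ValidationReport()
    records: list[OccurrenceRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        try:
            year_raw = row.get(columns.get("year", ""), "")
            year = int(float(year_raw)) if year_raw not in ("", None) else None
            rec = OccurrenceRecord(
                species_name=clean_name(row[columns["species_name"]]),
                country=row[columns["country"]].strip(),
                publication_id=row[columns["publication_id"]].strip(),
                year=year,
                higher_taxon=row.get(columns.get("higher_taxon", ""), "") or None,
                life_form=row.get(columns.get("life_form", ""), "") or None,
                substrate=row.get(columns.get("substrate", ""), "") or None,
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ChecklistSchemaError(f"{path.name}: unreadable row {i + 1}: {exc}") from exc
        for problem in rec.validate(countries):
            if "country" in problem:
                report.unknown_countries.append((i, rec.country))
            else:
                report.bad_years.append((i, rec.year))
        records.append(rec)

    for fld in ("year", "higher_taxon", "life_form", "substrate"):
        col = columns.get(fld)
        if col and col in df.columns:
            n_missing = int((df[col] == "").sum())
            if n_missing:
                report.missing_optional[fld] = n_missing
        elif col:
            report.missing_optional[fld] = len(df)

    return Checklist(records=records, provenance=provenance or str(path),
                     countries=countries, validation=report)


@dataclass
class NormalizationLog:
    """Everything normalize_names did: substitutions, drops, unknowns."""

    substitutions: list[tuple[str, str]] = field(default_factory=list)
    collapsed: list[tuple[str, str]] = field(default_factory=list)
    dropped_supraspecific: list[str] = field(default_factory=list)
    unknown: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (self.substitutions or self.collapsed or self.dropped_supraspecific)

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [{"action": "substitute", "from": a, "to": b} for a, b in self.substitutions]
            + [{"action": "collapse", "from": a, "to": b} for a, b in self.collapsed]
            + [{"action": "drop_supraspecific", "from": a, "to": ""}
               for a in self.dropped_supraspecific]
            + [{"action": "unknown", "from": a, "to": a} for a in self.unknown]
        )
        return pd.DataFrame(rows, columns=["action", "from", "to"])

    def summary(self) -> str:
        return (f"{len(self.substitutions)} substitutions, "
                f"{len(self.collapsed)} infraspecific collapses, "
                f"{len(self.dropped_supraspecific)} supraspecific drops, "
                f"{len(set(self.unknown))} names not in the synonym table")


def normalize_names(
    cl: Checklist,
    syn: SynonymTable,
    drop_supraspecific: bool = True,
    collapse_infraspecific: bool = True,
) -> tuple[Checklist, NormalizationLog]:
    """Normalize every record name against a synonymy backbone.

    Each record's name is (optionally) collapsed to its binomial, then
    replaced by its accepted name when the table marks it a synonym.  Names
    absent from the table are retained verbatim and logged as unknown — such
    names most often refer to genuinely distinct taxa, so dropping them would
    understate richness.  Supraspecific records are dropped when requested.

    Idempotent: running the output through again yields an identical
    checklist and an empty log (unknown names are re-reported).
    """
    log = NormalizationLog()
    out: list[OccurrenceRecord] = []
    for rec in cl.records:
        name = clean_name(rec.species_name)
        if infer_rank(name) == "supraspecific":
            if drop_supraspecific:
                log.dropped_supraspecific.append(name)
                continue
            out.append(replace(rec, species_name=name))
            continue
        if collapse_infraspecific:
            binomial = collapse_to_species(name)
            if binomial != name:
                log.collapsed.append((name, binomial))
            name = binomial
        status, accepted = syn.resolve(name)
        if status == "synonym" and accepted != name:
            log.substitutions.append((name, accepted))
            name = accepted
        elif status == "unknown":
            log.unknown.append(name)
        out.append(replace(rec, species_name=name))
    normalized = replace(cl, records=out, normalized=True, validation=cl.validation)
    return normalized, log
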