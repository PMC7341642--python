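"""Synthetic checklists with known ground truth.

The generator emulates the statistical structure of a compiled regional
checklist: publications as sampling events of very unequal size, strongly
heterogeneous per-species detectability (lognormal, so most species are
rarely recorded and uniques dominate), small country ranges, uneven
per-country effort, taxon-group composition, and nomenclatural noise
(synonym usage, occasional misidentification).  Every record's true species
is known, so estimator recovery and normalization round-trips are testable.

It makes no attempt to fit any real checklist; it reproduces the *kind* of
data the analysis modules consume, with tunable truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .checklist import Checklist, OccurrenceRecord, SynonymTable, WEST_AFRICA
from .errors import ConfigurationError

#: Synthetic worldwide taxon-group composition used for group assignment.
#: Shares are plausible order-level fractions of described fungal diversity;
#: they are generator defaults, not measurements.
DEFAULT_GROUP_PROPORTIONS = {
    "Agaricales": 0.13,
    "Capnodiales": 0.05,
    "Pucciniales": 0.06,
    "Helotiales": 0.04,
    "Xylariales": 0.04,
    "Polyporales": 0.03,
    "Pezizales": 0.03,
    "Russulales": 0.023,
    "Meliolales": 0.018,
    "Ustilaginales": 0.012,
    "Erysiphales": 0.010,
    "Phallales": 0.002,
    "other": 0.545,
}

#: Life-form composition of the generated species pool (fractions of
#: species).  The "both" entry yields species carrying saprotroph and
#: plant-parasite forms together.
DEFAULT_LIFE_FORM_PROPORTIONS = {
    "plant-parasite": 0.364,
    "saprotroph": 0.270,
    "saprotroph+plant-parasite": 0.062,
    "lichenized": 0.115,
    "ectomycorrhizal": 0.051,
    "arthropod-parasite": 0.044,
    "other": 0.094,
}

#: Substrate composition for lichenized species.
DEFAULT_SUBSTRATE_PROPORTIONS = {
    "foliicolous": 0.48,
    "corticolous": 0.42,
    "saxicolous": 0.06,
    "bryicolous": 0.03,
    "terricolous": 0.01,
}

_SYLLABLES = ["ba", "co", "di", "fu", "ga", "le", "mi", "no", "pu", "ra",
              "se", "ti", "vo", "xe", "zy"]


@dataclass
class SimulationConfig:
    """Knobs of the checklist generator.

    Defaults emulate a literature-compiled regional checklist at a size the
    analyses handle in seconds: 1000 true species over the 14 configured
    countries sampled by 200 publications averaging ~19 records each, with
    lognormal detectability (sigma 1.5, giving the uniques-heavy incidence
    structure typical of such compilations) and small geometric country
    ranges.  Per-country effort weights default to a seeded lognormal draw,
    reproducing the strongly uneven effort such compilations show.
    """

    S_true: int = 1000
    n_countries: int = 14
    group_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROPORTIONS))
    range_model: str = "uniform"  # or "distance-decay"
    range_geometric_p: float = 0.55  # P(range size = k) ~ Geometric(p)
    decay_scale_km: float = 800.0  # distance-decay range model scale
    n_publications: int = 200
    records_per_publication_mean: float = 19.0
    records_per_publication_dispersion: float = 0.6  # NB shape; smaller = more skew
    detection_heterogeneity: float = 1.5  # lognormal sigma of detectability
    country_effort_weights: Mapping[str, float] | None = None
    effort_sigma: float = 1.0  # lognormal sigma of default effort weights
    p_group_focus: float = 0.3  # chance a publication focuses on one group
    synonyms_per_species: int = 1
    p_synonym: float = 0.0
    p_misid: float = 0.0
    seed: int = 0

    def countries(self) -> list[str]:
        codes = sorted(WEST_AFRICA)
        if self.n_countries <= len(codes):
            return codes[: self.n_countries]
        return codes + [f"X{i:02d}" for i in range(self.n_countries - len(codes))]

    def validate(self) -> None:
        if self.S_true < 1:
            raise ConfigurationError("S_true must be >= 1")
        if self.n_countries < 1 or self.n_publications < 1:
            raise ConfigurationError("need >= 1 country and >= 1 publication")
        props = dict(self.group_proportions)
        if not props or any(p < 0 for p in props.values()) or sum(props.values()) <= 0:
            raise ConfigurationError("group proportions must be nonnegative, not all zero")
        for name in ("range_geometric_p",):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigurationError(f"{name} must be in (0, 1]")
        for name in ("p_group_focus", "p_synonym", "p_misid"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.country_effort_weights is not None:
            w = [self.country_effort_weights.get(c, 0.0) for c in self.countries()]
            if any(x < 0 for x in w):
                raise ConfigurationError("effort weights must be nonnegative")
            if sum(w) <= 0:
                raise ConfigurationError("zero sampling effort everywhere")
        if self.records_per_publication_mean <= 0:
            raise ConfigurationError("records_per_publication_mean must be positive")


@dataclass
class GroundTruth:
    """The generator's registry: what is actually out there.

    ``registry`` has one row per true species (species_id, accepted_name,
    group, detectability, life_forms, substrates); ``ranges`` maps species_id
    to its set of occupied countries; ``synonyms`` maps accepted_name to its
    synonym names.
    """

    registry: pd.DataFrame
    ranges: dict[str, set]
    synonyms: dict[str, list[str]]
    synonym_table: SynonymTable
    config: SimulationConfig

    @property
    def S_true(self) -> int:
        return len(self.registry)

    def accepted_names(self) -> list[str]:
        return list(self.registry["accepted_name"])

    def species_by_country(self) -> dict[str, set]:
        out: dict[str, set] = {c: set() for c in self.config.countries()}
        names = dict(zip(self.registry["species_id"], self.registry["accepted_name"]))
        for sid, countries in self.ranges.items():
            for c in countries:
                out[c].add(names[sid])
        return out

    def write_json(self, path: str | Path) -> None:
        cfg = {k: (dict(v) if isinstance(v, Mapping) else v)
               for k, v in asdict(self.config).items()}
        payload = {
            "config": cfg,
            "registry": self.registry.to_dict(orient="records"),
            "ranges": {k: sorted(v) for k, v in self.ranges.items()},
            "synonyms": self.synonyms,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _species_names(n: int, rng: np.random.Generator) -> list[str]:
    """Deterministic unique pseudo-Latin binomials."""
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < n:
        genus = "".join(rng.choice(_SYLLABLES, size=3)).capitalize()
        epithet = "".join(rng.choice(_SYLLABLES, size=3)) + rng.choice(
            ["num", "ense", "icola", "oides", "ata", "ella"])
        name = f"{genus} {epithet}"
        if name not in seen:
            seen.add(name)
            names.append(name)
    return names


def _synonym_names(accepted: list[str], per_species: int,
                   rng: np.random.Generator) -> dict[str, list[str]]:
    taken = set(accepted)
    out: dict[str, list[str]] = {}
    for name in accepted:
        genus, epithet = name.split(" ", 1)
        syns = []
        while len(syns) < per_species:
            alt_genus = "".join(rng.choice(_SYLLABLES, size=3)).capitalize() + "ia"
            candidate = f"{alt_genus} {epithet}"
            if candidate not in taken:
                taken.add(candidate)
                syns.append(candidate)
        out[name] = syns
    return out


def _default_centroid_grid(countries: list[str]) -> dict[str, tuple[float, float]]:
    """Evenly spaced synthetic centroids used by the distance-decay model."""
    return {c: (8.0 + 2.0 * (i % 4), -15.0 + 3.0 * (i // 4))
            for i, c in enumerate(countries)}


def _draw_ranges(cfg: SimulationConfig, countries: list[str],
                 rng: np.random.Generator) -> list[set]:
    n = len(countries)
    ranges: list[set] = []
    if cfg.range_model == "uniform":
        for _ in range(cfg.S_true):
            k = min(n, int(rng.geometric(cfg.range_geometric_p)))
            ranges.append(set(rng.choice(countries, size=k, replace=False)))
        return ranges
    if cfg.range_model == "distance-decay":
        from .spatial import haversine_km
        cents = _default_centroid_grid(countries)
        dist = np.array([[haversine_km(*cents[a], *cents[b]) for b in countries]
                         for a in countries])
        for _ in range(cfg.S_true):
            seed_c = int(rng.integers(n))
            p_in = np.exp(-dist[seed_c] / cfg.decay_scale_km)
            member = rng.random(n) < p_in
            member[seed_c] = True
            ranges.append({countries[i] for i in np.nonzero(member)[0]})
        return ranges
    raise ConfigurationError(f"unknown range_model {cfg.range_model!r}")


def simulate_checklist(cfg: SimulationConfig) -> tuple[Checklist, GroundTruth]:
    """Generate a checklist and its ground truth, deterministically per seed.

    Species get group labels, country ranges, lognormal detectability, and
    life forms/substrates; each publication picks a country by effort weight
    (and with probability ``p_group_focus`` a focal group), then samples the
    species present there without replacement with probability proportional
    to detectability.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    countries = cfg.countries()

    accepted = _species_names(cfg.S_true, rng)
    groups_pool = list(cfg.group_proportions)
    gp = np.array([cfg.group_proportions[g] for g in groups_pool], dtype=float)
    groups = rng.choice(groups_pool, size=cfg.S_true, p=gp / gp.sum())
    detect = rng.lognormal(mean=0.0, sigma=cfg.detection_heterogeneity,
                           size=cfg.S_true)
    ranges = _draw_ranges(cfg, countries, rng)

    lf_pool = list(DEFAULT_LIFE_FORM_PROPORTIONS)
    lf_p = np.array(list(DEFAULT_LIFE_FORM_PROPORTIONS.values()))
    life_forms = rng.choice(lf_pool, size=cfg.S_true, p=lf_p / lf_p.sum())
    sub_pool = list(DEFAULT_SUBSTRATE_PROPORTIONS)
    sub_p = np.array(list(DEFAULT_SUBSTRATE_PROPORTIONS.values()))
    substrates: list[list[str]] = []
    for lf in life_forms:
        if lf != "lichenized":
            substrates.append([])
            continue
        k = 2 if rng.random() < 0.2 else 1
        substrates.append(list(rng.choice(sub_pool, size=k, replace=False,
                                          p=sub_p / sub_p.sum())))

    species_ids = [f"sp{i:05d}" for i in range(cfg.S_true)]
    registry = pd.DataFrame({
        "species_id": species_ids,
        "accepted_name": accepted,
        "group": groups,
        "detectability": detect,
        "life_forms": ["|".join(sorted(lf.split("+"))) for lf in life_forms],
        "substrates": ["|".join(s) for s in substrates],
    })

    if cfg.country_effort_weights is not None:
        weights = np.array([cfg.country_effort_weights.get(c, 0.0) for c in countries])
    else:
        weights = rng.lognormal(mean=0.0, sigma=cfg.effort_sigma, size=len(countries))
    weights = weights / weights.sum()

    by_country: dict[str, np.ndarray] = {
        c: np.array([i for i in range(cfg.S_true) if c in ranges[i]], dtype=int)
        for c in countries}
    if all(len(v) == 0 for v in by_country.values()):
        raise ConfigurationError("no species occupies any country")

    nb_shape = cfg.records_per_publication_dispersion
    nb_p = nb_shape / (nb_shape + cfg.records_per_publication_mean)

    records: list[OccurrenceRecord] = []
    for p in range(cfg.n_publications):
        country = None
        for _ in range(100):
            cand = countries[rng.choice(len(countries), p=weights)]
            if len(by_country[cand]):
                country = cand
                break
        if country is None:  # effort concentrated on empty countries
            continue
        present = by_country[country]
        w = detect[present].copy()
        if cfg.p_group_focus > 0 and rng.random() < cfg.p_group_focus:
            focus = groups[present[rng.choice(len(present))]]
            w = np.where(groups[present] == focus, w * 25.0, w)
        n_rec = max(1, int(rng.negative_binomial(nb_shape, nb_p)))
        n_rec = min(n_rec, len(present))
        chosen = rng.choice(present, size=n_rec, replace=False, p=w / w.sum())
        year = int(rng.integers(1850, 2021))
        pub_id = f"pub{p:04d}"
        for i in chosen:
            forms = life_forms[i].split("+")
            lf = forms[int(rng.integers(len(forms)))]
            sub = substrates[i][int(rng.integers(len(substrates[i])))] if substrates[i] else None
            records.append(OccurrenceRecord(
                species_name=accepted[i], country=country, publication_id=pub_id,
                year=year, higher_taxon=str(groups[i]), life_form=lf, substrate=sub))

    synonyms = _synonym_names(accepted, cfg.synonyms_per_species, rng)
    entries: dict[str, tuple[str, str]] = {a: ("accepted", a) for a in accepted}
    for a, syns in synonyms.items():
        for s in syns:
            entries[s] = ("synonym", a)
    syn_table = SynonymTable(entries)

    truth = GroundTruth(registry=registry,
                        ranges={species_ids[i]: ranges[i] for i in range(cfg.S_true)},
                        synonyms=synonyms, synonym_table=syn_table, config=cfg)
    cl = Checklist(records=records, provenance=f"synthetic(seed={cfg.seed})",
                   countries={c: c for c in countries})
    return cl, truth


def inject_name_noise(
    cl: Checklist,
    gt: GroundTruth,
    p_synonym: float,
    p_misid: float,
    seed: int | None = None,
) -> tuple[Checklist, pd.DataFrame]:
    """Perturb record names with synonym usage and misidentification.

    Each record independently gets its name replaced by a synonym of its
    species with probability ``p_synonym``, or by a *different* registry
    species with probability ``p_misid``.  Returns the perturbed checklist
    and a log of every change.
    """
    if not 0 <= p_synonym <= 1 or not 0 <= p_misid <= 1 or p_synonym + p_misid > 1:
        raise ConfigurationError("need p_synonym, p_misid >= 0 with sum <= 1")
    if p_synonym > 0:
        missing = [r.species_name for r in cl.records
                   if not gt.synonyms.get(r.species_name)]
        if missing:
            raise ConfigurationError(
                f"p_synonym > 0 but no synonyms available for e.g. {missing[0]!r}")
    rng = np.random.default_rng(seed)
    accepted = gt.accepted_names()
    out = []
    log_rows = []
    for idx, rec in enumerate(cl.records):
        u = rng.random()
        new_name = rec.species_name
        action = None
        if u < p_synonym:
            syns = gt.synonyms[rec.species_name]
            new_name = syns[int(rng.integers(len(syns)))]
            action = "synonym"
        elif u < p_synonym + p_misid:
            other = rec.species_name
            while other == rec.species_name:
                other = accepted[int(rng.integers(len(accepted)))]
            new_name = other
            action = "misidentification"
        if action:
            log_rows.append({"row": idx, "action": action,
                             "from": rec.species_name, "to": new_name})
        out.append(OccurrenceRecord(
            species_name=new_name, country=rec.country,
            publication_id=rec.publication_id, year=rec.year,
            higher_taxon=rec.higher_taxon, life_form=rec.life_form,
            substrate=rec.substrate))
    noisy = Checklist(records=out, provenance=cl.provenance + "+noise",
                      normalized=False, countries=cl.countries)
    return noisy, pd.DataFrame(log_rows, columns=["row", "action", "from", "to"])


def make_database_extract(
    gt: GroundTruth,
    coverage: float,
    overlap_bias: float,
    seed: int | None = None,
    reference: Checklist | None = None,
) -> dict[str, set]:
    """Sample a database-style species list from the ground truth.

    Draws ``coverage * S_true`` species; ``overlap_bias`` enriches for
    species present in the ``reference`` checklist (1 = only shared species,
    as far as available; 0 = only species absent from it; 0.5 = indifferent).
    Each selected species is listed for every country in its true range.
    """
    if not 0 <= coverage <= 1 or not 0 <= overlap_bias <= 1:
        raise ConfigurationError("coverage and overlap_bias must be in [0, 1]")
    n_pick = int(round(coverage * gt.S_true))
    if n_pick == 0:
        warnings.warn("coverage yields an empty extract", stacklevel=2)
        return {}
    rng = np.random.default_rng(seed)
    names = gt.accepted_names()
    ref_species = reference.species_set() if reference is not None else set()
    in_ref = np.array([n in ref_species for n in names])
    w = np.where(in_ref, overlap_bias, 1.0 - overlap_bias).astype(float)
    idx = np.arange(gt.S_true)
    chosen: list[int] = []
    primary = idx[w > 0]
    if len(primary):
        take = min(n_pick, len(primary))
        wp = w[primary] / w[primary].sum()
        chosen = list(rng.choice(primary, size=take, replace=False, p=wp))
    if len(chosen) < n_pick:  # fill from zero-weight remainder
        rest = np.setdiff1d(idx, np.array(chosen, dtype=int))
        extra = rng.choice(rest, size=n_pick - len(chosen), replace=False)
        chosen += list(extra)

    sid = list(gt.registry["species_id"])
    out: dict[str, set] = {}
    for i in chosen:
        for c in gt.ranges[sid[i]]:
            out.setdefault(c, set()).add(names[i])
    return out


def write_extract_csv(extract: Mapping[str, set], path: str | Path) -> None:
    rows = [{"species_name": s, "country": c}
            for c in sorted(extract) for s in sorted(extract[c])]
    pd.DataFrame(rows, columns=["species_name", "country"]).to_csv(path, index=False)
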