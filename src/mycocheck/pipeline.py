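"""End-to-end orchestration: normalize -> estimate -> compare -> patterns -> spatial.

Everything numeric in the outputs is produced by the module operations; this
layer only sequences them, writes CSV/JSON artifacts, and records a manifest
of parameters so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .checklist import Checklist, SynonymTable, read_checklist, normalize_names
from .comparison import compare_datasets, overlap_table, overlap_long_format, read_species_lists
from .errors import ConfigurationError, MycocheckError
from .patterns import (categorical_summary, country_occupancy_distribution,
                       record_frequency_distribution, representation_classification)
from .reference import (WORLD_TOTAL_SPECIES, west_africa_centroids,
                        west_africa_summary, world_group_counts)
from .richness import (accumulation_curve, bootstrap_richness, build_incidence,
                       chao2, hawksworth_estimate)
from .spatial import geo_distance_matrix, jaccard_matrix, mantel_correlogram, mantel_test, read_centroids
from .util import round_half_up


@dataclass
class RunConfig:
    """Inputs and parameters of a full pipeline run."""

    checklist_path: str
    outdir: str
    synonym_path: str | None = None
    plant_table_path: str | None = None  # columns country, plant_species
    centroids_path: str | None = None
    extract_paths: Mapping[str, str] = field(default_factory=dict)  # label -> csv
    scope: list[str] | None = None
    sample_unit: str = "publication"
    hawksworth_ratio: float = 6.0
    n_boot: int = 200
    n_perm: int = 999
    overlap_threshold: float = 25.0
    seed: int = 0
    min_samples_per_country: int = 2

    def validate(self) -> None:
        for p in [self.checklist_path, self.synonym_path, self.plant_table_path,
                  self.centroids_path, *self.extract_paths.values()]:
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"input file not found: {p}")


class StageError(MycocheckError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _plant_table(cfg: RunConfig) -> dict[str, int]:
    if cfg.plant_table_path is None:
        ref = west_africa_summary()
        return dict(zip(ref["country"], ref["plant_species"].astype(int)))
    df = pd.read_csv(cfg.plant_table_path)
    if not {"country", "plant_species"}.issubset(df.columns):
        raise ConfigurationError("plant table needs columns country, plant_species")
    return dict(zip(df["country"].astype(str), df["plant_species"].astype(int)))


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages and write the report bundle; returns the manifest."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {},
                      "warnings": [], "parameters": {
                          "sample_unit": cfg.sample_unit,
                          "hawksworth_ratio": cfg.hawksworth_ratio,
                          "n_boot": cfg.n_boot, "n_perm": cfg.n_perm,
                          "overlap_threshold": cfg.overlap_threshold}}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    result = fn()
                for w in caught:
                    manifest["warnings"].append(f"{name}: {w.message}")
            except Exception as exc:
                raise StageError(name, exc) from exc
            manifest["stages"][name] = round(time.perf_counter() - t0, 3)
            return result
        return wrap

    cl = stage("load")(lambda: read_checklist(cfg.checklist_path))
    if cfg.scope:
        cl = cl.filter_countries(cfg.scope)

    def _normalize() -> Checklist:
        if cfg.synonym_path:
            syn = SynonymTable.read_csv(cfg.synonym_path)
        else:
            syn = SynonymTable({})
        norm, log = normalize_names(cl, syn)
        norm.write_csv(out / "checklist_normalized.csv")
        log.to_frame().to_csv(out / "normalization_log.csv", index=False)
        (out / "normalization_summary.txt").write_text(log.summary() + "\n")
        return norm

    norm = stage("normalize")(_normalize)
    plants = stage("plant_table")(lambda: _plant_table(cfg))

    def _estimate() -> pd.DataFrame:
        rows = []
        scopes = [("ALL", None)] + [(c, [c]) for c in sorted(norm.species_by_country())]
        for label, scope in scopes:
            sub = norm if scope is None else norm.filter_countries(scope)
            n_pubs = len(sub.publications())
            row = {"scope": label, "records": len(sub),
                   "species": len(sub.species_set()), "publications": n_pubs}
            if n_pubs >= cfg.min_samples_per_country:
                im = build_incidence(sub, sample_unit=cfg.sample_unit)
                ch = chao2(im)
                bo = bootstrap_richness(im, n_boot=cfg.n_boot, seed=cfg.seed)
                row.update(chao2=round_half_up(ch.value, 0), chao2_se=round_half_up(ch.se, 0),
                           bootstrap=round_half_up(bo.value, 0),
                           bootstrap_se=round_half_up(bo.se, 0))
            if label in plants:
                hw = hawksworth_estimate(row["species"], plants[label], cfg.hawksworth_ratio)
                row.update(hawksworth_E=hw.E, pct_known=hw.pct_known_display)
            elif label != "ALL":
                raise ConfigurationError(
                    f"plant table has no entry for scoped country {label!r}")
            else:
                total_p = sum(plants[c] for c in norm.species_by_country() if c in plants)
                if total_p:
                    hw = hawksworth_estimate(row["species"], total_p, cfg.hawksworth_ratio)
                    row.update(hawksworth_E=hw.E, pct_known=hw.pct_known_display)
            rows.append(row)
        df = pd.DataFrame(rows)
        df.to_csv(out / "summary_by_scope.csv", index=False)
        im_all = build_incidence(norm, sample_unit=cfg.sample_unit)
        accumulation_curve(im_all, method="exact").write_csv(out / "accumulation_exact.csv")
        return df

    summary = stage("estimate")(_estimate)

    def _compare() -> None:
        for label, path in cfg.extract_paths.items():
            extract = read_species_lists(path)
            overlaps = compare_datasets(norm, extract, threshold=cfg.overlap_threshold)
            overlap_table(overlaps).to_csv(out / f"overlap_{label}.csv", index=False)
            overlap_long_format(overlaps).to_csv(
                out / f"overlap_{label}_long.csv", index=False)

    if cfg.extract_paths:
        stage("compare")(_compare)

    def _patterns() -> None:
        freq = record_frequency_distribution(norm)
        freq.to_frame().to_csv(out / "record_frequency.csv", index=False)
        freq.rank_frame().to_csv(out / "rank_abundance.csv", index=False)
        occ = country_occupancy_distribution(norm)
        occ.to_frame().to_csv(out / "country_occupancy.csv", index=False)
        for fld in ("life_form", "substrate"):
            categorical_summary(norm, fld).to_csv(out / f"{fld}_summary.csv", index=False)
        groups: dict[str, dict] = {}
        for label in summary["scope"]:
            sub = norm if label == "ALL" else norm.filter_countries([label])
            counts: dict[str, int] = {}
            for r in sub.records:
                if r.higher_taxon:
                    counts.setdefault(r.higher_taxon, set()).add(r.species_name)  # type: ignore
            if counts:
                groups[label] = {g: len(s) for g, s in counts.items()}
                groups[label]["_total"] = len(sub.species_set())
        if groups:
            world = world_group_counts()
            known = {scope: {g: n for g, n in d.items()
                             if g == "_total" or g in world}
                     for scope, d in groups.items()}
            representation_classification(
                known, world, WORLD_TOTAL_SPECIES).to_csv(
                out / "representation.csv", index=False)

    stage("patterns")(_patterns)

    def _spatial() -> None:
        sets = {c: s for c, s in norm.species_by_country().items() if s}
        if len(sets) < 4:
            manifest["warnings"].append(
                "spatial: fewer than 4 countries with species; stage skipped")
            return
        cents = (read_centroids(cfg.centroids_path) if cfg.centroids_path
                 else west_africa_centroids())
        missing = [c for c in sets if c not in cents]
        if missing:
            raise ConfigurationError(f"no centroid for countries {missing}")
        dj = jaccard_matrix(sets)
        dg = geo_distance_matrix({c: cents[c] for c in sets})
        dj.write_csv(out / "jaccard_matrix.csv")
        dg.write_csv(out / "geo_distance_km.csv")
        res = mantel_test(dj, dg, n_perm=cfg.n_perm, seed=cfg.seed)
        (out / "mantel.json").write_text(json.dumps({
            "r_M": res.r_M, "p_perm": res.p_perm, "n_perm": res.n_perm,
            "tail": res.tail, "seed": cfg.seed}, indent=1))
        mantel_correlogram(dj, dg, n_perm=cfg.n_perm, seed=cfg.seed).write_csv(
            out / "mantel_correlogram.csv")

    stage("spatial")(_spatial)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
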