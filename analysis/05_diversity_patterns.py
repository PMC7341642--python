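#!/usr/bin/env python
"""Descriptive patterns of the normalized checklist: how unevenly species are
recorded, how narrowly they are distributed, and which taxon groups are over-
or under-represented relative to worldwide shares.

These summaries describe documentation effort, not ecology.  Outputs ->
results/patterns/.
"""

from pathlib import Path

from mycocheck import (categorical_summary, country_occupancy_distribution,
                       read_checklist, record_frequency_distribution,
                       representation_classification)
from mycocheck.reference import WORLD_TOTAL_SPECIES, world_group_counts

IN = Path("results/normalized/checklist_normalized.csv")
OUT = Path("results/patterns")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cl = read_checklist(IN)
    cl.normalized = True

    freq = record_frequency_distribution(cl)
    freq.to_frame().to_csv(OUT / "record_frequency.csv", index=False)
    freq.rank_frame().to_csv(OUT / "rank_abundance.csv", index=False)

    occ = country_occupancy_distribution(cl, thresholds=[7])
    occ.to_frame().to_csv(OUT / "country_occupancy.csv", index=False)

    for fld in ("life_form", "substrate"):
        categorical_summary(cl, fld).to_csv(OUT / f"{fld}_summary.csv", index=False)

    world = world_group_counts()
    group_counts: dict[str, dict] = {}
    scopes = ["ALL"] + sorted(cl.species_by_country())
    for label in scopes:
        sub = cl if label == "ALL" else cl.filter_countries([label])
        per_group: dict[str, set] = {}
        for r in sub.records:
            if r.higher_taxon in world:
                per_group.setdefault(r.higher_taxon, set()).add(r.species_name)
        counts = {g: len(s) for g, s in per_group.items()}
        counts["_total"] = len(sub.species_set())
        group_counts[label] = counts
    rep = representation_classification(group_counts, world, WORLD_TOTAL_SPECIES,
                                        min_species=200)
    rep.to_csv(OUT / "representation.csv", index=False)

    print(f"species: {freq.s_obs}, records: {freq.total_records}")
    print(f"recorded once: {freq.histogram.get(1, 0)} ({freq.pct(1)}%), "
          f"twice: {freq.histogram.get(2, 0)} ({freq.pct(2)}%)")
    print(f"single-country species: {occ.histogram.get(1, 0)} ({occ.pct(1)}%); "
          f"in >7 countries: {occ.count_above(7)}")
    evaluated = rep[rep["status"] != "not_evaluated"]
    print(f"representation: {len(evaluated)} scope/group cells evaluated, "
          f"{(evaluated['status'] == 'overrepresented').sum()} over- and "
          f"{(evaluated['status'] == 'underrepresented').sum()} under-represented")
    print(f"outputs -> {OUT}/")


if __name__ == "__main__":
    main()
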