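#!/usr/bin/env python
"""Spatial structure of compositional similarity between countries.

Builds the Jaccard dissimilarity matrix of country species lists and the
great-circle distance matrix of country centroids, then runs the Mantel test
and a Mantel correlogram.  Under heavy single-country rarity, little or no
distance structure is expected.  Outputs -> results/spatial/.
"""

import json
from pathlib import Path

from mycocheck import (geo_distance_matrix, jaccard_matrix, mantel_correlogram,
                       mantel_test, read_checklist)
from mycocheck.reference import west_africa_centroids

IN = Path("results/normalized/checklist_normalized.csv")
OUT = Path("results/spatial")
SEED = 20_260_919


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cl = read_checklist(IN)
    sets = {c: s for c, s in cl.species_by_country().items() if s}
    cents = west_africa_centroids()

    dj = jaccard_matrix(sets)
    dg = geo_distance_matrix({c: cents[c] for c in sets})
    dj.write_csv(OUT / "jaccard_matrix.csv")
    dg.write_csv(OUT / "geo_distance_km.csv")

    res = mantel_test(dj, dg, n_perm=999, seed=SEED)
    (OUT / "mantel.json").write_text(json.dumps({
        "r_M": res.r_M, "p_perm": res.p_perm, "n_perm": res.n_perm,
        "tail": res.tail, "seed": SEED}, indent=1))
    cg = mantel_correlogram(dj, dg, n_perm=999, seed=SEED)
    cg.write_csv(OUT / "mantel_correlogram.csv")

    print(f"{len(sets)} countries, {sum(len(s) for s in sets.values())} "
          "country species-list entries")
    print(f"Mantel: r = {res.r_M:.3f}, P = {res.p_perm:.3f} "
          f"(tail={res.tail}, {res.n_perm} permutations)")
    first = cg.classes[0]
    print(f"correlogram first class [{first.lower_km:.0f}, {first.upper_km:.0f}] km: "
          f"r = {first.r_M:.3f}, corrected P = {first.p_corrected:.3f} "
          "(negative r at short distance = nearby countries more similar)")
    print(f"outputs -> {OUT}/")


if __name__ == "__main__":
    main()
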