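#!/usr/bin/env python
"""Reconcile the normalized checklist with the database-style extract.

Counts shared and unique species per country and for the whole region, and
flags countries where the extract adds at least 25% to known richness.
Outputs -> results/overlap/.
"""

from pathlib import Path

from mycocheck import compare_datasets, read_checklist
from mycocheck.comparison import overlap_long_format, overlap_table, read_species_lists

IN_CL = Path("results/normalized/checklist_normalized.csv")
IN_EX = Path("results/synthetic/extract.csv")
OUT = Path("results/overlap")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cl = read_checklist(IN_CL)
    cl.normalized = True  # produced by the normalization step
    extract = read_species_lists(IN_EX)

    overlaps = compare_datasets(cl, extract, threshold=25.0)
    overlap_table(overlaps).to_csv(OUT / "overlap_by_scope.csv", index=False)
    overlap_long_format(overlaps).to_csv(OUT / "overlap_long.csv", index=False)

    region = overlaps["ALL"]
    print(f"checklist {region.n_a} species, extract {region.n_b} species, "
          f"shared {region.shared}")
    print(f"extract adds {region.only_b} species "
          f"(+{region.pct_added_by_b:.1f}% of checklist richness)")
    flagged = [s for s, o in overlaps.items()
               if s != "ALL" and o.substantial_addition]
    print(f"countries with >= 25% added by the extract: {len(flagged)} "
          f"({', '.join(sorted(flagged)) or 'none'})")
    print(f"outputs -> {OUT}/")


if __name__ == "__main__":
    main()
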