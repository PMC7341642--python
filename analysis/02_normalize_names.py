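#!/usr/bin/env python
"""Normalize the simulated checklist's names against its synonym table.

Synonyms are replaced by accepted names, infraspecific names collapsed to
binomials, supraspecific records dropped; unmatched names are kept verbatim
(they usually represent genuinely distinct taxa).  Writes the normalized
checklist and the full substitution log to results/normalized/.
"""

from pathlib import Path

from mycocheck import SynonymTable, normalize_names, read_checklist

IN = Path("results/synthetic")
OUT = Path("results/normalized")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cl = read_checklist(IN / "checklist.csv")
    syn = SynonymTable.read_csv(IN / "synonyms.csv")
    norm, log = normalize_names(cl, syn)

    norm.write_csv(OUT / "checklist_normalized.csv")
    log.to_frame().to_csv(OUT / "normalization_log.csv", index=False)

    before, after = len(cl.species_set()), len(norm.species_set())
    print(f"records: {len(cl)} in, {len(norm)} out")
    print(f"distinct names: {before} -> {after} "
          f"({before - after} merged by synonymy)")
    print(log.summary())
    print(f"outputs -> {OUT}/")


if __name__ == "__main__":
    main()
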