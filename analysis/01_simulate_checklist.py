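#!/usr/bin/env python
"""Generate the synthetic study inputs: a checklist with nomenclatural noise,
its synonym table and ground truth, and a database-style species extract.

The checklist emulates a literature-compiled regional inventory: publications
of very unequal size, lognormal detectability, small country ranges, uneven
per-country effort.  Outputs land in results/synthetic/.
"""

from pathlib import Path

from mycocheck import (SimulationConfig, inject_name_noise,
                       make_database_extract, simulate_checklist)
from mycocheck.synthetic import write_extract_csv

OUT = Path("results/synthetic")
SEED = 20_260_919


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)  # defaults: S_true=1000, 200 publications
    clean, truth = simulate_checklist(cfg)
    noisy, noise_log = inject_name_noise(clean, truth, p_synonym=0.15,
                                         p_misid=0.01, seed=SEED + 1)
    extract = make_database_extract(truth, coverage=0.45, overlap_bias=0.7,
                                    seed=SEED + 2, reference=clean)

    noisy.write_csv(OUT / "checklist.csv")
    truth.synonym_table.to_frame().to_csv(OUT / "synonyms.csv", index=False)
    truth.write_json(OUT / "ground_truth.json")
    noise_log.to_csv(OUT / "noise_log.csv", index=False)
    write_extract_csv(extract, OUT / "extract.csv")

    print(f"true species pool: {truth.S_true}")
    print(f"checklist: {len(noisy)} records, {len(noisy.species_set())} distinct "
          f"names, {len(noisy.publications())} publications")
    print(f"name noise: {len(noise_log)} perturbed records "
          f"({(noise_log['action'] == 'synonym').sum()} synonyms, "
          f"{(noise_log['action'] == 'misidentification').sum()} misidentifications)")
    n_extract = len(set().union(*extract.values()))
    print(f"database extract: {n_extract} species over {len(extract)} countries")
    print(f"outputs -> {OUT}/")


if __name__ == "__main__":
    main()
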