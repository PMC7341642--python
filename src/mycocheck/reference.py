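"""Packaged reference tables for the West African study region.

* ``west_africa_summary()`` — the printed per-country summary of the
  compiled checklist (vascular-plant richness, fungal records/species/
  publication counts, and the published estimator values).  These are
  *inputs* for the ratio extrapolation and display checks, not outputs of
  this package.
* ``west_africa_centroids()`` — editable country centroid coordinates
  (decimal degrees) for the 14 countries, for geographic distance matrices.
* ``world_group_counts()`` — a per-order worldwide species-count table.
  This file is a synthetic stand-in: the anchored entries (Meliolales,
  Russulales, and the 138,054 world total) match published shares; the rest
  are plausible placeholders for exercising the classification rule.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Total described fungal species worldwide used as the denominator of the
#: taxon-representation classification.
WORLD_TOTAL_SPECIES = 138_054


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("mycocheck").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def west_africa_summary() -> pd.DataFrame:
    """Per-country checklist summary (printed reference values)."""
    df = _read("west_africa_table1.csv")
    return df.rename(columns={"fungal_species": "fungal_species"})


def west_africa_centroids() -> dict[str, tuple[float, float]]:
    df = _read("west_africa_centroids.csv")
    return {str(r["country"]): (float(r["lat"]), float(r["lon"]))
            for _, r in df.iterrows()}


def world_group_counts() -> dict[str, int]:
    df = _read("world_group_counts_synthetic.csv")
    return dict(zip(df["group"], df["species_worldwide"].astype(int)))
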