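# mycocheck

Checklist analytics for regional fungal biodiversity.

Compiled checklists — occurrence records of fungi and fungus-like organisms
gathered from literature, one record per citation of a species for a country
in a publication — are often the only species-diversity information available
for under-explored regions such as West Africa. This package implements the
quantitative pipeline such a compilation needs: taxonomic name normalization
against a synonymy backbone, incidence-based richness estimation, species
accumulation curves, plant-ratio extrapolation of expected richness,
reconciliation with database extracts (GBIF- or fungarium-style species
lists), descriptive diversity patterns, and spatial similarity analysis. A
synthetic-checklist generator with known ground truth makes every stage
testable without any external data.

It is written for biodiversity informaticians and mycologists who compile or
analyse national/regional checklists, and for anyone who needs seedable,
unit-tested implementations of the underlying estimators.

## Methods

With publications (or single records) as sampling units, let *m* be the
number of units, *m_i* the number of units citing species *i*, *S_obs* the
observed species count, and *Q1*, *Q2* the numbers of species found in
exactly one / two units.

- **Chao2** (classic, small-sample corrected): with *A* = (*m*−1)/*m*,
  *Ŝ* = *S_obs* + *A·Q1²*/(2*Q2*), with the standard analytic variance; a
  bias-corrected form is used when *Q2* = 0.
- **Bootstrap richness**: *Ŝ* = *S_obs* + Σᵢ (1 − *m_i*/*m*)^*m*; its
  standard error comes from seeded resampling of sampling units.
- **Exact accumulation curve** (Mao Tau):
  E[*S*(*k*)] = *S_obs* − Σᵢ C(*m*−*m_i*, *k*)/C(*m*, *k*), evaluated by
  log-gamma so record-level matrices with tens of thousands of columns are
  stable; a permutation-based curve with SDs is also available.
- **Hawksworth extrapolation**: expected fungal richness *E* = *R·P* from
  the area's vascular-plant richness *P* at the working ratio *R* = 6
  fungal species per plant species; knownness = 100·*S_obs*/*E*.
- **Dataset overlap**: shared/unique species between two normalized lists,
  per country and for the union, with a configurable
  "adds ≥ 25%" flag.
- **Mantel test / correlogram**: Pearson correlation of Jaccard
  dissimilarity against great-circle centroid distance, permutation p-values
  (resolution exactly 1/(n_perm+1)), equal-width distance classes (Sturges)
  with progressive Holm correction.

## Worked example

```python
from mycocheck import (SimulationConfig, simulate_checklist, inject_name_noise,
                       normalize_names, build_incidence, chao2,
                       bootstrap_richness, hawksworth_estimate)

cfg = SimulationConfig(S_true=300, n_publications=80, seed=42)
clean, truth = simulate_checklist(cfg)
noisy, _ = inject_name_noise(clean, truth, p_synonym=0.2, p_misid=0.0, seed=1)
cl, log = normalize_names(noisy, truth.synonym_table)
print(log.summary())

im = build_incidence(cl, sample_unit="publication")
print(f"S_obs={im.S_obs} m={im.m} Q1={im.Q1} Q2={im.Q2}")
print("chao2:", chao2(im).display())
print("bootstrap:", bootstrap_richness(im, n_boot=500, seed=1).display())

hw = hawksworth_estimate(S_obs=4843, P=7072)
print(f"expected richness E={hw.E}, known={hw.pct_known_display}%")
```

prints

```
292 substitutions, 0 infraspecific collapses, 0 supraspecific drops, 0 names not in the synonym table
S_obs=278 m=80 Q1=54 Q2=39
chao2: 315 ± 13
bootstrap: 305 ± 18
expected richness E=42432, known=11.4%
```

The simulation hides 300 true species behind 80 publications with strongly
heterogeneous detectability and 20% synonym usage; normalization merges the
synonyms back, 278 species are observed, and both estimators move the
estimate toward (but, as expected for nonparametric lower-bound style
estimators under heavy rarity, not all the way to) the truth. The last two
lines apply the 6:1 fungus:plant ratio to the printed West African totals:
with 7072 vascular plants, 42,432 fungal species are expected, of which the
4843 known represent 11.4%.

## Analysis drivers

`analysis/01_simulate_checklist.py` … `06_spatial_similarity.py` run the full
study on synthetic data end to end (simulate → normalize → estimate richness
→ reconcile with a database extract → diversity patterns → spatial
similarity), each printing what it found and writing tables under
`results/`. A `mycocheck` CLI with the same stages as subcommands
(`validate`, `normalize`, `estimate`, `hawksworth`, `compare`, `patterns`,
`mantel`, `simulate`, `run`) is installed as well.

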