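# Methods

## Data model

A checklist is an ordered list of occurrence records; each record is one
citation of a scientific name for a country in one publication, optionally
with year, higher taxon, life form, and substrate. A record is one input
row: duplicate (species, country, publication) rows are retained by default,
because compiled checklists count repeated citations as records; an explicit
`deduplicate()` switch collapses them. Countries come from a configured set
(the 14 West African countries by default); rows with unknown countries are
loaded and flagged in a validation report, never silently dropped, so the
input remains auditable.

Rank is inferred from name structure. One word means supraspecific; an
infraspecific marker (`var.`, `subsp.`, `ssp.`, `f.`, `forma`,
case-insensitive) after the epithet means infraspecific; `cf.`/`aff.`
qualifiers mean the identification is not confidently at species rank, and
such names are treated as supraspecific for normalization — a conservative
choice, since counting them as species would inflate richness with uncertain
determinations. Names are compared after trimming, whitespace squeezing,
hybrid-sign removal, and case-normalizing the genus epithet only; no author
string parsing is attempted. Orthographic variants are treated as distinct
species unless the synonym table links them: fuzzy matching would make the
counts irreproducible.

Normalization optionally collapses infraspecific names to binomials, then
replaces synonyms by accepted names via the synonym table (chains followed
to a configurable depth, default 5; cycles are errors). Names absent from
the table are kept verbatim and logged as unknown, because unmatched names
in compiled checklists usually denote genuinely distinct taxa; dropping them
would understate richness. The operation is idempotent, never increases the
distinct-species count, and changes the record count only by the
supraspecific drops.

## Richness estimation

Sampling units are publications (mirroring how checklist data accumulate) or
individual records; both views are supported because accumulation has been
reported against either axis. From the species × unit presence matrix the
estimators use only the incidence frequencies.

Chao2 uses the classic small-sample-corrected form with `A = (m-1)/m`:
`S_obs + A*Q1^2/(2*Q2)` and the standard analytic variance; at `Q2 = 0` the
bias-corrected fallback `S_obs + A*Q1*(Q1-1)/2` avoids division by zero.
This is the conventional incidence-based definition; the test suite
cross-checks value and standard error against vegan's `specpool`, which
agrees to numerical precision on matrices exercising the classic branch.

The bootstrap estimator's point value is the closed form
`S_obs + sum_i (1 - m_i/m)^m`; its standard error is the SD of re-estimates
over seeded resamples of the sampling units (default B = 1000). A resampled
rather than closed-form SE was chosen because it is simpler, seedable, and
directly checkable against a Monte-Carlo oracle.

The exact accumulation curve evaluates binomial ratios through log-gamma,
which stays finite when records are the sampling unit and `m` reaches the
tens of thousands. The expected curve is clipped to be non-decreasing to
absorb last-digit float noise, and pinned to `S_obs` at `k = m` (where the
formula is exact). The permutation method reports the per-effort mean and SD
over seeded random orderings.

The Hawksworth extrapolation multiplies vascular-plant richness `P` by the
working ratio `R = 6` fungal species per plant species; `E = R*P` and
`%known = 100*S_obs/E`. An `S_obs` above `E` sets a flag rather than raising:
the ratio is a working hypothesis, not a bound. Estimator values are never
truncated at `E`; the two kinds of estimate are reported side by side.
Percentages are displayed rounded half-up to one decimal (banker's rounding
would turn 2.565% into 2.5 rather than the conventional 2.6); raw values are
kept in all exports.

## Dataset reconciliation

Species identity after normalization is exact string equality of accepted
binomials. Comparison is two-level: per country using each dataset's own
country attribution, and for the whole region using the union over
countries; a species the two datasets place in different countries is unique
on both sides at country scope but shared regionally. The
"substantial addition" flag defaults to 25% of the reference list's
richness and is configurable.

## Diversity patterns

Record-frequency and country-occupancy distributions are per-species counts
with histograms and half-up percentages; rank lists break ties
alphabetically so outputs are deterministic. Taxon-group representation
compares a group's local percentage share against its worldwide share:
more than double is over-represented, less than half under-represented,
scopes with fewer than 200 species are not evaluated (too noisy); the factor
and threshold are parameters. Life-form summaries assign a species whose
form set matches a configured combination (default saprotroph +
plant-parasite) to that combined category and multi-count other multi-form
species over `S_obs`; substrate summaries always multi-count, with
percentages over assignments. All pattern outputs describe collection
activity, not ecological composition.

The packaged worldwide group-count table is a synthetic stand-in (flagged in
its filename): only its total (138,054) and two anchored shares (Meliolales
1.8%, Russulales 2.3%) reflect published values; the remaining counts are
plausible placeholders for exercising the classification rule.

## Spatial analysis

Compositional distance is Jaccard dissimilarity of country species sets
(a metric; the suite property-tests the triangle inequality). Geographic
distance is the haversine great-circle distance between country centroids
(editable CSV shipped with the package; deriving centroids from polygons is
out of scope). The Mantel statistic is the Pearson correlation of
lower-triangle entries; the null is built by jointly permuting rows and
columns of the second matrix, with `p = (1 + #extreme)/(n_perm + 1)`, so the
p-value resolution is exactly `1/(n_perm + 1)`. Defaults — 999 permutations,
one-tailed "greater" — follow common usage in vegetation ecology software
and are recorded in output metadata. Zero-variance matrices return
`r = 0, p = 1` instead of failing.

The correlogram cuts observed distances into equal-width classes (Sturges'
rule on the pair count by default) and Mantel-tests dissimilarity against
each class's binary membership matrix, two-sided by default, correcting
progressively: class *k*'s corrected p is its Holm-adjusted value among the
first *k* classes in increasing distance order. Because dissimilarity is
tested against membership, positive spatial structure at short distances
appears as negative r in the first classes; the output documents this sign
convention. Empty classes are dropped with a warning; classes whose pairs do
not touch every label are flagged.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume:
publications as sampling events of very unequal size (negative binomial,
default mean 19 records, dispersion 0.6), lognormal per-species
detectability (default sigma 1.5, producing uniques-heavy incidence
matrices like real compilations), small geometric country ranges (default
P(size=k) ~ Geometric(0.55), so most species occupy one or two countries),
uneven per-country effort (seeded lognormal weights, sigma 1), optional
publication-level taxon focus (default probability 0.3, mimicking
specialist monographs), life-form/substrate labels drawn from
checklist-like proportions, and nomenclatural noise: each record can use a
synonym (every species gets at least one generated synonym) or a
misidentified name. Default pool size is 1000 species over 14 countries and
200 publications — large enough to show the rarity structure, small enough
that every stage runs in seconds.

What it does **not** emulate: temporal dynamics of publication activity,
taxonomic correlation between neighbouring publications, within-country
spatial structure, shared detectability trends across related species, or
any fit to a real checklist. Passing recovery tests therefore show that the
estimators and the normalization round-trip behave correctly under the
assumed sampling model, not that any real checklist satisfies that model.

Distance-decay ranges are available (`range_model="distance-decay"`, scale
800 km on a synthetic centroid grid) for spatial-power experiments; the
default is uniform because compiled checklists are dominated by effort, not
geography.

## Numerical and testing choices

Seeds: every stochastic operation takes an explicit seed and threads it
through `numpy.random.default_rng`; one generator stream per operation keeps
module outputs independently reproducible. Permutation counts in tests are
chosen so p-value granularity does not mask the property under test.
Monte-Carlo test sizes (500 replicates for SE calibration, 200 for recovery,
1000 null simulations for type-I error) keep the whole suite under ten
seconds while leaving the binomial noise of each check well inside its
tolerance. Independent oracles: exhaustive permutation enumeration for the
Mantel p-value, all-orderings enumeration for the accumulation curve,
vegan's `specpool` (via Rscript) and scikit-bio's Mantel statistic as
third-party cross-checks.

## Limitations

- The published estimator values for the real West African checklist
  ("7485 ± 1445", "900 ± 151") are not reproduced: they require the full
  supplementary record set and the producing tool's exact variant, neither
  of which is bundled. Estimator correctness is established by property and
  oracle tests instead.
- Nomenclatural handling is string-based; no validity checking, author
  parsing, or live queries to nomenclatural databases.
- The correlogram's class definition, permutation count, and tail are
  configurable because conventions differ; outputs record the settings used.
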