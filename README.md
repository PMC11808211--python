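# vacniche

Statistical pipeline for studying what happens to a mammal's parasites when
the host invades a new range. When a host establishes outside its native
range, each of its parasites has one of four **fates**: *retained* (sampled
from the focal host in both ranges), *lost* (native range only), *acquired*
(non-native range only), or *not acquired* (circulating on other hosts in
the invaded community but never on the focal host). Two classic ideas hang
on these fates:

* **Enemy release** — invaders benefit by leaving parasites behind; the net
  version compares parasite species richness (PSR) between ranges after
  accounting for acquisitions.
* **Vacated niche** — a lost parasite leaves an open niche most likely
  filled by a *related* parasite, so acquired parasites should sit
  taxonomically close to lost ones.

`vacniche` implements the full analysis chain for association-record data of
the kind compiled in literature-derived host–parasite databases, plus a
synthetic-data generator with a tunable vacated-niche effect so every stage
is testable without any downloads.

## The core statistic

Parasite relatedness is proxied by a fixed-depth taxonomic tree: seven ranks
(kingdom … species), unit branch lengths, so the distance between two
species is `2 × (7 − depth of their most specific shared taxon)` — an even
integer in {0, …, 14}. For each focal host and parasite type, the observed
statistic is the mean over acquired parasites of the minimum distance to the
lost set. Two resampling null models contextualise it:

* **random acquisition** — 1000 pseudo-acquired sets resampled from the pool
  of lost + not-acquired parasites (potential non-native associations);
* **RRA** (random-relative-to-associations) — 100 pseudo-acquired sets from
  the host's known associations (retained + lost + acquired).

Each model yields `z = (observed − null mean) / null sd`; negative z means
lost and acquired parasites are more related than chance, with one-tailed
significance at `z < −1.645`. Results based on fewer than 10 comparisons are
flagged low-n; combinations with no losses or no acquisitions of a type are
reported as not computable.

The enemy-release side provides a phylogenetic paired t-test of PSR between
ranges (paired differences modelled as multivariate normal with covariance
`σ²·C(λ)`, Pagel's λ profiled by maximum likelihood, `t = μ̂/SE(μ̂)` on
`n − 3` df), proportional PSR change `1 − PSR_nonnative / PSR_native`,
Baselga's partition of Sørensen dissimilarity into turnover and nestedness,
mean Bray–Curtis environmental dissimilarity between ranges, and
single-predictor OLS regressions. Lost-vs-acquired trait comparisons use
Mann–Whitney U (host-specificity scores) and an r×2 Fisher exact test
(parasite types; non-exclusive transmission modes).

## Worked example

Generate a synthetic study with moderate niche clustering and run the null
models:

```bash
vacniche simulate --n-hosts 5 --theta 1.5 --seed 42 --out-dir sim
vacniche null-models --associations sim/associations.csv \
    --taxonomy sim/taxonomy.csv --seed 42 --out-dir results
```

or equivalently run the numbered drivers `analysis/01_simulate.py` …
`analysis/06_calibration_and_power.py`. On this bundle the null-model stage
prints:

```
50 (host x type x model) results -> results/null_models.csv
  random_acquisition: median z = -2.28, significant (z < -1.645): 21/25
  rra: median z = -1.73, significant (z < -1.645): 14/25
  Spearman z ~ n_comparisons: rho = -0.245, p = 0.087
```

i.e. with a true clustering effect (θ = 1.5) most host × parasite-type
combinations give significantly negative z under both null models, and z is
not significantly correlated with the number of comparisons. The calibration
driver summarises the generator sweep (500 simulated invasions per level):

```
 theta  n_usable  mean_z  significance_rate  negative_z_rate_powered
   0.0       500  -0.064              0.060                    0.527
   1.0       500  -2.863              0.822                    0.993
   3.0       500  -3.299              0.910                    0.976
```

At θ = 0 the z distribution is centred near zero with a ~5% false-positive
rate; as θ grows the distribution shifts strongly negative.

## Layout

```
src/vacniche/    library: types, io, fates, taxodist, nullmodels, enemy,
                 traits, synthetic, experiments, pipeline, cli
analysis/        numbered narrative drivers writing results/
scripts/         acceptance.py
tests/           pytest suite (unit, property-based, acceptance)
docs/methods.md  models, assumptions, parameter choices, limitations
```
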