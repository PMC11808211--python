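# Methods

This note documents the models implemented in `vacniche`, the assumptions
and numerical choices behind them, what the synthetic-data generator does and
does not emulate, and known limitations.

## Fate classification

Fates are focal-host-centric and per invasion (one focal host × one invaded
region). From association records (host, parasite, range label):

* retained = focal-host parasites sampled in both ranges;
* lost = focal host, native only; acquired = focal host, non-native only;
* not acquired = parasites of *other* hosts in the non-native records that
  were never sampled from the focal host.

Every parasite receives exactly one fate. A parasite the focal host lost may
still circulate on other hosts in the invaded range; its fate stays `lost`
and its community presence is kept separately (`community_nonnative`), so it
still contributes to the random-acquisition pool (which is lost ∪
not-acquired regardless). Native-range records of non-focal hosts are
ignored: the invaded community is defined by non-native records only.

Parasite identity is the trimmed, whitespace-normalised species name; no
synonym resolution is attempted. Range membership is an input column — GIS
range construction is a data-preparation concern, deliberately outside this
package.

Richness identities hold by construction and are asserted against the five
well-studied invasive mammals' published counts: native PSR = retained +
lost, non-native PSR = retained + acquired.

## Taxonomic distances

Each parasite carries a seven-rank classification. The tree has the root
above kingdom, one node per taxon, unit branch lengths, every leaf at depth
7; the distance between species is twice the number of ranks below their
most specific shared taxon (0 iff identical, 14 when only the root is
shared). All leaves share a depth, so the distance is ultrametric:
`d(p, r) ≤ max(d(p, q), d(q, r))`.

Missing rank entries become per-species placeholders (`?family:SpeciesX`),
so incomplete classification can only *decrease* apparent relatedness, never
inflate it. Distances are defined within a parasite type only; each type
gets its own tree and querying a species absent from a tree is an error.

## Null models

Observed statistic per (host × type): the mean over acquired parasites of
the minimum distance to the lost set ("how close is each acquired parasite
to its nearest lost relative"). The orientation is acquired→lost: the
number of comparisons equals the number of acquired parasites of that type.
Fewer than 10 comparisons flags the result low-n. If the host lost none or
acquired none of a type, the statistic is not computable and the combination
is reported as a missing point, never silently dropped.

Null distributions are built by redrawing pseudo-acquired sets of the true
size, with replacement, from

* random-acquisition pool = lost ∪ not-acquired (1000 draws), or
* RRA pool = retained ∪ lost ∪ acquired (100 draws),

recomputing the identical statistic each draw. z = (observed − null mean) /
null sd, with the sd over replicate statistics using an n−1 denominator;
quantile = fraction of null statistics ≤ observed. A null with zero spread
is flagged degenerate (z undefined, never significant) rather than dropped.
One-tailed significance is z strictly below the rounded 5% normal quantile,
−1.645. The resampling unit is configurable (`null_unit="set"` default,
`"pair"` redraws single minima) because the level at which "draws" operate
is a genuine modelling choice; set-level preserves the statistic's sampling
unit and gives z a clean interpretation.

**Self-pairs.** A pseudo-acquired parasite drawn from the pool may itself be
a lost species. Its minimum distance is taken to the *other* lost species —
a parasite cannot fill its own vacated niche, and scoring self-pairs as
distance 0 would drag the null mean down mechanically (an effect worth
roughly +0.4 to +0.9 z units at realistic pool compositions, destroying
calibration). A lone lost species with no other lost relative is excluded
from its own pool. With this convention a uniformly drawn acquired set is
exchangeable with the null draws up to finite-pool effects.

**Residual finite-pool bias.** Exchangeability is not exact: a pool member
that is a lost species sees one fewer lost reference than a true acquired
parasite does, an O(1/|lost|) asymmetry that no self-pair convention can
remove. Under the default generator conditions this leaves the θ = 0 mean z
at about −0.05 to −0.07 — well inside the ±0.15 calibration band, but the
calibration checks use 500 simulated invasions so that the Monte-Carlo error
of the check itself (SE ≈ 0.05) does not dominate this small bias.

An exhaustive oracle (`exhaustive_null`) enumerates every with-replacement
pseudo-set (guard 10⁶ outcomes) and returns exact null moments; the test
suite verifies the sampled nulls against it, and verifies the enumeration
against the closed form for a mean of iid draws from the pool profile.

## Enemy release

* **Phylogenetic paired t-test.** Paired PSR differences are multivariate
  normal with mean μ and covariance σ²·C(λ); C is the host tree's
  shared-path-length matrix, λ ∈ [0, 1] scales off-diagonals. λ is profiled
  by bounded ML search (tolerance 1e−8, boundary candidates checked);
  t = μ̂/SE(μ̂) on n−3 df (n−2 when λ is fixed). The residual variance uses
  an n−1 denominator by default so that at λ = 0 on an ultrametric tree the
  statistic reduces *exactly* to the classical paired t; `variance="ml"`
  gives the full-ML scaling, which matches the established R implementation
  to ~1e−5 relative on fixtures (frozen oracle values in the tests). At
  least 4 hosts are required (df ≥ 1); equal differences are degenerate.
* **PSR change** = 1 − PSR_nonnative / PSR_native (native PSR must be > 0).
* **Beta partition** (Sørensen family): with a shared, b native-only, c
  non-native-only species, β_sor = (b+c)/(2a+b+c), turnover β_sim =
  min(b,c)/(a+min(b,c)), nestedness β_sne = β_sor − β_sim. Proportions of
  β_sor are NaN-flagged when β_sor = 0. β_sor = β_sim + β_sne by
  construction and by property test.
* **Environmental dissimilarity**: each shared climate variable is min–max
  scaled to [0, 1] over the pooled locations (Bray–Curtis needs non-negative
  inputs, and raw bioclim units would let large-magnitude variables
  dominate; the scaling is a package choice, config-overridable by
  pre-scaling inputs). Constant variables are dropped with a warning. The
  statistic is the mean Bray–Curtis distance over all (native location,
  non-native location) pairs; symmetric and row-order invariant.
* **Regressions**: OLS of each response (PSR change, turnover proportion,
  nestedness proportion, β_sor) on each predictor (time since invasion,
  population density, log home range, environmental dissimilarity), one at a
  time; home-range area is log-transformed. p-values are reported
  unadjusted — these are exploratory fits, not confirmatory tests.

## Trait tests

Mann–Whitney U (two-sided, tie-corrected, exact method for small untied
samples) compares host-specificity score distributions of lost vs acquired
parasites; the scores are inputs, not recomputed. Parasite-type (5×2) and
transmission-mode (4×2) tables are tested with an r×2 Fisher exact test:
conditional on both margins, two-sided by summing the probability of every
table no more probable than the observed one; exhaustive enumeration up to
10⁷ tables, beyond that Monte-Carlo with 10⁵ Patefield-sampled tables, a
seed, and a reported standard error. Transmission modes are non-exclusive: a
parasite with k modes adds one count to each of its k rows, so column sums
may exceed parasite counts. Traits whose table has fewer than two occupied
categories (or an empty fate column) are skipped as untestable.

## Synthetic data generator

The generator emulates the *statistical structure* the analyses assume, per
focal host × parasite type: candidate retained / lost / not-acquired sets
drawn uniformly from a random taxonomy, then an acquired set drawn without
replacement from the lost ∪ not-acquired candidates with weight
exp(−θ·d), where d is the candidate's (self-excluded) minimum distance to
the lost candidates. Drawn species leave their candidate sets, so
classifying the emitted records reproduces the ground truth exactly. θ = 0
gives uniform acquisition (matching the random-acquisition null); large θ
forces acquisition of the closest relatives of lost parasites. The
exponential kernel is the simplest monotone choice; θ is the recoverable
effect parameter. A config switch restricts candidates to never-hosted
species for pool-mismatch sensitivity analyses.

Default conditions (chosen once as the study conditions): per host × type,
retained ~ U[2,10], lost ~ U[5,20], acquired ~ U[2,8], not-acquired ~
U[15,40] — magnitudes echoing per-type counts of well-sampled mammal
invasions; taxonomies of 80 species per type generated by a
Chinese-restaurant partition at each rank (concentrations 0.6, 0.6, 1.0,
1.5, 2.5 from phylum to genus), which yields a few higher taxa per type and
genera holding ~2–3 species, so congeners of lost parasites exist in
realistic numbers. Host trees are ultrametric coalescent simulations; traits
are lognormal/uniform; specificity scores standard normal; climate tables
are 19 Gaussian variables with a range-level mean shift.

Not emulated: sampling-effort heterogeneity across hosts and parasites,
spatial structure within ranges, name synonymy noise, and correlations
between traits and fates. Passing calibration/power checks on these
synthetics therefore demonstrates correctness of the statistical machinery
under the stated model, not robustness to the observational biases of real
literature-derived data.

## Pipeline and reproducibility

Stages (fates → null models / enemy release / trait tests) run in dependency
order; requesting a downstream stage without its upstream output is an
error naming the missing stage. Every stochastic stage derives its own
substream seed from the master seed and a stable CRC-based label, so adding
a stage never perturbs another stage's draws and full runs are byte-for-byte
reproducible. Tables are plain CSV/TSV with full-precision floats;
write-then-read reproduces every value exactly.

Problem sizes used by the shipped analyses: 5 simulated invasions for the
narrative drivers; 500 single-type invasions per θ level for calibration and
power (≈3 s per level on one core).

## Known limitations

* The taxonomic distance treats all rank steps as equal; it is a proxy, not
  a calibrated phylogeny.
* The z statistic carries the small negative finite-pool bias described
  above; it is negligible against the −1.645 decision threshold but visible
  in high-precision calibration averages.
* The r×2 Fisher test and Mann–Whitney U assume independent parasites;
  phylogenetic pseudo-replication among congeners is not corrected.
* With five hosts the regressions and the paired t-test have very low power;
  they are reported with unadjusted p-values as exploratory summaries.
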