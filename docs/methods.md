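# Methods

## Problem and model

`metawebkit` turns a curated table of literature observations of species
interactions into a *metaweb*: the regional pool of potential
consumer-resource links, weighted by a semi-quantitative interaction
strength, stratified by season, and organised into interaction layers
(predation `Pr`, scavenging `Sc`, herbivory `He`, pollination `Po`,
kleptoparasitism `Kl`, coprophagy `Co`, detritus `De`). The design target is
a Svalbard-style high-Arctic system, but nothing in the code is specific to
a species list.

The central difficulty is that literature sources quantify interaction
strength in incommensurable native metrics (frequency of occurrence,
relative biomass, caloric fraction, prey counts, ...). The scaling procedure
is:

1. **Standardization.** Within each study-consumer pair, raw values are
   rescaled so the consumer's interactions sum to 100%. This removes the
   metric's scale; it requires a uniform metric within the pair, and a mixed
   pair is rejected as incommensurable rather than converted (no defensible
   conversion exists between, say, occurrence frequency and biomass).
2. **Ordinal binning.** Each standardized share is mapped to a log2-spaced
   ordinal score: 0 absence (0%), 1 marginal (0–5%], 2 auxiliary (5–20%],
   4 primary (20–67%], 8 keystone (>67%, an interaction roughly twice as
   strong as any other the consumer has). Bins are upper-inclusive:
   "over 67%" defines the keystone class, so 67% itself is primary; the 67
   cut is applied as the literal printed constant, not 200/3.
3. **Seasonal averaging.** Per (consumer, resource, layer, season), the
   per-study scores are averaged with equal weights (no study is privileged
   by sample size or metric) and rounded half-away-from-zero to one decimal,
   so multi-study links can take intermediate strengths in [0, 8].

Each study is assigned a season from its covered calendar months: winter is
November–March, summer is May–September, and the block holding a strict
majority of *all* covered months wins. April and October belong to neither
block; studies dominated by them, or tied between blocks, are *unclassified*
and excluded from seasonal averaging with a logged warning. (An alternative
reading — comparing only the two block counts — agrees on every clear-cut
case; the strict-majority form is the more conservative convention for
mixed-month studies.)

Two complements handle data scarcity:

* **Case-study floor.** A link-season documented only by anecdotal case
  reports receives the constant minimal averaged score 0.1, however many
  reports exist — the floor encodes "the link exists" and nothing more. When
  any quantitative study covers the link-season, case reports are ignored.
  A case report whose months classify to a season floors only that season;
  a monthless (or unclassifiable) report is season-agnostic and floors every
  season lacking quantitative data. The season-agnostic rule is this
  package's convention; it errs toward recording existence rather than
  silently dropping anecdotes.
* **Winter extrapolation.** Summer strength can be copied to winter for an
  explicit, curator-supplied list of (consumer, resource, layer) triples —
  never automatically. Extrapolation refuses to overwrite a measured winter
  strength, but replaces a case-only winter floor, which is strictly less
  informative than a summer measurement.

## Metaweb assembly

Edges run **resource → consumer** (energy-flow direction), with the layer
and season as edge attributes in a `networkx.MultiDiGraph`; one edge per
(consumer, resource, layer, season) key, zero-strength links are no edges.
Pollination stays in the same unipartite graph (plant → pollinator, energy
via nectar and pollen). Kleptoparasitism is book-kept with the robbed victim
as the resource (victim → kleptoparasite): the stolen energy originates in
the victim's foraging effort, and this keeps the layer unipartite without
inventing three-way edges.

Layers supported by fewer than `min_links` *measured* links (default 3) are
dropped wholesale — case-only floors and extrapolations do not count as
support, since a layer alive only on anecdotes is unresolved. The default
of 3 is this package's choice of the smallest count distinguishable from an
isolated observation; the threshold is exposed as a parameter.

Subwebs are induced restrictions to a consumer set × resource set × layer
set. Crossover profiles sum a consumer's incoming strengths by resource
realm (marine / terrestrial / coastal) and report fractions; a consumer with
no incoming energy under the requested filter has an undefined split
(`None`), not a zero vector.

## Knowledge-bias scoring

Literature-derived networks inherit literature bias, so each node gets an
explicit knowledge score: every (publication, species) pair contributes 1 if
the publication measured interaction strength for that species and 0.25 if
it was a case study; a publication that does both for the same species
counts once, as measured. Node sums divided by the node's species count give
*weighted knowledge*, displayed to two decimals. Records from review
articles flagged `excluded_review` are removed before scoring (a review
re-reports primary studies and would double-count them); the pipeline
applies the same exclusion before scaling. Because the interaction-record
schema resolves only nodes, an optional `species` column carries the
within-node focal taxon; when blank, the node itself forms the pair.

The accumulation curve is the cumulative count of distinct studies by
publication year (a study appearing under two years is counted at the
earlier one).

## Synthetic literature generator

`SynthConfig`/`generate_records` emulate the statistical structure the
analysis assumes, so every stage runs without external data:

* Each consumer has a latent true diet: Dirichlet(α = `true_diet_concentration`,
  default 1.0, a flat prior over the simplex) shares across 3–8 resource
  nodes, each pair carrying one fixed layer drawn from `layer_weights`.
* Studies sample consumers with flagship taxa oversampled by
  `flagship_oversampling` (default 4×, a study-count bias of the order seen
  for charismatic Arctic residents) at `flagship_fraction` 0.15.
* Seasonal coverage is summer-heavy: `winter_study_fraction` 0.15.
* `case_study_fraction` 0.25 of studies are anecdotal single-link reports
  (80% carry months, 20% are monthless); `excluded_review_fraction` 0.02 are
  flagged reviews.
* Metric heterogeneity is simulated by pure scale transformations (percent,
  per-mille, counts), exactly what standardization must neutralize.
* Measurement noise resamples observed shares from
  Dirichlet(true_shares × 100 / `measurement_noise`); at noise 0 every study
  observes the true diet exactly. Default 0.5 (observed shares within a few
  percentage points of truth). The noise model is this package's choice; any
  seed-deterministic resampling around the truth would serve.
* Publication years follow a Beta(3, 1.2) ramp over 1900–2025, giving the
  slow-then-accelerating accumulation typical of a century of regional
  literature.

Everything derives from one `numpy.random.default_rng(seed)`; identical
configs give byte-identical CSVs.

What the generator does **not** emulate: taxonomic correlation between
diets, spatial structure, within-study sample-size variation, metric-specific
distortion (a biomass metric reweighting an occurrence diet), or real
species identities. Passing tests therefore demonstrate the pipeline's
arithmetic and bookkeeping under the stated sampling structure, not
robustness to those real-data features.

**Parameter recovery.** A recovered link is a measured (consumer, resource,
layer) whose averaged strength, mapped to the nearest ordinal class (ties to
the lower class), equals the class of the true diet share. With zero noise
every study observes the truth, so recovery is exact (≥ 95% asserted);
recovery degrades monotonically as noise grows — checked at noise 0/2/8
averaged over 3 seeds with 18 nodes × 150 studies, sizes chosen to keep the
full suite around ten seconds.

## Numerical choices

* Rounding is half-away-from-zero via `decimal` (Python's built-in `round`
  is banker's and would send 1.25 → 1.2 instead of 1.3).
* Standardized shares sum to 100 within 1e-9 (float error only); a share is
  clipped at 100 before binning to guard accumulated float excess.
* The brute-force test reference recomputes every link with exact `Fraction`
  arithmetic, so implementation/reference agreement is asserted with no
  tolerance.
* CSV and GraphML exports serialize strengths as one-decimal strings, making
  export→import round-trips bit-exact.
* Self-loops (cannibalism) are rejected by default and admitted via
  `allow_self_loops`.

## Known limitations

* The season convention for April/October-spanning and tied studies, the
  season-agnostic case floor, the victim-as-resource kleptoparasitism
  convention and the `min_links = 3` default are all documented choices on
  questions the underlying procedure leaves open; alternatives are
  config-reachable where a parameter exists.
* Averaging is over studies, not study-years within a study; a long-running
  study counts once.
* No co-occurrence filtering: the product is a metaweb (potential links),
  not a realized network.
* No conversion between metric types — incommensurable groups are errors by
  design.
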