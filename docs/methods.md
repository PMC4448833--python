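# Methods

## Data model and filters

A sighting is a date, a time (minute resolution), a behavioural state
(`socialize`, `travel`, `forage`, `other` — unknown labels are coerced to
`other` with a warning), a set of photo-identified members, and a count of
unidentified animals.  Group size is members + unidentified.  Tables are
kept sorted by (date, time); the sort is stable so equal timestamps keep
input order, which makes every downstream computation order-deterministic.

Two filters run in a fixed order — calves first, then resights — because a
record retained only because a calf padded its membership must not survive
the resight screen:

* **Calf filter**: dependent calves mirror their mothers and would inflate
  mother-associated dyads; they are removed from memberships and records
  left empty are dropped.  Every member must be present in the registry
  (fail loudly rather than guess life stage).
* **Resight filter**: scanning in time order, a record is excluded if any
  member was seen less than 60 minutes earlier the same day, or if all of
  its members were already seen that day.  Exclusions are judged against
  *retained* records only; otherwise exclusion chains would cascade
  through a survey day.  The rule is restricted to a calendar day (no
  midnight carry-over) and the operation is idempotent.

## Association networks

For each unordered pair, X, Y_a, Y_b are tallied over the records of one
activity (or all records).  HWI = X / (X + (Y_a + Y_b)/2).  Networks are
simple, undirected, weighted; pairs with X = 0 carry no edge.  Pruning
removes individuals sighted fewer than `min_sightings` times *within the
activity's records* (an individual seen five times overall but once while
foraging is pruned from the forage network); the default thresholds are 3
for activity networks and 1 for the overall network, exposed per network.
Pruning does not edit sighting membership: counts for retained pairs still
include sightings containing pruned individuals.  Weights are stored at
full precision; reports round to 3 decimals.

`threshold_scan` reports vertex/edge counts and the permutation-test CV
p-value across candidate thresholds, supporting the conventional choice of
the lowest threshold that still shows significant non-random association;
the choice itself is left to the analyst.

## Metrics

Average degree 2E/V; average strength (mean summed incident weight,
2·Σw/V); average edge weight Σw/E; number of connected components
(isolated vertices count); average clustering on the *unweighted*
topology, the definition being purely combinatorial, with degree-< 2
vertices contributing 0 (so the average stays well defined on sparse
forage-like networks; this convention is noted rather than configurable in
v1).  `average_strength = average_degree × average_edge_weight` is an
algebraic identity and is used as a cross-check in the tests.  Group-size
statistics use sample SD and include unidentified animals.

## Data-stream permutation test

The sightings of one activity form a binary group-by-individual incidence
matrix A.  The null hypothesis is that individuals associate randomly
given each group's size (row sums) and each individual's sighting
frequency (column sums).  The chain move is a checkerboard swap: draw two
occupied cells (g, i), (h, j) uniformly; if g ≠ h, i ≠ j, A[g, j] = A[h,
i] = 0, flip the 2×2 submatrix, otherwise stay put.  Counting rejected
proposals as steps keeps the stationary distribution uniform over the
margin-fixed ensemble (a retry-until-success rule would not).  A hard
error is raised when no swap exists at all (all column supports nested).

Because margins are fixed, the HWI denominator of a dyad, (n_i + n_j)/2,
is constant along the chain; only the co-occurrence counts X change, and a
swap touches only two rows/columns of X, so each step is O(N) with the
running HWI mean/SD/CV maintained incrementally (float accumulators are
re-synced from scratch, and margins re-verified, every 1000 recorded
samples).  Statistics are computed over **all** dyads among individuals
retained at the pruning threshold, zeros included — nonzero-only means
would be far higher and would not match how association distributions are
summarized in this literature.

**Chain layout.**  The classical layout (burn-in from the observed matrix,
then record) is only asymptotically valid; at short chain lengths it
underestimates the null spread and measurably inflates the rejection rate
(~10% at nominal 5% with 2000 recorded samples at this data scale).  The
default is therefore the Besag–Clifford *serial* scheme: draw U uniform on
{0..n}, run U recorded steps from the observed matrix, reset to the
observed matrix, and run the remaining n − U.  Under the null the observed
statistic is exchangeable with the n sampled ones, so the rank p-value
(#{samples at or beyond observed} + 1)/(n + 1) is exactly valid at any
chain length; measured type-I over 200 null datasets at 2000 permutations
is 7%.  The cumulative layout remains available
(`scheme="cumulative"`, burn-in default 1000 attempted swaps).

Both one-sided tails are reported for mean, SD and CV (ties counted in
both, so p_low + p_high ≥ 1); the package never hard-codes which tail
constitutes "significance".  Preferred/avoided companionship appears as a
small upper-tail CV/SD p-value, usually accompanied by a small lower-tail
mean p-value.  Default significance level 0.05, configurable.

## Edge-rearrangement randomization

Random networks are generated from the observed one by `swaps_per_edge ×
E` double-edge swaps (degree-preserving rewiring; an existing-edge
proposal is retried) followed by random reassignment of the observed
weight multiset to the rewired edges.  Two-tailed p = 2·min(#{null ≥
obs}+1, #{null ≤ obs}+1)/(n_random+1), capped at 1.  This null conserves
the degree sequence and the weight multiset, hence it *fixes* average
degree, average edge weight and therefore average strength (2Σw/V); such
metrics yield degenerate null distributions and are flagged
`degenerate` with no p-value instead of producing a meaningless 1.0 —
clustering, component counts and community structure are the quantities
this null can actually test.  Degeneracy is detected with a 1e-9 relative
tolerance because weight reshuffling perturbs conserved sums at the last
ulp.  Default significance level 0.003, configurable.

## Communities and overlap

WalkTrap (random-walk agglomeration, walk length default 4 — the
algorithm authors' default — with HWI weights as transition propensities)
is run via igraph on the non-isolated part of the network; the dendrogram
is cut at maximum modularity, isolated vertices are appended as singleton
blocks, and the reported modularity is for the full weighted graph.  The
result is deterministic for a fixed network and walk length.

Variation of information is computed from the block contingency table;
VI ≥ 0 with equality iff the partitions coincide, VI ≤ log(n), and the
triangle inequality holds (all property-tested).  Networks for different
activities have different vertex sets, so two comparisons are offered:
`intersection` (restrict both partitions to shared vertices) and
`union_singletons` (default: pad each partition with singletons for
vertices absent from its network, treating transients as maximally
separate).  Default log base 2 (bits): cross-network distances among
~150 individuals then live naturally on a 0–log2(147) ≈ 7.2-bit scale.
Smaller VI = larger overlap in all reporting.

## Synthetic survey generator

Defaults emulate the study conditions: 150 adults + 10 dependent calves,
8 latent communities (uniform assignment), 124 days at Poisson(2.44)
sightings/day (~300 sightings), activity mix 0.14/0.29/0.57
socialize/travel/forage, zero-truncated Poisson group sizes with means
8.4/4.1/3.0 (a zero-truncated negative-binomial option exists for
overdispersion), and within-community preference odds of 1000/1000/1
— "high" preference is operationalized as community-pure grouping
(< 1% of companion draws are outsiders), and forage at 1 encodes the
absence of preferential foraging associations.  Groups are assembled by
drawing a focal individual uniformly and companions by weighted sampling
without replacement; the underlying count parameters are calibrated so
the *truncated* distributions hit the configured means exactly.

Detection: members are identified independently; failures count as
unidentified, and a group with no identified member is never recorded.
Because this truncation inflates the observed identified proportion,
`detection_prob` (default 0.8) is defined on the observable scale — the
expected per-group identified proportion — and the internal per-member
rate is calibrated against the group-size mixture to hit it (calves are
ignored in that calibration; the residual bias is ~0.02).

Timestamps are spaced > 60 minutes within a day, so the resight filter
only removes occasional same-composition repeats.  Everything is
deterministic given the config seed (separate seed streams for population
and sightings).

What the generator does *not* emulate: spatial structure and home ranges,
demographic turnover, day-level availability correlations, and — by
default — heterogeneous individual sightability.  The last is available
as an option (`sightability_shape`), but it is a genuine departure from
the permutation test's conditional-uniform null and inflates its
rejection rate even without planted preference; with it off, per-individual
sighting counts are Binomial-like rather than long-tailed.  Passing tests
therefore demonstrate correctness under exchangeable group filling, not
robustness to gregariousness heterogeneity (for which generalized
affiliation indices are the standard remedy, out of scope here).

Under independent detection, the jointly-quoted field summaries
(~300 sightings, group-size means ~3–8.4, identified proportion 0.8, and
~4.3 mean sightings per individual over ~150 individuals) are mutually
inconsistent; the generator prioritizes the structural parameters, making
the per-individual mean emergent (~6.5–7).

## Pipeline and reproducibility

`run_pipeline` executes read → filter → per-network build/metrics/
permutation/randomization/communities → overlap matrix → pairwise
Mann–Whitney tests, writing every intermediate plus a consolidated JSON
report.  Per-stage seeds are derived deterministically from the top-level
seed and recorded in the report; a rerun with the same config is
byte-identical.  Library defaults match the study-scale analysis
(200 000 permutations, 10 000 random networks); `scripts/acceptance.py`
uses 20 000 permutations per network, 1000 random networks, 200 null
datasets × 2000 permutations for type-I calibration and 20 datasets for
the power study — sizes chosen so the whole script completes in about a
minute while keeping Monte-Carlo error well below the effects measured.

## Known limitations

* Mann–Whitney U uses the exact distribution only for small tie-free
  samples (min n ≤ 8); group sizes are small integers, so real comparisons
  are effectively always tie-corrected normal approximations.
* The permutation test is unrestricted (no day- or period-stratified
  swaps) and carries no gregariousness correction.
* WalkTrap + max-modularity inherits modularity's resolution limit: very
  small planted communities sampled shallowly can be merged.
* The edge-rearrangement null cannot test degree-, strength- or
  mean-weight-type metrics (conserved by construction); conclusions about
  those require a different null than the one implemented here.
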