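# Methods

## Data model

An `EventTable` holds an events×units binary matrix plus per-event
metadata: an event identifier (unique), an optional condition label, an
optional individual identifier (for clustered resampling), and arbitrary
stratification variables. Unit labels are canonicalised by uppercasing,
stripping non-alphanumerics, and prefixing `AU` when the remainder is
purely numeric (`au12`, `AU 12` and `12` all become `AU12`; non-numeric
labels such as syllable names pass through unchanged, keeping the
containers usable for other communication systems).

Events with zero active units are **kept**: they carry information in
every probability denominator. Rare-unit filtering defaults to
`min_count = 2` (units that do not occur more than once are removed), and
units can also be dropped by name — e.g. units whose code conflates
different muscle movements; both removals are returned in a report and the
operation is idempotent.

## Probabilities

All quantities are plain counting ratios over events, held as exact
integer counts; probabilities are formed on demand and rounded (2
decimals) only in reports.

* unconditional: `P(A) = #events containing every unit of A / #events`;
* conditional: `P(B|A) = #events with A and B / #events with A`; pairs
  whose conditioning unit never occurs are omitted (not NaN);
* specificity: `P(C|A) = #occurrences of A in condition C / #occurrences
  of A`, which sums to 1 over conditions; its complement view is the
  occurrence probability `P(A|C)`.

Combination enumeration is capped at `max_order` (default 2) and, by
default, restricted to combinations observed at least once: full subset
enumeration grows as 2^k (with 27 AUs, billions of combinations) and the
analyses this package serves work at the unit and dyad level. Single
units are always all reported, including never-active ones.

## Null models and tests

**Within-event permutation** (`permutation_event_counts`) redraws which
units are active in each event as a uniform random subset of the same
size. Row sums are conserved exactly; column totals are free. This is
the null for *single units*: does a unit appear more often than a face
activating units indiscriminately would produce? The expected single-unit
null probability has closed form (mean event size / number of units),
which the implementation reproduces exactly in tests.

**Fixed-margins permutation** (`permutation_fixed_margins`) conserves
both row and column sums exactly, via checkerboard-swap MCMC: repeatedly
pick two 1-cells at random and, when they form a 2×2 pattern
`[[1,0],[0,1]]`, exchange it for `[[0,1],[1,0]]`. Burn-in and the gap
between successive samples are 5× the number of 1-cells (a standard
heuristic; each attempted swap touches two cells, so 5× fill gives every
1-cell several expected opportunities to move). The matrix is stored as
per-row bitmasks, making a swap attempt O(1). Exact conservation was
chosen over conservation in expectation because it makes the dyad test
conditional on unit frequencies: a significant dyad co-occurs more often
than its members' frequencies can explain. On small matrices the chain
provably reaches every margin-equivalent matrix (tested against
exhaustive enumeration).

**Bootstrap** (between-condition questions): events of the comparison
("null") condition are drawn with replacement; the resample size defaults
to the size of the *test* condition so observed and null probabilities
share granularity. With clustering, whole clusters (individuals, videos)
are drawn with replacement and contribute all their events, the final
cluster truncated in drawn order to hit the target size exactly
(truncation distorts marginals less than rejecting the overshooting
cluster). With stratification, per-level counts follow target
proportions via largest-remainder rounding (ties broken by level order);
targets default to the test condition's composition, so differences in
sampling effort across, say, sexes cannot masquerade as condition
effects.

**Reduction**: for each element, `p_increase = #{null ≥ observed}/iters`,
`p_decrease = #{null ≤ observed}/iters` (ties counted as extreme on both
sides, so the two sum to ≥ 1 and p-values are multiples of
1/iterations and never 0 when the observed value is attainable under the
null); effect size = observed − null mean. Both directions are reported
because "more extreme" is otherwise ambiguous; no multiple-testing
correction is applied — p-values are raw and should be interpreted
accordingly. Elements never observed are not tested. Default 1000
iterations (p-value resolution 0.001); a warning is raised below 100.

**Reproducibility**: one master integer seed; iteration *i* uses an
independent RNG substream keyed by the counter *i* (`SeedSequence
spawn_key`), so results are bit-identical across runs and independent of
evaluation order.

### Calibration — a known limitation

The single-condition permutation tests are well calibrated: under
independence the dyad test rejects at or slightly below nominal α
(discreteness makes it mildly conservative; empirically ≈ 0.02–0.04 at
α = 0.05 on 50-event tables).

The between-condition bootstrap test is **anti-conservative under a true
null**. The null distribution reflects only the resampling variance of
the null condition's events, while the observed probability carries its
own, unaccounted sampling variance; with equal sample sizes the observed
− null-mean difference has roughly √2 the spread the bootstrap
quantiles assume, giving a one-sided type-I error near
Φ(−1.645/√2) ≈ 0.12 at α = 0.05 (and ≈ 0.03 at α = 0.01). The
acceptance script measures this honestly
(`bootstrap_type1_rate_alpha_05`), and the corresponding calibration
test in the suite documents the discrepancy. In practice this means
between-condition p-values rank elements well and have high power for
real enrichment, but their nominal levels are optimistic; the stringent
default α = 0.01 partly compensates. Sparser or noisier null data widen
the null distribution, pushing the test toward false negatives instead —
the small-sample behaviour users should expect for rare elements.

## Networks

Graphs are `networkx` objects. Four builders:

* **bipartite** unit–condition graphs: edge (u, c) iff u occurred
  significantly more in c than the all-other-conditions bootstrap
  predicts (α = 0.01 default, i.e. observed above 990 of 1000 bootstrap
  values); weight `P(u|c)` (occurrence mode) or `P(c|u)` (specificity
  mode); edges never run within a node class;
* **conditional** directed graphs: edge A→B with weight `P(B|A)` iff the
  probability strictly exceeds 0.3 and the pair co-occurs ≥ 3 times
  (defaults chosen to suppress edges driven by one or two shared
  events);
* **significance** graphs per condition: undirected, unweighted; an edge
  is a dyad with `p_increase ≤ α`; nodes are the units observed in the
  condition, with a `significant` flag for single units;
* **co-occurrence** graphs: weight = joint probability, the blind
  system-level view used for community detection.

Metrics: density = edges / (n(n−1)/2); transitivity = global clustering
coefficient (3 × triangles / connected triples), reported as 0 with an
explicit `transitivity_defined=False` flag when the graph has no
connected triple; degree = edge count; strength = **mean** edge weight
per node. Directed graphs are symmetrized before density/transitivity.

Community detection is greedy agglomerative modularity maximisation
(fast-greedy style): starting from singletons, repeatedly merge the
connected community pair with the largest modularity gain, and return
the dendrogram cut with maximal Newman–Girvan modularity
`Q = Σ_c (e_cc − a_c²)`. Ties in gain are broken by the
lexicographically smallest pair of community representatives, making
results fully deterministic (library implementations do not guarantee a
tie order, which is why the algorithm is authored here; `networkx` and
`python-igraph` serve as independent cross-checks in the test suite).
Isolated nodes stay singleton communities. Bipartite graphs are
clustered as plain weighted undirected graphs; no bipartite-specific
modularity variant is used.

Exports (GraphML, edge-list CSV, node-link JSON) write nodes and edges
in sorted order at full precision, so fixed inputs give byte-stable
files; GraphML/JSON round-trip node attributes, the CSV form carries
edges plus node-class columns.

## Synthetic data

The generator emulates the structure of posed facial-expression
databases: seven conditions of unequal size (45/18/59/25/69/28/83; 327
events), each defined by a core of action units at high probability,
with shared units appearing across conditions, a low baseline for
everything else, and the hard FACS exclusion between jaw-drop and
mouth-stretch units (AU26/AU27: if both are drawn, one survives,
uniformly at random — dropping both would distort marginals more).
Optional mechanisms: *coupling* sets replace their members' independent
draws with one joint Bernoulli draw (conditional probabilities within
the set become 1 before exclusivity resolution), and *individual biases*
add a per-individual, per-unit Normal(0, σ) shift on the log-odds of
activation, modelling subjects who idiosyncratically use or avoid
specific muscles.

The packaged `ck_like_spec` puts primary core units at 0.85–0.97 and
secondary units at 0.2–0.5 with baseline 0.01 — posed databases admit an
event only when it displays the stereotype, so core activation sits near
ceiling. On this spec the blind pooled analysis finds three communities
(raised-brow, lowered-brow, smile) with modularity ≈ 0.33–0.35 across
seeds.

What passing tests on this generator do **not** show: real FACS data have
temporal structure (sequences, transitions), intensity grades,
inter-coder noise, and individual repertoires far richer than a single
log-odds shift; conclusions about those features require real data.

## Problem sizes and numerics

Tests and the acceptance script use deliberately small problem sizes —
hundreds of events, ≤ 19 units, 200–1000 resampling iterations, 100–200
replicates for calibration and recovery rates — chosen so the full suite
re-runs in minutes while keeping Monte-Carlo error well inside the
asserted tolerances (binomial 95% intervals at the stated n). Exact
arithmetic is used wherever possible (integer counts, bitmask swaps);
the only floating-point comparisons are on derived ratios, tested via
exact equality where the computation is exact and `pytest.approx`
otherwise. Degenerate inputs are defined, not special-cased: empty unit
sets after filtering are valid tables, matrices without a checkerboard
return unchanged, graphs without connected triples report flagged zero
transitivity, and one-cluster partitions have modularity exactly 0.
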