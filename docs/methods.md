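# Methods

## Problem and scoring model

Given *n* scored match fragments between one query sequence *y* and one
database sequence *x*, find, for every fragment, the best-scoring *local*
chain ending in it: an ordered sequence of fragments that is strictly
colinear and pairwise disjoint on both sequences, scored as the sum of
fragment scores minus the gap costs between consecutive members. Local
means a chain is started fresh whenever no predecessor chain's score
covers the gap cost to the current fragment; on an exact tie the
connection is made, preferring the longer chain. Chains sharing the same
first fragment are treated as one family, and only the best chain of each
family is reported (a fragment interior to good chains may head no report
at all). Fragments from different queries, database sequences, or strands
are chained separately. Only two-dimensional fragments (one query, one
database sequence) are supported.

Gap costs between consecutive members, with d_x and d_y the number of
characters strictly between the matched blocks on database and query:

* linear: g1 = λ·d_x + ε·d_y. λ weighs the database distance and ε the
  query distance; the assignment of weights to axes is this package's
  convention and is symmetric under swapping.
* sum-of-pair: g_sop = λ·|d_x − d_y| + ε·min(d_x, d_y). For ε ≤ 2λ this
  closed form equals the cheapest alignment of two anonymous blocks of
  lengths d_x and d_y, where λ prices a character against a gap and ε a
  character pair; the test suite asserts that identity against an
  explicit minimization. ε > 2λ is accepted with a warning (the closed
  form then exceeds the cheapest alignment and loses that reading).

Coordinates are 0-based half-open internally and 1-based inclusive in all
text formats. Under half-open coordinates d = successor begin − predecessor
end, and abutting fragments (d = 0) are chainable with zero cost. Any
fixed ±1 offset in the distance convention shifts every connection's cost
by a constant absorbed by the choice of λ and ε; the convention is
centralized in `gap_distances` so it can be changed in one place.

## Sparse dynamic programming

The sweep processes fragment start and end events in database order. End
events are scheduled at the last covered base (end − 1) and start events
precede end events at equal coordinates; together this makes a fragment
ending exactly where another begins *active* in time (abutment chains)
while a one-base overlap is excluded — both directed tests in the suite.

At a start event the model's range-maximum structures return the best
candidate predecessor; its true value (chain score minus gap cost) is
recomputed from the retrieved fragment rather than inverted from the
transformed priority, which removes any floating-point offset drift
between octants. At an end event the fragment's chain is inserted with
its transformed priority.

Priorities are chosen so that, within the admissible region, ordering by
priority equals ordering by score minus gap cost:

* linear: priority = score + λ·end_x + ε·end_y, stored in one 'max-below'
  staircase keyed by end_y (the sweep order already guarantees the
  database-side constraint).
* sum-of-pair: the cost is piecewise linear in two octants split by the
  diagonal end_x − end_y. Octant 1 (predecessor diagonal ≤ successor
  diagonal, i.e. d_x ≥ d_y; the boundary is assigned here — both octant
  formulas agree on it): priority = score + λ·end_x + (ε−λ)·end_y, stored
  in a range tree keyed by (diagonal, end_y). Octant 2 (strictly larger
  diagonal, d_x < d_y): priority = score + (ε−λ)·end_x + λ·end_y, stored
  in a 'max-above' staircase keyed by the diagonal alone — a strictly
  larger predecessor diagonal combined with the sweep order already
  implies disjointness on the query, so no second key is needed. The
  better of the two candidates by recomputed true value wins.

Ties among equal-valued predecessors are broken arbitrarily by the
structures; reported scores are deterministic, chain membership on exact
ties is not guaranteed stable, and tests compare scores and family
structure rather than tie-broken paths.

## RMQ structures

Key universes are fixed before the sweep by rank-condensing every value
that can be inserted or queried: all begin/end query positions, and for
sum-of-pair costs all begin/end diagonals. The 1D structure is a
dominance staircase over such a universe: an entry is dropped (or later
evicted, eagerly at insert time) when another entry has a no-less-
permissive key and no-smaller priority, so stored priorities are strictly
monotone in key and a range-max is a single predecessor/successor lookup
in a bisected rank list. Any ordered dictionary over a fixed universe
satisfies this contract; the implementation uses `bisect` on a plain
list, whose expected staircase size under random priorities is
logarithmic (a smoke test bounds it loosely).

The 2D structure is a static, array-backed range tree over the diagonal
universe (padded to a power of two); each node holds a staircase over the
query-end universe for its canonical subset, so an insert touches exactly
the O(log U) nodes on its leaf-to-root path and a prefix query decomposes
top-down into at most ceil(log2 U) + 1 canonical nodes (asserted via an
instrumentation counter). No fractional cascading and no rebalancing.

Query bounds: the diagonal bound is inclusive for octant 1 and strict for
octant 2, matching the octant split; query-end bounds are inclusive
because end_y = beg_y′ is a legal abutment under half-open coordinates.
Both strict and inclusive variants exist and both are exercised against
linear-scan oracles on randomized operation sequences.

## Clustering pre-pass

Two adjacent fragments on the database may be assigned to different
clusters when the cheapest conceivable gap cost across the database gap D
between them exceeds every achievable chain score, so the split provably
cannot change any chaining outcome. With `max_score` an upper bound on
any chain score formed from fragments scanned so far and `max_y` an upper
bound on any query-side distance in the group, the cheapest bridge costs
at least λ·D (linear) or λ·(D − max_y) (sum-of-pair), giving split
thresholds floor(max_score/λ) + 1 and floor(max_score/λ) + max_y + 1
respectively; λ = 0 makes the database axis free and disables splitting.

`max_score` is realized as the running sum of fragment scores — a chain
score never exceeds the sum of its member scores, and only fragments
scanned before the split point can sit in a predecessor chain, so the
running sum is safe. When the query length is known it is tightened to
query length × the best per-position fragment score seen so far, also a
valid bound since chain members are disjoint on the query. `max_y` is the
*global* query extent of the group (max end − min begin), computed in a
linear pre-pass: a running estimate would not be safe for sum-of-pair
costs, because a fragment scanned after the split point can realize a
query distance larger than the estimate at the split and make the bridge
cheaper than estimated. The scan keeps a frontier (max database end of
the current cluster) so contained or overlapping fragments never trigger
a split. The binding requirement is the invariance property — per-cluster
chaining must reproduce whole-group output exactly — which the test suite
asserts over randomized bundled instances for both models; threshold
tightness is secondary. Clustering is on by default (`--no-cluster`
disables it).

## Synthetic data

`generate_uniform_fragments` emulates the hit density of a sensitive seed
search: length-100 fragments placed uniformly on a 1 kb query and a
100 kb virtual database, scores i.i.d. normal truncated positive. The
normal's mean/sd are not fixed by that setup; the defaults (20 ± 5) are
arbitrary and documented as such. `generate_scattered_homology` plants
one colinear chain of conserved blocks whose database- and query-side
spacings agree up to a jitter (drawn per spacer), at a random database
offset, among uniformly placed low-scoring decoys that may overlap the
planted chain (as real BLAST dumps do). Neither generator emits sequence
content, models local score correlation, repeats, or strand mixtures;
passing tests therefore demonstrate algorithmic correctness on realistic
fragment *geometry*, not end-to-end sensitivity on real genomes.

## Numerical and scale choices

Scores and costs are Python floats; tests compare at absolute tolerance
1e-9 while the sweep itself performs exact float arithmetic with no
rounding of its own. Chain scores print at four decimals; the fragment
TSV writer emits shortest-round-trip floats so read-after-write is exact.
The quadratic reference DP (`brute_force_chain`) evaluates every
chainable predecessor directly from the gap cost functions — no
priorities, no octants — and is the oracle for the sweep on instances up
to a few hundred fragments. Randomized suites use 200 instances per gap
model (n ≤ 60) for oracle equivalence, 100 bundled instances per model
for clustering invariance, and a 100 000-fragment uniform instance as the
scale check, sizes at which the whole suite runs in seconds on one core
while still exercising every code path (splits, ties, abutments, both
octants).

## Limitations

* Local chaining only; no global (end-to-end) chaining mode.
* Two-dimensional fragments only; no multi-genome chaining.
* Fragment scores enter linearly; no affine or otherwise transformed
  score weighting.
* No SAM/PSL input and no sequence-level processing — the tool consumes
  and emits match fragments and chain reports only.
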