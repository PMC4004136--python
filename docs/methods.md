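# Methods

## Graph model and conventions

Edges store information flow (followee → follower), so diffusion operations
are plain BFS over out-edges; the "follows" relation is the edge reversal.
Two follower counts coexist per account and are never conflated: the
*structural* count (out-degree within the sampled graph) and the *declared*
count (the platform-reported global total). Every audience metric documents
which one it consumes; Level-2 sums default to declared counts, because a
sampled follower graph cannot contain the followers' global audiences, with
a `structural=True` flag for the in-graph alternative.

Clustering and group cohesion are computed on the undirected projection:
both notions (triangles around a node; common versus total neighbors of a
group) are direction-agnostic. In group cohesion the members are excluded
from their own neighbor sets, so two mutual followers are not counted as
their own shared audience. The phrase "common neighbors divided by total
neighbors" admits a second reading — an average of pairwise Jaccard indices
— so the intersection-over-union of the whole group is the primary
operation and `pairwise_jaccard` is exposed separately; no claim is made
that either is the historically intended variant.

Diameter is unweighted BFS. In strict mode any mutually unreachable ordered
pair yields an explicit infinite flag rather than being dropped; non-strict
mode maximizes over finite distances only.

## Audience metrics

Dissemination potential is followers plus the sum of followers' declared
counts with **no deduplication**: the metric is defined under the assumption
that no two followers share a listener, and stays a theoretical ceiling. The
same convention applies to actual dissemination (sum of retweeters' declared
counts; the origin's own first-hop audience and the retweeter count itself
are not added — this reproduces the published per-tweet magnitudes and
fractions exactly). Exact de-duplicated variants on the structural graph
(`unique_two_hop_reach`, `unique_actual_dissemination`) are separate,
clearly named operations rather than flags, since they answer a different
question and require the second-hop accounts to be present in the sample.

Pruning semantics is `tweet_count <= t` ("at most t tweets"), with `None` as
the prune-nothing sentinel; the zero-tweeter analysis is `t = 0`. Reduction
is reported as a percentage of the original potential and flagged undefined
when that potential is zero. Printed fractions use a mixed-precision
formatter (3 significant figures, 2 below 1e-4) matching how such tables are
typically typeset.

## Diffusion simulation

The independent cascade uses one resend coin per node, not per edge — the
node-centric formulation ("each person resends with some fixed independent
probability"). Implementation detail that matters for testing: each node
holds a single uniform draw and forwards iff it falls below p. Runs sharing
a uniform table are therefore *coupled* across p — the reached set is
monotone non-decreasing in p realization by realization, and p = 1
reproduces the deterministic flood exactly (same reached set, hops and
message counts). `cascade_experiment` draws one uniform table per repetition
and reuses it across the whole p grid. Hop numbering starts at 1 for direct
followers. Redundant receptions count deliveries to reached nodes beyond
each node's first; deliveries back to the source are not counted.
Monte-Carlo checks use 3-standard-error bands with 10,000 repetitions on toy
graphs; expected reach on enumerable graphs is verified against exhaustive
enumeration over all coin outcomes.

Beyond-second-hop audiences are available only through simulation; no
closed-form third/fourth-hop metric is provided.

## Synthetic data

`make_star`, `make_random` (directed G(n, p) with p = mean_degree/(n−1)) and
`make_power_law` generate the three reference topology classes. The
power-law generator draws each node's out-degree exactly from the discrete
power law P(k) ∝ k^−α truncated to [min_degree, n−1] (inverse-CDF over the
exact pmf — continuous-approximation samplers proved visibly biased at
min_degree 1) and wires each node to that many distinct uniform targets.
Out-degrees match the drawn sequence exactly, which is what the
exponent-recovery check fits; in-degrees are approximately Poisson. The
exponent estimator is the exact discrete MLE (numerical maximization of the
Hurwitz-zeta likelihood); the closed-form continuous approximation is kept
as a documented cheap alternative.

`make_twitter_fixture` emulates the study population: K organization
accounts, follower sets of configured sizes, pairwise overlap realized by
minting a dedicated shared-follower pool per org pair (exact to rounding,
auditable, at the price of empty higher-order intersections unless
configured), declared listener counts from a per-org heavy-tailed law
(power-law scale solved so the median lands on target, via the Pareto
median xmin·2^(1/(α−1))), and tweet activity from a zero-inflated discrete
lognormal. Defaults are the study conditions: four organizations with
follower sets 7546 / 5955 / 11,768 / 213,122, zero-activity masses 6.92% /
7.22% / 8.17% / 18.43%, listener-count medians 120 / 165 / 81 / 35 (the
largest group's median is unpublished beyond a majority below 50; 35 is a
realistic sub-50 choice), pairwise overlap 0.25 (inside the observed 13–55%
band), organization tweet volumes 2788 / 2979 / 1184 / 7065. All randomness
flows through one explicitly seeded numpy generator; identical seed and
config give byte-identical edge lists.

What the generator does **not** emulate: correlation between a follower's
activity and audience size (drawn independently), reciprocal follows,
homophily, temporal dynamics, and follower-to-follower edges inside a
group's audience. Passing tests on fixtures therefore demonstrate metric
correctness and qualitative structure (heavy tails, overlap, zero mass),
not distributional fidelity to any real 2012 snapshot; quantities that
depend on that snapshot are reproduced only as printed-arithmetic checks on
exactly-shaped inputs.

## Problem sizes

Exponent recovery and the cascade sweep use n = 5000 power-law graphs; the
small-world diameter-growth check compares n = 1000 versus n = 4000 over
five seeds (exact BFS diameters via igraph in the test suite);
goodness-of-fit for the random generator uses n = 2000 at mean degree 8;
enumeration oracles use ≤ 6-node graphs (≤ 2^5 coin outcomes) against
10,000-rep Monte-Carlo means. The analysis drivers run the full-scale
default population (~227,000 accounts), which generates in a few seconds.

## I/O

Edge lists (information-flow direction, `#` comments, auto-detected header)
and account tables (CSV; thousands separators accepted on read, never
written; unknown columns preserved; rows with status disabled / private /
unrecognizable excluded and tallied into the data-cleaning report) are the
canonical formats; GraphML export exists for interoperability. All writers
sort output so identical invocations are byte-identical. Account ids are
opaque strings throughout. The `read_network` loader attaches the cleaning
tally to the returned graph (`graph.cleaning`) so the filtering step stays
auditable without changing the return type.

## Known limitations

- Group overlap targets are honored pairwise only; triple-and-higher
  intersections are empty by construction unless explicitly configured.
- Per-org listener-count medians drift slightly when overlap is high,
  because shared followers draw their attributes from the first owning
  org's law.
- The potential metric double-counts shared Level-2 audiences by design;
  use the unique-reach variants when the sample contains the second hop.
- `diameter` computes exact all-pairs BFS and is meant for small graphs;
  large-scale diameter work should go through the graph's networkx export.
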