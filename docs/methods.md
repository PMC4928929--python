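# Methods

This note records the models, conventions, and parameter choices behind
`grnevo`, and what the synthetic-data tests do and do not demonstrate.

## Network model and distances

A gene network is a set of gene symbols (uppercased, whitespace-stripped;
no alias resolution) with weighted edges that are either strictly
directed or undirected. Internally every undirected edge is stored as
two reciprocal directed arcs sharing one weight; all downstream
computation uses this arc representation only. Self-loops and
non-positive weights are rejected; duplicate arcs merge by keeping the
maximum weight (configurable to `sum` or `error`).

Distances are **unweighted hop counts** along arc directions, computed by
BFS on the full network. Edge weights in inferred GRNs are confidence
scores, not lengths, so treating them as metric lengths would conflate
evidence with proximity. A weighted mode mapping weight w to length 1/w
(Dijkstra) is available but non-default. Unreachable pairs have infinite
distance and contribute zero wherever inverse distances are averaged;
this keeps every efficiency in [0, 1] on unweighted networks.

## Evolutionary rate and age

Per-column rate = (number of distinct residues in the column) / (total
branch length of the tree, in billions of years). Gap characters
(`-.?*`) and ambiguity codes (`X B Z J`) are excluded from the distinct
count; columns with fewer than two non-gap residues are skipped. A
gene's ER is the mean over informative columns, in substitutions per
site per By. Two counting conventions exist because the literal
"number of different residues" differs by one from the conventional
minimum-substitution count: `distinct` (default; a fully conserved
column contributes 1/span, giving the observed nonzero floor of real ER
tables) and `distinct_minus_one` (conserved columns contribute 0). The
time span is always the sum of all branch lengths of the supplied tree;
no tree ships with the package.

Age is the smallest index of a clade containing an ortholog in an
ordered 13-clade presence/absence profile, 0 the oldest stratum, 12 the
youngest (human-only). Adding a presence at an older clade can only
decrease an age.

## Communities

Directed weighted modularity is
Q = (1/m) Σ_ij [W_ij − s_i^out s_j^in / m] δ(c_i, c_j), with m the total
arc weight and s the weighted out/in strengths. Q of the one-community
partition is identically 0. Optimization uses the Leiden algorithm with
the directed-modularity objective (greedy agglomerative refinement of
Louvain), seeded for determinism; the reported Q is always re-evaluated
with the package's own formula, which doubles as a cross-check against
the optimizer's internal objective. Community indices are re-assigned by
size, descending, ties broken by lexicographically smallest member gene;
the same tie-break rule applies everywhere an ordering is needed (spy
ordering, SE-curve ties), so a fixed seed reproduces every output byte
for byte.

## Randomization nulls

**Degree-preserving rewiring.** Double-edge swaps are proposed
separately within the strictly directed arc class ((a→b, c→d) →
(a→d, c→b)) and the undirected edge class (random re-pairing), with
proposals rejected if they would create a self-loop or an arc that
already exists anywhere in the graph (including the other class). Swap
*attempts* are counted, not acceptances; the default budget is 10× the
class size, which empirically decorrelates the arc set on the synthetic
networks used here. Degrees are preserved exactly by construction. The
kernel is JIT-compiled (numba) because the null batteries run hundreds of
replicates with tens of thousands of attempts each.

**Edge-difference test.** For every arc j→i with both endpoints
annotated, record value(j) − value(i); the statistic is the population SD
("width") of these differences. n_random rewired replicates give the
null widths; z = (width − mean) / SD(null, ddof=1), and the one-tailed
empirical p (narrower-than-null direction) is (r+1)/(n+1), so with
n = 20,000 and no null below the real width the p-value floor is
5.0×10⁻⁵. If all null widths are identical (e.g. a graph with no legal
swap) the z is flagged undefined rather than reported.

**Group mean test.** n_sets (default 300) random sets of the group's
size are drawn without replacement from the annotated network genes —
from the sorted value multiset, so the test depends only on values and
group size, not labels. Significance is a one-tailed normal tail in the
observed direction using the null set-means' mean and SD. The normal
approximation (rather than an empirical rank) is deliberate: set means
of dozens of genes are close to Gaussian, and it resolves p-values far
below 1/n_sets, which an empirical rank cannot. Labels hot/cold
(ER) or young/old (age) are assigned when p < α (default 10⁻³);
otherwise "average". A two-sample KS statistic against all annotated
values accompanies each test. The shuffled-community control permutes
genes across communities while preserving sizes.

## Centrality and correlations

Degree centrality = (in + out degree)/(2(n−1)) on the arc view, so an
undirected edge counts once in each direction. PageRank uses damping
0.85 (unremarkable standard choice), uniform teleport, and arc weights
as transition weights row-normalized by out-strength. Betweenness uses
directed hop-count shortest paths, normalized by (n−1)(n−2).
Correlations (Pearson + Spearman, two-sided p) are computed over the
genes shared by both inputs; constant inputs are flagged degenerate, not
silently dropped. Group-level correlation takes one point per gene set
at (mean centrality, mean ER/age); singleton groups reduce exactly to
the gene-level correlation on those genes.

## Efficiency measures

Implemented exactly as displayed in the README, on BFS distances over
the full network (paths may leave the set). The interset denominator
|I||J| − |I∩J| makes E_II = E_I an algebraic identity, which the tests
check bitwise. The cumulative SE curve sorts annotated genes ascending
by ER (coldest first) or age (oldest first), ties by symbol, and
evaluates the SE of the first k genes for k = start, start+step, …, n
(the final, all-gene window is always appended). Controls shuffle the
gene order on the unchanged network; the seed governs only these
shuffles. Window sums are grown incrementally by border blocks of the
inverse-distance matrix; the full window is summed directly so its value
is bitwise identical across orderings. The IE matrix orders groups by
mean age, oldest (lowest value) first; entry (i, j) is the efficiency
from column group j to row group i.

## Enrichment

Upper-tail hypergeometric p of the community/set overlap within the
shared universe, BH-corrected within each community's battery (mirroring
per-list reporting of annotation tools); rows pass at adjusted p below
the threshold (default 10⁻⁴), at most top-k (default 3) per community.
This is a transparent approximation: no EASE-style modified scores and
no ontology-aware propagation or fuzzy clustering.

## Synthetic data

The generator plants, in one seeded draw: (1) a stochastic block model
whose K communities sit on a core–periphery axis — within-community
probability p_in = 0.15; each community has an outreach rate
interpolating geometrically from p_out_core = 0.05 (core) to
p_out_far = 0.005 (periphery) in its peripherality c/(K−1), and a pair's
between-community probability is the geometric mean of the two outreach
rates, so core communities are denser to everything and acquire higher
PageRank; (2) half of the edges strictly directed with random
orientation, weights U(0.5, 2) as confidence stand-ins; (3) ER ~
Normal(center_c, 0.5) clipped at 0 with centers (0.5, 1, 2, 3) from core
to periphery, and age = rounded Normal(center_c, 1.5) clamped to [0, 12]
with centers (1, 4, 8, 11) — cold/old core, hot/young periphery; (4) per
community, three annotation sets of ~40% of the community's genes with a
10% leakage fraction drawn from the rest of the network, tagged
P/L/B/C in rotation. Default sizes are 4×75 genes; the SE-curve
demonstrations use 4×200 so a 500-gene window exists. `null_generate`
returns the identical network with (ER, age) pairs permuted across genes.

What passing tests show: the pipeline recovers planted community
structure (NMI ≳ 0.95), detects planted edge assortativity at |z| ≈ 30
while staying calibrated (|z| ≤ 3) on permuted annotations, labels the
planted hot community at p < 10⁻³ with type-I control at the same α,
and reproduces the core–periphery signatures (cold-core SE excess above
shuffled controls; negative group-level PageRank–age correlation).
What they do not show: real GRNs have heavy-tailed degree distributions,
hierarchical and overlapping communities, and annotation structure far
messier than nested sets; effect sizes on real data are typically much
smaller than the planted ones, and nothing here validates the biological
correctness of any specific inferred network.

## Numerical and reproducibility choices

All randomness flows from integer seeds through `numpy` generators;
derived seeds stay below 2³¹. Reruns of the pipeline with the same seed
are byte-identical (verified in tests); every output carries a header
with the seed and a hash of the analysis configuration (the output
directory is excluded from the hash). Degenerate situations are flagged
explicitly rather than coerced: constant correlation inputs, zero-variance
rewiring nulls, singleton sets for SE. `run_all` adapts the SE-curve
start window to n//4 (min 10) when fewer than 600 genes are annotated,
since the conventional 500-gene window would not exist; the module-level
default remains 500.

## Known limitations

Hop-count distances ignore edge confidence by default (a deliberate
modeling stance, switchable); the group-test normal approximation is
slightly anticonservative in the extreme tails for very small groups;
the enrichment stand-in is not a replacement for curated annotation
tools; BFS-based efficiency on very large networks (≫10⁴ nodes) would
benefit from sparser sampling of source nodes, which is not implemented.
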