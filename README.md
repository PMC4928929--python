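# grnevo

Evolutionary and topological analysis of gene regulatory networks (GRNs).

Genes do not evolve in isolation: a gene's evolutionary rate and age are
coupled to where it sits in the regulatory network. `grnevo` is a toolkit
for quantifying that coupling. It is aimed at computational biologists
who have (i) a weighted, partially directed gene network as an edge list,
(ii) per-gene evolutionary rates (ERs) and/or phylostratigraphic ages,
and (iii) optionally, functional gene sets — and who want to ask whether
slowly evolving ("cold"), old genes cluster together and occupy the
network core while rapidly evolving ("hot"), young genes sit at the
periphery.

## What it computes

**Annotation.** The ER of a gene is the mean over alignment columns of
(number of distinct residues) / (total branch length of the phylogeny in
billions of years), in substitutions per amino-acid site per By; it can
be computed from a FASTA alignment plus a Newick tree, or loaded from a
table. Age is the index (0 = oldest … 12 = youngest) of the earliest
clade, in an ordered presence/absence profile, containing an ortholog.

**Communities.** Directed, weighted modularity

```
Q = (1/m) Σ_ij [ W_ij − s_i^out s_j^in / m ] δ(c_i, c_j)
```

optimized by a seeded greedy agglomerative (Leiden) algorithm.

**Randomization nulls.** Two tests against chance:

* *edge level* — the width (SD) of the distribution of ER (or age)
  differences across edges, compared with degree-preserving rewired
  replicates (double-edge swaps, exact in/out-degree preservation), giving
  a z-score and an empirical p with the (r+1)/(n+1) estimator;
* *group level* — a group's mean ER/age against equal-size random gene
  sets, with one-tailed significance labeling groups hot/cold or
  young/old, plus a two-sample KS statistic against the background.

**Centrality.** Degree centrality, PageRank, and betweenness per gene,
with Pearson/Spearman correlations against ER and age at the gene level
and at the group level (one point per gene set at its mean centrality and
mean ER/age).

**Set and interset efficiency.** For a node set *M* and sets *I*, *J*
(distances d_ij = hop count from j to i on the full network, unreachable
pairs contributing 0):

```
E_global = (1/(n(n−1)))   Σ_{i≠j}            1/d_ij
E_M      = (1/(|M|(|M|−1))) Σ_{i,j∈M, i≠j}   1/d_ij
E_IJ     = (1/(|I||J|−|I∩J|)) Σ_{i∈I,j∈J,i≠j} 1/d_ij
```

E_M > E_global means the set is more tightly knit than the network
average; E_IJ is asymmetric on directed networks and E_II = E_I exactly.
The package also traces cumulative SE curves (SE of the k coldest/oldest
genes as k grows, against shuffled-order controls) and interset-efficiency
matrices over groups ordered oldest to youngest.

**Enrichment.** A transparent hypergeometric + Benjamini–Hochberg
over-representation test of gene sets within communities (a stand-in for
web annotation tools), with a size-preserving shuffled-community control.

**Synthetic data.** A seeded generator plants all of the above structure
(core–periphery stochastic block model, ER/age gradients, nested
annotation sets) so the entire pipeline is testable offline; a matched
null permutes annotations across genes.

## Worked example

```
$ grnevo synth --seed 7 --out demo
$ grnevo run-all --edges demo/network.tsv --er demo/gene_er.tsv \
    --age demo/gene_age.tsv --gmt demo/gene_sets.gmt --seed 1 --out demo/out
communities: 4  Q=0.4925
global efficiency: 0.3987
```

The synthetic network has 300 genes in four planted communities on a
core–periphery axis. `run-all` recovers 4 communities with directed
modularity Q = 0.49, and the network's global efficiency is 0.40 (mean
inverse hop distance over all ordered pairs). `demo/out/edge_diff.tsv`
then shows the edge-level assortativity test:

```
attribute  n_edges  width     null_mean  null_sd    z         p_upper
er         3359     0.987482  1.50612    0.0157097  -33.0141  0.00497512
age        3359     3.44715   5.45533    0.0565611  -35.5046  0.00497512
```

The ER differences across real edges (width 0.99) are far narrower than
in 200 degree-preserving rewirings (1.51 ± 0.016): interacting genes have
similar rates, z ≈ −33, with the empirical p at its floor 1/(200+1).
`table1_report.tsv` summarizes each community and its top enriched gene
sets — e.g. the largest community here is labeled `cold` (mean ER 0.67
below random sets of its size, p ≈ 8×10⁻¹⁰) and `old` (1.9 age strata
below, p ≈ 2×10⁻⁷), and its top enriched set is itself significantly
cold. `table3_report.tsv` holds the centrality–evolution correlations,
and `ie_matrix.tsv` the interset efficiencies between enriched groups,
oldest first.

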