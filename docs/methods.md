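# Methods

`xgrkit` interprets genomic summary data — gene lists, GWAS SNPs with
p-values, or genomic regions — against plain-text knowledgebases.  Two
analysis families are provided: ontology enrichment (EAG/EAS/EAR) and
gene-subnetwork identification (SAG/SAS/SAR), where the S and R variants
first convert SNPs or regions into scored candidate genes.  This note
documents the statistical models, the algorithms, the defaults and the
design decisions, and what the synthetic benchmarks do and do not show.

## Ontologies and annotation propagation

An ontology is a set of terms with gene annotations and an optional term DAG
(edges child → parent).  Before testing, annotations are propagated by the
true-path rule: a gene annotated to a term is implicitly annotated to every
ancestor, i.e. `propagated[t] = direct[t] ∪ ⋃ propagated[children(t)]`.
Propagation always restarts from the direct annotations, so it is
idempotent.  Whether enrichment servers test direct or propagated
annotations varies in practice; we propagate by default and expose
`--no-propagation` to disable it.

## Enrichment statistics

For each term a 2×2 table is formed from the input list (size `n`), the
term's propagated annotation set restricted to the universe (size `K`),
their overlap (`k`), and the gene universe (size `N`; by default every gene
with at least one propagated annotation, overridable with a custom list).
Cells are `a = k`, `b = K − k`, `c = n − k`, `d = N − K − n + k`.

* **p-value** — one-sided (enrichment-direction) Fisher's exact test, the
  upper hypergeometric tail `P(X ≥ k)`, computed via `scipy.stats.hypergeom`
  and verified in the test suite against an exact rational-arithmetic
  summation (relative error < 1e−10 over 1,000 random tables).
* **Z-score** — the overlap standardized by the exact null moments,
  `z = (k − μ)/σ` with `μ = nK/N` and
  `σ² = nK(N−K)(N−n)/(N²(N−1))`; degenerate tables (σ = 0, e.g. `K = N`)
  return 0 by convention.
* **Odds ratio and 95% CI** — the sample odds ratio `ad/(bc)` with a Woolf
  logit interval `exp(ln OR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d))`.  When any cell is
  zero, 0.5 is added to all four cells (Haldane–Anscombe) before both the OR
  and the interval are computed, so strong enrichments report finite values.
  A conditional-MLE odds ratio is deliberately out of scope.
* **FDR** — Benjamini–Hochberg step-up, computed across the tested terms by
  default.  BH is implemented directly (a few lines of numpy, cross-checked
  against `statsmodels`) because the `--fdr-scope eligible` option needs an
  explicit test count `m` covering size-eligible terms whose overlap fell
  below `min_overlap`.

Terms are eligible when their in-universe propagated size lies in
`[min_term, max_term]` (defaults 10, 2000) and are tested when
`k ≥ min_overlap` (default 3).  Results sort by
(FDR, p, −Z, term id) — fully specified so runs are reproducible.

## SNP and region linking

Coordinate conventions: SNP positions are 1-based; regions and evidence
intervals are 0-based half-open (BED semantics), a SNP occupying
`[pos−1, pos)`.  One genome build per run is assumed; no liftover.

1. **Thresholding and LD expansion (SNPs).**  Input SNPs with
   `p < 5×10⁻⁸` (flag `--p-threshold`) are kept as seeds; LD-panel proxies
   with `r² ≥ 0.8` (flag `--r2-min`) are added, inheriting the seed's
   p-value and provenance.  A proxy reachable from several seeds keeps the
   most significant one.  Proxies carry their own genomic coordinates from
   the extended panel columns so they can feed positional evidence.
2. **Proximity.**  An entity links a gene when the distance `d` to its TSS
   is strictly below the window `W` (default 50 kb), with linearly decaying
   weight `1 − d/W`.  Strict inequality avoids zero-weight boundary
   evidence.  For regions, `d = 0` when the TSS falls inside the interval.
3. **Interval maps (PCHi-C, ABC).**  Half-open interval overlap, indexed
   with an interval tree.  Raw weight is the interaction strength divided by
   the dataset-wide maximum — per-dataset normalization keeps heterogeneous
   assays comparable; several intervals hitting the same (entity, gene) keep
   the maximum.
4. **e/pQTL (SNPs only).**  A join on rsid; the dataset weight in (0, 1] is
   used as is.

**Score combination.**  Each evidence row contributes
`c = raw_weight × s`, where `s = min(−log₁₀ p_seed, 10)/10` for SNP-derived
evidence and `s = 1` for region evidence.  Contributions are summed per gene
(`--pool max` instead keeps only the strongest contribution per dataset kind
before summing across kinds), giving a raw score that is rescaled linearly
to the reported 1–10 display scale; when all raw scores tie, every gene
displays 10 (a sole linked gene is top evidence).  The scheme is additive
and monotone: adding an evidence dataset can never lower a gene's raw score.

## Subnetwork identification

Gene scores `x ≥ 0` come either from gene-level p-values,
`x = min(−log₁₀ p, 16)` (the cap guards against `p = 0` underflow), or from
linked-gene display scores.  Given a regularization level λ, every network
node gets prize `x − λ` (unscored nodes have `x = 0`, acting as potential
Steiner connectors rather than being excluded).  The solver seeks a
connected subgraph maximizing the prize sum — a node-weighted
prize-collecting Steiner tree problem — with a deterministic heuristic:

1. **Growth** (Takahashi–Matsuyama style): starting from a root, repeatedly
   attach the positive-prize seed with the cheapest path to the current
   tree, where a path costs the folded negative prizes `(−prize)₊` of the
   nodes it adds (tree nodes are free) plus a tiny ε = 1e−6 per edge that
   breaks ties towards fewer hops.  Remaining ties resolve towards
   lexicographically smaller nodes, making the construction bit-reproducible.
2. **Restarts.**  A single greedy growth cannot see route sharing — three
   seeds around one expensive hub should pay for the hub once, but per-seed
   shortest paths each prefer an individually cheaper detour.  Growth is
   therefore restarted from several roots and the best outcome kept: on
   components of ≤ 16 nodes every node serves as a root (cheap, and
   empirically exact — see below); on larger components the top 3 seeds by
   prize and the top 3 hub candidates by star gain (own prize plus adjacent
   seed prizes) are used.
3. **Exact subtree reduction.**  Each grown tree is reduced by a
   maximum-weight connected-subtree dynamic program
   (`down[v] = prize[v] + Σ_children max(0, down[c])`), which discards any
   branch that costs more than it collects.  This subsumes iterative
   negative-leaf pruning and makes the solver exactly optimal whenever the
   underlying graph is a tree (every optimal connected set has positive
   leaves, hence lies inside the seed-spanning subtree the growth produces).

Connected components are solved independently and the best tree returned.
Validated against exhaustive connected-subset enumeration on 62,753 random
graphs of ≤ 8 nodes, the solver matched the optimum on every instance; the
test suite asserts the ≥ 0.9-of-optimum bound on 500 such graphs plus
exactness on all paths and stars.

**Size control.**  The desired subnetwork size `target_n` is reached by
bisection on λ ∈ [0, max x]: larger λ lowers all prizes and shrinks the
tree.  The λ = 0 tree is evaluated first; bisection stops when the size is
within `tol` (default ⌈0.1·target_n⌉) or after `max_iter = 50` iterations,
returning the iterate closest in size, ties broken by larger objective, then
smaller λ.  For exact optimizers the Lagrangian exchange argument makes size
non-increasing in λ; for this heuristic the test suite checks monotonicity
across the bisection trace on benchmark inputs.

**Significance.**  A degree-preserving permutation test: network nodes are
binned by degree quantiles (up to 10 bins, fewer when there are fewer
distinct degrees), scores are shuffled within bins — preserving any
score–hubness relationship under the null — and the full λ-search is re-run
per permutation with the same target and tolerance.  The reported
`empirical_p = (1 + #{objective_b ≥ objective_obs})/(1 + B)` with B = 100
permutations by default (`--permutations` to change); re-running the search
inside the null, rather than freezing λ, keeps the null statistic exchangeable
with the observed one.  Under iid scores the resulting p-values are uniform
to KS-test resolution (checked at B = 99 over 200 repetitions).

## Synthetic data generator

`generate_fixtures` writes a mutually consistent toy knowledgebase and
analyser inputs, all deterministic given a seed (byte-identical files on
regeneration):

* **Genome** — one chromosome with gene TSSs on a 100 kb grid, matching
  average human gene density so the default 50 kb proximity window links a
  SNP to its own locus rather than a block of neighbours.
* **Ontology** — 50 terms of 20–200 genes drawn from a 2,000-gene pool, a
  shallow 5-root DAG, and one designated planted leaf term (≥ 40 genes).
* **Network** — 100 genes: a Barabási–Albert background (m = 2) plus a
  10-gene planted module (pairwise edge probability 0.6 over a spanning
  path) bridged into the background; edge weights uniform in [0.7, 1).
* **LD panel** — 4-proxy blocks (r² ~ U(0.5, 1), positions within ±30 kb)
  around half of the significant SNPs.
* **Evidence** — promoter-window PCHi-C (±12 kb of the TSS) and downstream
  ABC enhancer windows (+4..+9 kb) covering the signal genes plus a random
  fraction of all genes; e/pQTL rows for most signal SNPs plus random
  background rows.
* **Inputs** — a gene list of 30 planted + 30 background genes; gene-level
  p-values of 10^−U(6,8) on the module versus U(0.05, 1) elsewhere; 200
  SNPs of which only the 20 placed within ±10 kb of planted-term TSSs reach
  genome-wide significance (background p ≥ 10⁻⁶); 120 regions of which 20
  overlap the planted genes' enhancer windows.

The generator emulates the *structure* of real knowledgebases, not their
content: it has a single chromosome, uniform gene spacing, independent
uniform interaction strengths, no correlated LD structure beyond blocks, and
planted effects far stronger than typical polygenic signals.  Passing the
planted-recovery benchmarks therefore demonstrates that the pipelines
propagate a clear signal faithfully end to end — not that the method has any
particular power on real GWAS or epigenomic data.

## Benchmarks computed by the test suite and `scripts/acceptance.py`

All empirical claims above are recomputed, not asserted: Fisher vs
brute-force summation (1,000 tables, N ≤ 200); closed-form checks
(z = 3.0 and p = 1/120 for the (N, n, K, k) = (10, 3, 3, 3) table, BH on
[.01, .02, .03, .04], Haldane OR = 105 for cells (3, 0, 0, 7)); PCST vs
enumeration (500 random graphs ≤ 8 nodes; all paths/stars); planted-term
recovery (rank 1 with FDR < 0.05 in ≥ 95/100 seeds); planted-module
recovery (median Jaccard ≥ 0.6 over 50 seeds, target 10); permutation-null
KS uniformity (200 repetitions at B = 99 on a 25-node network, chosen so the
full benchmark completes in minutes on one CPU).

## Numerical and degenerate-input conventions

* σ = 0 tables → Z = 0; `k = 0` → p = 1 exactly.
* p-values of 0 in gene summaries → score capped at 16.
* Duplicate network edges keep the maximum weight; duplicate SNP rows keep
  the minimum p.
* Proximity requires strictly positive weight (`d < W`).
* Empty evidence → empty linked-gene list (not an error); no seeds after
  prize assignment → empty subnetwork with objective 0.
* All orderings (results, evidence rows, tree tie-breaks) are fully
  specified; any two runs with the same inputs and seed produce
  byte-identical output files.

## Known limitations

* The heuristic solver carries no approximation guarantee on general
  graphs; its quality is established empirically at small scale.
* LD r² values are consumed, never computed; there is no fine-mapping or
  colocalization, and distance decay is linear only.
* Gene identifiers are opaque case-sensitive symbols; no alias resolution.
* Enrichment ignores term–term dependence in the DAG when correcting for
  multiple testing (plain BH, as servers of this kind report).
* The permutation p-value is lower-bounded at 1/(B+1); small p requires
  raising `--permutations`.
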