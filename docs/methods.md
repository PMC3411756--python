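# Methods

## Model

An additive bicluster is a pair (G, Σ) of a gene subset and a condition
subset such that every member gene's profile over Σ is a shared column
profile plus a per-gene constant. Exact additivity never holds in data, so
membership is certified through a threshold ε on *relative expression*: for
a seed (g_s, s_s),

    E′_{gτ} = (E_{gτ} − E_{g_s τ}) − (E_{g s_s} − E_{g_s s_s}),

and a condition τ is coherent for gene g (w.r.t. that seed) when
|E′_{gτ}| ≤ ε, dissimilar when strictly greater. The seed gene's profile is
identically zero and every gene is zero at the seed condition, so the seed
is trivially a member and the seed condition is always included. Because
each member is within ε of the seed gene, any two members are within 2ε of
each other on every included condition — the bicluster's coherence
certificate. E′ is exactly the two-row/two-column double difference
Δ_{iji′j′} = (a_{i′j′} − a_{ij′}) − (a_{i′j} − a_{ij}) with (i, j) fixed at
the seed, the same quantity whose squares average (over all quadruples,
divided by 4·|I|²·|J|²) to the mean-squared-residue H-score; both identities
are verified by brute force in the test suite.

## Search procedure

For every seed, genes with at most D_max = n − min_coherent_condition
dissimilar conditions form a candidate table (one row per gene); rows with
identical dissimilar sets are grouped (gene-set union) and the table is
sorted ascending by dissimilar-set size, ties broken by the lexicographic
order of the sorted condition indices, then by smallest gene index. The
table is then drained as a worklist: the first row is popped; if its gene
set (plus the implicit seed gene) reaches min_gene, a bicluster is emitted
whose condition set is the complement of the row's dissimilar set. The
popped row is then combined with every surviving row — union of genes,
union of dissimilar sets — discarding unions that exceed D_max and
deduplicating by dissimilar set. Biclusters from all seeds are deduplicated
by (gene set, condition set) and ordered by size, making output
byte-identical across runs.

**Design choice — emitted rows are also combined.** An alternative reading
treats emission and combination as mutually exclusive (a row that becomes a
bicluster is simply removed). That variant loses valid results: at
min_gene = 2 every row is emitted on first touch, no combination ever
happens, and a maximal bicluster whose members have *different* dissimilar
sets (e.g. {g_s, a, b} with a dissimilar only on condition 1 and b only on
condition 2) is never formed from any seed. Combining emitted rows too
restores the method's exhaustiveness promise — every maximal coherent
(gene set, condition set) pair is contained in some output — which the test
suite checks against a brute-force oracle on small random matrices. The
exclusive variant remains available as `combine_emitted=False`. Termination
is guaranteed either way: dissimilar sets live in the finite lattice of
condition subsets of size ≤ D_max, newly created rows always have strictly
larger dissimilar sets than the row being processed (or merge into existing
ones), and gene sets only grow.

Emission uses |G| ≥ min_gene with the seed gene counted as a member
(`strict_min_gene=True` switches to a strict inequality). Aggregation by
seed gene unions the gene sets of all biclusters sharing a seed gene and
deliberately does not intersect condition sets: aggregates group co-behaving
genes, not a common coherent condition set.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| ε (`epsilon`) | 0.35 | z-score | coherence band half-width; members differ ≤ 2ε |
| τ (`tau`) | 3ε | z-score | minimum expression range to enter the analysis |
| `min_gene` | 5 | genes | minimum bicluster gene count (seed included) |
| `min_coherent_condition` | 12 | conditions | minimum retained-condition count |

Defaults suit a 17-point z-scored time course: ~68% of standard-normal
values lie in [−1, 1], so ε = 0.35 (band width 0.7) is a meaningfully tight
fraction of the data's spread. τ is computed from ε in decimal arithmetic so
printed thresholds are exact (3 × 0.15 is 0.45, not 0.4499…9). Genes whose
range does not *strictly* exceed τ are removed entirely by default; a
`--filter-seeds-only` mode keeps them as candidate members and only removes
them from the seed list. `min_coherent_condition` counts the seed condition
(which is always coherent). Normalization is per-gene z-score (population
SD, divisor N) by default, with a matrix-wide `global` mode available;
per-gene normalization is idempotent and a zero-variance profile is an
error, to be filtered by the caller.

## Significance model

Treating z-scored values as standard normal, a value falls within ε of any
given level with probability p = Φ(ε) − Φ(−ε) = 2Φ(ε) − 1. Coherence of a
random gene with a seed across conditions is a Bernoulli scheme, giving
p₁ = P[Bin(n, p) ≥ min_coherent_condition], and across m genes
p₂ = P[Bin(m, p₁) ≥ min_gene]. Both tails use the ≥ convention ("at least
the minimum") and are computed as exact binomial survival functions
(scipy), which agree with term-by-term summation to 1e−12 for n ≤ 25 (a
property test). At ε = 0.35, n = 17, m = 2884, min_coherent_condition = 12,
min_gene = 5 this gives p₂ ≈ 9.98·10⁻⁴. The model is a-priori and ignores
the multiplicity of seeds and the dependence between overlapping
biclusters; it bounds the chance of *a* bicluster of the minimum
dimensions, not a family-wise error rate.

Overlap evaluation is the exact upper-tail hypergeometric probability of
the observed intersection (drawing y₂ genes from a universe of n with y₁
marked). Correspondence curves report, per found (or seed-gene-aggregated)
cluster, the minimum p over reference clusters, cumulatively. Term
enrichment filters at raw p ≤ 0.05 by default; Benjamini–Hochberg
adjustment is available but off, keeping the per-term convention.

## Synthetic data and what it shows

The generator embeds planted blocks base_profile[τ] + gene_offsets[g] +
noise in an i.i.d. standard-normal background, emulating a z-scored matrix
with additive structure. Planted gene sets are drawn disjointly (an error
if oversubscribed); condition sets are part of the recipe and may overlap
across plants, which is safe because disjoint gene sets mean no cell is
written twice. Planted noise is uniform on [−w, w] with w = √3·noise_sd
(so its SD is noise_sd): a bounded support allows an exact recovery
statement. The seed-relative value between two planted genes on planted
conditions is a sum of four noise draws, so |E′| ≤ 4w; whenever 4w ≤ ε
(`recoverable_by_construction`), the planted block is coherent from any
internal seed and the exhaustive scan *must* contain it. The recovery
studies use noise_sd = ε/12 (4w ≈ 0.58ε), comfortably inside that
guarantee. Matrices with plants are not re-normalized in the algorithm
tests — per-gene standardization rescales rows unequally and destroys
planted additivity — while a separate CLI path exercises the full
normalize → filter → cluster pipeline.

The generator does not emulate platform noise models, missing values,
heavy-tailed expression, or correlated backgrounds; passing tests show the
search is exhaustive and correct w.r.t. its own coherence definition, not
that ε = 0.35 is appropriate for any particular real dataset.

Problem sizes in the test suite were chosen to keep the whole suite fast
while still exercising every guarantee: oracle comparisons run on 8×6 and
8×8 matrices (where exhaustive enumeration over all seeds and condition
subsets is feasible — the oracle is guarded at 10×10), and recovery runs
100 matrices of 200 genes × 17 conditions with one planted 8 × 12 block,
mirroring a time-course-sized panel at a few-second cost.

## Numerical choices and degenerate inputs

Strict inequalities follow the definitions: dissimilar means |E′| > ε,
filtered means range ≤ τ, so boundary values are coherent and filtered
respectively. The relative profile's seed-condition entry is set to exactly
0.0 (not left to floating cancellation). Rows with missing or non-numeric
cells are dropped at read time and reported, never imputed; duplicate gene
IDs are an error naming the duplicates; an empty matrix (or one emptied by
filtering) is an error at run level. An empty candidate table, an empty
bicluster list, and a pure-noise matrix at tiny ε are all valid empty
results. Condition indices are 0-based internally and reported 1-based with
their labels. An optional wall-clock budget can truncate the seed scan
(off by default); truncated runs are still deterministic up to the budget
but are not exhaustive.

## Limitations

Worst-case table growth is exponential in D_max (the dissimilar-set
lattice), though tables stay small in practice because background genes
rarely pass the D_max cutoff; the instrumentation counters
(`TableStats`) expose per-size row counts to monitor this. Only additive
(shift) patterns are found — multiplicative/scaling patterns are out of
scope, as are overlap-control post-processing beyond exact deduplication
and any greedy node-deletion δ-bicluster search (only the H-score itself is
implemented). The significance model assumes independence across genes and
conditions and standard-normal margins; real expression data violate both,
so p₂ is a calibration guide rather than an exact error rate.
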