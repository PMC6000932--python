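# Methods

## Model and definitions

The pipeline analyses unordered pairs of genes of one focal ("anchor")
genome. Adjacency is a rank property: per chromosome, genes are totally
ordered by (start, end, gene_id) — coordinates are 1-based inclusive, GFF3
convention — and *neighboring* means adjacent in that order. Strand and
intergenic distance are deliberately ignored: the quantities of interest
depend on gene order, not spacing, and rank order is robust to coordinate
rescaling.

The pair universe is the union of anchor-adjacent pairs and the
intrachromosomal interaction set. Three evidence flags are assigned:
I (membership in the interaction set), A (anchor-adjacent and orthologs
rank-adjacent in at least one comparator), E (anchor-adjacent and orthologs
both present but separated in at least one comparator). The "at least one"
(existential) reading is the default because the class "both
always-neighboring and evolutionary neighboring" is non-empty only under
it: A and E can co-occur for one pair only if different comparators witness
them. The universal alternative ("every comparator where both orthologs are
present agrees") is available as `rule="all"` for sensitivity analysis.
With many-to-many ortholog maps a pair counts as NEIGHBORING in a species
if *any* ortholog combination is adjacent (permissive rule, the simplest
well-defined one; the strict all-combinations variant is a switch).
Interaction pairs that are rank-adjacent but carry neither A nor E evidence
are labeled NONE rather than INTRA_ONLY, because the intrachromosomal-only
class is defined on pairs that are not linear neighbors; their count is
logged.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions for every planted-effect check.

**Genomes.** The anchor has `n_genes` = 2000 genes in contiguous blocks on
`n_chromosomes` = 5 chromosomes, 1 kb genes with 1 kb gaps (lengths are
cosmetic — adjacency depends only on order), total genome size
2 kb × n_genes. Each of 6 comparators is derived independently (star
phylogeny) by, in order: gene loss, inversions (reverse a random contiguous
gene-index segment), translocations (move a short segment to another
chromosome). The ortholog map is the identity on surviving genes; an
optional tandem-duplication step (off by default) inserts co-orthologs
sharing a cluster to exercise many-to-many handling.

**Clustered loss.** Genes are lost in contiguous segments: a two-state
Markov chain along each chromosome whose stationary loss probability is the
configured rate and whose deleted runs average `loss_run_mean` = 8 genes.
Segmental deletion is how annotated genes actually drop out of synteny
comparisons, and it is what gives physically neighboring genes correlated
presence across species — with independent per-gene loss, an adjacent
pair's two genes would survive independently, every pair class would have
the same conservation-count distribution as random pairs, and conservation
could not distinguish colocalized classes from background at all. The
marginal per-gene loss rate still equals the configured probability
(verified by test), and loss 1.0 still removes everything.

**Comparator tiers.** One close comparator (inversions 40, translocations
1, loss 0.085 — ten times lower than the distant tier throughout), two
moderately diverged (200 / 10 / 0.50) and three deeply diverged
(400 / 10 / 0.85). The tiers matter: a single "far" tier cannot
simultaneously leave the always-only class with a conservation signal
(which needs comparators where presence usually implies preserved
adjacency) and populate the evolutionary classes (which need comparators
where presence usually implies separation). Three tiers resolve this and
mirror real phylogenies — a congeneric relative, confamilial species, and
distant angiosperms whose detectable orthologs drop to ~15% and whose gene
order is essentially scrambled.

**Interactions.** `n_interaction_pairs` = 600 distinct same-chromosome
pairs sampled without replacement with probability ∝ (gene-index
distance)^(−decay), decay = 2.0. Power-law contact decay is the standard
Hi-C observation; the exponent makes ~1/3 of drawn pairs rank-adjacent, so
the interaction set overlaps the adjacency universe the way real contact
calls do and all seven classes receive pairs.

**Planted effects.** A disjoint set of universe pairs (no shared genes)
receives the planted signals: expression profiles drawn bivariate-normal
with ρ = 0.5 over 50 conditions, and, on H3K27me3 and X5mC only, a shared
latent level (unit s.d.) plus per-gene noise of s.d. 0.3, giving
E|Δ| = 2·0.3/√π ≈ 0.34 against a background of 2/√π ≈ 1.13 (two
independent unit normals). All
other gene × condition and gene × mark values are independent standard
normal. Because planted pairs must be gene-disjoint while adjacent pairs
chain through shared genes, at most ~n_genes/2 pairs can be planted; the
greedy selection takes interaction∩adjacent pairs first (they feed the
rarest classes) and then interleaves interaction-only and remaining
adjacent pairs 1:2, so every class keeps a workable planted share
(~25% for the large adjacency-only classes, near-total for the small
interaction classes).

**Seeds.** All randomness flows from one root seed through named
`numpy.random.SeedSequence` spawns, one per stage in fixed order; the
derived seeds are recorded in the report, so any stage can be rerun in
isolation and identical config + seed reproduces every file byte for byte.

**What the generator does not emulate.** Real expression correlation
structure (tissue blocks, shared regulons beyond pairs), quantitative
ChIP/bisulfite signal distributions, realistic Hi-C contact matrices,
gene-family expansion beyond tandem pairs, a resolved phylogeny (branches
are independent), and the pair-count density of any real interaction data
set. Passing planted-effect tests therefore shows the machinery recovers
known signal of the stated form and size — not that real genomes carry
such signal.

## Statistics

*Permutation null.* Each replicate draws the class's number of uniformly
random distinct gene pairs (distinct genes within a pair) from the anchor
gene universe and re-evaluates the statistic; random pairs may span
chromosomes. The empirical p uses the add-one estimator
(1 + exceed)/(1 + n): with n permutations the smallest attainable p is
1/(n+1), and the pipeline reports that honest bound rather than "p < ε"
claims below the resolution of the null. Replicates with undefined
statistics are dropped (run aborts if they exceed half).

*Bootstrap.* Error bars are the standard deviation of the means of
`n_boot` = 1000 (default) resamples with replacement, matching the original
sample size.

*Mann–Whitney U.* Midranks for ties; for n₁+n₂ ≤ 12 the two-sided p comes
from exact enumeration of the conditional rank distribution (valid under
ties as a permutation test); otherwise a tie-corrected normal approximation
with continuity correction. The exact-with-ties path is the reason this is
implemented in-package; scipy's implementation serves as an independent
cross-check in the tests on tie-free data. If all values are identical the
test is flagged degenerate with p = 1.

*Relative change.* Both conventions are kept because published per-class
increments demonstrably use both: NEW_BASE = 100·(a−b)/a and
OLD_BASE = 100·(a−b)/b. The bundled worked-example table records, for every
published increment, which convention reproduces it; six printed values
reproduce under neither convention from their own printed inputs and are
flagged `consistent=False` — they are reported as arithmetic
inconsistencies in the source numbers, not chased.

*Conservation.* "Found in a species" defaults to both-orthologs-present
(status ≠ ABSENT): evolutionary-neighboring pairs cannot by definition be
found *as neighbors* elsewhere, so presence is the only reading consistent
across classes; a stricter found-as-neighbors mode is a switch. Means are
over comparators only (the anchor never counts itself). The conservation
level axis is the exact integer species count, ungrouped; the close-set
share at level k pools all found-incidences of pairs found in exactly k
species. Levels with no pairs are dropped from the Spearman trend.

*Phylogenetic coefficient.* r = r₁·r₂, r₁ = 2·N_n/N_A, r₂ = T_c/T_A.
r₁ is the fraction of anchor genes participating in always-neighboring
pairs against the comparator (hence the factor 2); r₂ corrects for genome
amplification. r is homogeneous in the two genome sizes. Note r is not
bounded by 1: a comparator retaining nearly all adjacencies with a
similar-sized genome can exceed it (r₁ counts pairs against genes).

## Numerical and degenerate-input choices

Pearson correlations need ≥ 3 shared non-missing conditions and nonzero
variance in both profiles; pairs failing this (or missing from the matrix)
are excluded and counted, never treated as non-co-expressed — fractions
should not be deflated by data availability. The co-expression rule is
signed r ≥ t by default (|r| ≥ t is a flag). Correlations are clipped to
[−1, 1] against rounding. Ties in gene start positions break by (end,
gene_id); pair canonicalization is lexicographic. Empty classes are skipped
with a log entry; an empty pair universe, overlapping planted pairs,
unknown marks and infeasible rearrangement rates raise typed errors that
the CLI maps to exit codes 2 (input), 3 (config), 4 (stage failure).

## Scaling of the shipped checks

The test suite and the acceptance script run the resampling machinery at
1000 permutations and 200 bootstrap resamples and calibration sweeps at
a few thousand simulations — sizes chosen so the whole suite completes in
a few minutes on one CPU while leaving every comparison far from its
decision boundary; the pipeline defaults remain 10,000 and 1000.

## Known limitations

Statuses are computed per pair, not per synteny block: no collinearity
chains, no interchromosomal colocalization, no ortholog inference (the
ortholog table is an input), no WGD detection, no expression normalization
or multiple-testing correction. The brute-force classification oracle used
in the tests is quadratic in gene count and intended only for small
genomes. With very small universes the no-colocalization sampler may be
infeasible (it requires enough non-adjacent, non-interacting pairs) and
raises rather than silently shrinking the sample.
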