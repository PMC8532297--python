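# Methods

## Scope and data model

The package analyses sets of annotated mitochondrial genomes below the
family level. A `MitoRecord` holds one genome (A/C/G/T/N alphabet; other
ambiguity codes are rejected at parse time because silently counting them
would corrupt composition and skew statistics), its gene features in
GenBank convention (1-based, inclusive coordinates; features may wrap the
origin only on circular records) and a five-level taxonomy
(subfamily/tribe/genus/species/individual). Gene names are normalized to
the 37 canonical insect mitochondrial symbols; the duplicated leucine and
serine tRNAs are accepted only with a codon-family tag ((UUR)/(CUN)/
(AGN)/(UCN)) or an anticodon — an untagged `trnL`/`trnS` fails validation
rather than being guessed. Genomes without an assembled control region
are accepted as incomplete; "whole-genome" statistics then cover the
assembled span only.

## Composition and skews

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C), computed on the annotated
majority strand; minus-strand genes are reverse-complemented before
pooling into gene-class partitions because skew is strand-dependent.
Partition pooling concatenates gene sequences before counting; "overall"
composition is pooled counts (a per-genome mean is available as a flag on
the report). Tribe-level values are unweighted means over member samples.
N and gap symbols are excluded from all counts. Zero denominators yield
NaN sentinels, never exceptions. Percentages are reported to one decimal
in outputs; internal values keep full precision.

## Codon usage

All indices are parametrized by a `GeneticCode` loaded from Biopython's
NCBI registry (default table 5, invertebrate mitochondrial: 62 sense
codons; twelve 2-fold, six 4-fold, one 6-fold and one 8-fold family).
Stop codons and codons containing N or gaps are excluded from counts;
internal stops are counted and logged, not fatal (neutral simulations and
misannotated boundaries both produce them).

* RSCU(c) = observed(c)/(family total/family size); an unobserved family
  gives NaN for all its codons, while an unused codon of an observed
  family gives 0 — the two cases mean different things.
* ENC follows Wright: per amino acid with n ≥ 2 observed codons,
  F = (nΣp² − 1)/(n − 1); ENC = N₁ + Σₖ Nₖ/F̄ₖ over family sizes k,
  capped at the sense-codon count. When a size class has no observable
  family, its F̄ is imputed as the family-count-weighted mean of the
  observable classes, which keeps ENC defined on short genes.
* CBI = (N_opt − N_ran)/(N_tot − N_ran) over multi-codon families, with
  N_ran = Σ n_a/k_a. The "optimal" codon per family is the most frequent
  synonym in the pooled dataset under analysis (a self-referential
  reference set, recorded in the report metadata), so every sample is
  scored against one shared reference.
* GC3s is the G+C fraction at third positions of multi-codon-family
  codons. Correlations (ENC or CBI against GC3s across genomes) are
  Pearson with two-sided p.

## Divergence

* **K2P**: P and Q are transition and transversion proportions under
  pairwise deletion (sites with a gap or N in either sequence of the pair
  are dropped); d = −½ln(1−2P−Q) − ¼ln(1−2Q). Saturated pairs (either
  logarithm undefined) become NaN, are excluded from category means and
  reported as counts.
* **Rank stratification**: each unordered pair is assigned to exactly one
  of five categories by the most specific shared rank (within species;
  among species within genus; among genera within tribe; among tribes
  within subfamily; between subfamilies); category means are arithmetic
  over defined distances.
* **Nucleotide diversity** uses complete deletion (columns containing any
  gap or N are removed for all samples) — deliberately different from
  K2P's pairwise deletion, matching the conventions of the distance and
  diversity programs practitioners use; both conventions are documented
  per output. π is the mean pairwise difference proportion, profiled in
  300-site windows stepped by 25 on the gap-stripped columns and reported
  at window midpoints; the genewide value is computed directly, not as a
  window average.
* **Ka/Ks** is Nei–Gojobori (1986) with Jukes–Cantor correction.
  Potential synonymous sites per codon position count only viable single
  mutations (changes to stop codons are excluded from numerator and
  denominator), and N = 3 − S per codon so S + N always equals three
  times the codons compared. Observed differences at 2–3 positions
  average over all mutational orderings, excluding orderings through stop
  codons (if all orderings are blocked, all are kept rather than dropping
  the codon silently). p ≥ 3/4 or S = 0 gives NaN sentinels.

## Supermatrices

Genes concatenate in the canonical lepidopteran mitogenome order (cox1,
cox2, atp8, atp6, cox3, nad3, nad5, nad4, nad4l, nad6, cob, nad1, nad2;
rrnL, rrnS; tRNAs alphabetically) — the order itself is a free choice,
but fixing it makes outputs deterministic and diffable. Schemes P12,
P123, P123R, P123RT select codon positions and gene classes. Missing
samples are padded with `-` (not N, per supermatrix convention) and
listed in a coverage report. Every column carries provenance
(gene, source column, codon position), which makes the column mapping an
invertible bijection; charsets are exported in NEXUS `sets` and RAxML
dialects with `\3` stride notation.

## Distance trees

UPGMA (size-weighted average linkage, node height = cluster distance/2)
supplies the rooted ultrametric tree; on ultrametric input it reproduces
the cophenetic distances exactly. NJ (Saitou–Nei Q-criterion) is used for
topology checks; negative branch lengths are clamped to zero with a
warning. Both break merge ties by lexicographic cluster label so runs are
bit-reproducible. Trees are dendropy objects; newick I/O preserves
underscores.

The pipeline's ultrametric tree for informativeness profiling is UPGMA on
mean K2P over the P123RT supermatrix columns, depth-normalized to 1 — a
desk-scale substitute for an externally dated chronogram. A user-supplied
ultrametric newick tree is accepted everywhere a tree is consumed, so a
dated tree can be dropped in unchanged.

## Phylogenetic informativeness

Per-site rates are ML estimates under Jukes–Cantor via Felsenstein
pruning on the fixed depth-1 ultrametric tree: gaps/N are missing data
(partial vectors of ones), invariant or <2-taxon columns short-circuit to
λ = 0, and variable columns maximize the column likelihood over
[0, rate_cap]. The column likelihood can be multimodal in λ, so the
search brackets the global maximum on a 201-point coarse grid before a
bounded refinement to 1e−6; identical site patterns are solved once.
rate_cap defaults to 20 on a depth-1 tree and capped sites are counted,
keeping saturation artifacts visible. Richer models could be swapped in
behind the same interface; JC is the deliberate desk-scale choice.

Informativeness uses the quartet-internode approximation
ρ(t; λ) = 16λ²t·e^(−4λt), whose peak is at t = 1/(4λ) with value 4/e for
λ = 1 — a site is most informative at the depth matching its rate. Net PI
sums ρ over a partition's sites (additive over disjoint site sets);
per-site PI divides by length. The default time grid is 200 uniform
points on (0, 1]. Rankings at a time point sort by net PI (per-site
optionally), ties lexicographic.

One caveat worth recording: for single-change column patterns the ML
rate is dominated by the no-change term over the rest of the tree, so a
change on a *long* branch can receive a slightly *higher* λ̂ than one on
a short branch (the remaining conserved tree is smaller). Rates are
therefore most interpretable as increasing with the number of implied
changes, which is the property the tests assert.

## The simulator

HKY was chosen over GTR as the smallest model producing both composition
bias and a transition/transversion distinction that K2P-style estimators
can see; κ defaults to 4, a conventional mitochondrial-scale value.
Branch lengths are expected substitutions/site at rate multiplier 1 (Q is
scaled to unit expected rate at stationarity); each gene has a rate
multiplier, and protein-coding genes apply codon-position multipliers
(1.0, 0.4, 5.0 for positions 1/2/3 — third fastest, second slowest)
normalized to mean 1 within the gene as deterministic site classes, so
per-gene expected distances stay exactly (path length × gene rate).
Default equilibrium frequencies are A 0.405, C 0.115, G 0.078, T 0.402
(AT-rich with negative GC-skew); rRNA genes in the frozen configuration
use a more AT-rich set (A+T ≈ 85%) so the rRNA-vs-PCG composition
contrast found in real insect mitogenomes is reproducible. Everything is
driven by one `numpy` generator seeded from the config, so identical
seeds give bit-identical sets.

`paper_like_config()` freezes the study-structure conditions: a 30-tip
clock-like tree with two subfamilies (split height 0.085
substitutions/site), three tribes each, two genera per tribe, 2–3
species per genus, and one species sampled as six conspecific
individuals on 0.001 terminal branches; 13 protein genes with realistic
lepidopteran lengths and multipliers from 0.60 (nad5-like, slowest) to
1.90 (nad6-like, fastest); two rRNAs (0.55/0.50) and 22 tRNAs of 65–72 nt
at 0.30. The split heights put pairwise expectations at ~0.002 within
species, ~0.06 among congeneric species, ~0.10 among genera, ~0.12–0.14
among tribes and ~0.17 between subfamilies — the divergence scale
rank-stratified mitochondrial distances actually occupy, and shallow
enough that the fast genes do not saturate the K2P correction.

What the simulator deliberately does **not** emulate: indels (alignments
are gap-free; gap handling is tested by masking columns), selection on
codons (Ka/Ks truth comes from hand-built codon pairs instead; simulated
"CDS"s freely contain stop codons), control-region microsatellites, RNA
secondary structure, and strand-asymmetric mutation. Passing tests on
simulations therefore validate the estimators and the pipeline plumbing
under a known neutral process — not the biological claims any particular
real dataset would support.

## Problem sizes and tolerances

Tests and the acceptance script run the frozen 30-tip, ~14.9 kb
configuration (single replicates for rank means and informativeness,
20 seeded replicates for the diversity-extremes check), 50 seeded
replicates for NJ topology recovery at up to 12 taxa, and 20 random
columns for the dense-grid (step 1e−3) site-rate comparison. The 1-D
rate search tolerance is 1e−6; UPGMA cophenetic agreement is checked at
1e−9; ENC/RSCU/CBI oracle cases are exact closed forms. These sizes are
the package's own reproducibility budget: large enough that every
qualitative contrast asserted is forced by the generating parameters,
small enough to re-run casually.
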