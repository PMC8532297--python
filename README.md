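# mitocomp

Comparative mitogenomics of annotated mitochondrial genomes, built for
below-family-level studies of insects (the motivating system is leaf-roller
moths, whose mitogenomes carry the typical 37 genes: 13 protein-coding
genes, 22 tRNAs, 2 rRNAs and a control region, with ~80% A+T content).

Given GenBank records, a five-level taxonomy table and per-gene alignments,
the package computes:

* **Composition and strand asymmetry** per genome, gene class and codon
  position: AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C).
* **Codon-usage bias** under the invertebrate mitochondrial code (NCBI
  table 5): RSCU, Wright's effective number of codons
  ENC = Σₖ Nₖ/F̄ₖ (62 under uniform usage, 20 at one codon per amino
  acid), the codon bias index CBI = (N_opt−N_ran)/(N_tot−N_ran), GC3s,
  and the ENC~GC3s / CBI~GC3s correlations.
* **Divergence**: Kimura 2-parameter distances
  d = −½ln(1−2P−Q) − ¼ln(1−2Q) stratified by taxonomic rank (within
  species → between subfamilies), sliding-window nucleotide diversity π
  (300 bp window, 25 bp step), and Nei–Gojobori Ka/Ks with Jukes–Cantor
  correction.
* **Supermatrices** for the four standard partitioning schemes (P12, P123,
  P123R, P123RT) with NEXUS/RAxML charset export.
* **Distance trees**: deterministic UPGMA (ultrametric) and
  neighbor-joining.
* **Phylogenetic informativeness**: per-site Jukes–Cantor rates λ̂ by
  maximum likelihood on an ultrametric tree, profiled as
  ρ(t; λ) = 16λ²t·e^(−4λt), which peaks at t = 1/(4λ).
* **A ground-truthed simulator**: HKY evolution along a newick tree with
  per-gene and per-codon-position rate multipliers, AT-rich equilibrium
  frequencies, and a frozen 30-tip study-like configuration, so every
  stage is testable without downloading data.

## Worked example

```python
from mitocomp.synthetic_data import paper_like_config, simulate_set
from mitocomp import divergence as dv

simset = simulate_set(paper_like_config(seed=1))
matrix = dv.pairwise_matrix(simset.blocks["nad2"])
print(dv.rank_mean_distances(matrix, simset.config.taxonomy)
        [["rank_category", "mean_distance", "n_pairs"]].to_string(index=False))
```

prints

```
                rank_category  mean_distance  n_pairs
               within_species       0.002615       15
   among_species_within_genus       0.067696       19
    among_genera_within_tribe       0.103968       36
among_tribes_within_subfamily       0.138452      149
          between_subfamilies       0.166585      216
```

— the mean K2P distance of the `nad2` gene rises monotonically with
taxonomic rank, exactly the clock-like signal the simulator encodes
(conspecific individuals sit on ~0.001-substitutions/site terminal
branches; subfamilies split near 0.085).

The same data can be driven end-to-end from the shell:

```bash
mitocomp simulate --seed 1 --out scratch/sim
mitocomp run --config run.yaml       # composition ... informativeness
```

`run` writes one TSV/FASTA/NEXUS family per stage plus a `manifest.json`
keyed by input checksums; re-running with unchanged inputs skips
up-to-date stages.

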