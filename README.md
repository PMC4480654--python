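# exonedge

Tools for asking how much of a genome's dN/dS signal — and of its familiar
correlation with gene expression — is carried by the conserved *edges* of
exons, the regions flanking intron junctions where exonic splicing
enhancers (ESEs) constrain both synonymous and non-synonymous sites, and
by lineage-specific substitution polarized with an outgroup.

The package is aimed at molecular-evolution analyses of compact,
intron-rich genomes (the motivating system is an *Arabidopsis*-style
three-taxon comparison: two ingroup species plus an outgroup on the fixed
topology `((ingroup1, ingroup2), outgroup)`). Because the interesting
claims are distributional — "removing exon edges shifts dN/dS upward",
"the expression correlation weakens after edge removal" — everything is
exercised end to end on synthetic orthologue trios with known ground
truth, generated by the built-in simulator.

## What it computes

**Pairwise dN/dS (NG86 counting).** For each gene, expected synonymous
(S) and non-synonymous (N) sites per codon, pathway-averaged difference
counts (Sd, Nd), Jukes–Cantor-corrected rates
`d = -(3/4)·ln(1 - 4p/3)`, and ω = dN/dS. Genes with fewer than 150
aligned bases, saturated proportions (p ≥ 3/4), or dS = 0 are flagged
invalid, not clamped.

**Lineage-specific dN/dS.** The single internal node of the trio is
inferred per codon column by parsimony over the 61 sense codons; branch
counts average uniformly over tied ancestors. Branches with dS < 0.02,
dS > 2 or dN > 2 are filtered as unreliable.

**Neutrality index.** With divergence counts (Ds, Dn) and within-species
polymorphism counts (Ps, Pn),

    NI = ln[ (2·Ds + 1)(2·Pn + 1) / ((2·Dn + 1)(2·Ps + 1)) ]

NI > 0 is consistent with purifying selection, NI < 0 with positive
selection; the +1 pseudo-counts keep NI finite for any counts.

**Exon-edge trimming and the randomization test.** Up to 30 codons are
removed from each edge of every eligible exon (fully aligned, in frame,
length a multiple of three), and — matched gene by gene — the same number
of codons is removed uniformly at random (s = 1000 replicates). With q
the number of replicates in which the sequential estimate exceeds the
random one (or falls below it, for NI), the empirical p-value is
`p = (s - q + 1)/(s + 1)`. The same machinery tests cross-gene Spearman
correlation strengths for attenuation after edge removal.

**Covariates and statistics.** Expression level, Z-scores, expression
breadth, tissue specificity `tau = Σ(1 - x_i/x_max)/(n - 1)`; an
EST-subsampled alternative-splicing index (mean event count over 100
random samples of 10 mapped ESTs); Spearman and partial Spearman
correlations, Steiger's test for dependent correlations, a 2×2
chi-square on the proportion of genes with dN/dS > 1, and Kruskal–Wallis
distribution comparisons.

## Worked example

```python
import numpy as np
from exonedge import (SimulationConfig, simulate_dataset, estimate_pairwise,
                      estimate_lineage, TrimSpec, randomization_test,
                      neutrality_result)

ds = simulate_dataset(SimulationConfig(n_genes=50), seed=7)
g = ds.alignments[0]
snps = [s for s in ds.snps if s.gene_id == g.gene_id]

e = estimate_pairwise(g, ("ingroup1", "ingroup2"))
ni = neutrality_result(g, e, snps)
res = randomization_test(g, TrimSpec(k=10), ("dS", "omega"), s=1000,
                         rng=np.random.default_rng(7),
                         pair=("ingroup1", "ingroup2"))
```

prints (via the obvious format strings):

```
g00000: dN=0.0141 dS=0.2122 dN/dS=0.067 (Sd=43.0, Nd=10.0, 316 codons)
NI = -0.313  (Ds=43.0, Dn=10.0, Ps=8, Pn=1)
edge removal, dS: sequential=0.3300 null median=0.2143 q=1000 p=0.000999
edge removal, omega: sequential=0.0725 null median=0.0656 q=643 p=0.3576
branch ingroup1: dN/dS=0.105 (dS=0.089) [ok]
branch ingroup2: dN/dS=0.040 (dS=0.117) [ok]
branch outgroup: dN/dS=0.100 (dS=0.225) [ok]
```

Reading it: this gene is under purifying selection (ω ≈ 0.07). Removing
10 codons from each exon edge raises its dS from 0.21 to 0.33, higher
than *all* 1000 matched random removals (p ≈ 0.001) — the synonymous
conservation concentrated at exon edges. Its ω barely moves (p = 0.36),
and per-branch rates pass the dS/dN reliability filters.

The same analyses run from the shell:

```
exonedge simulate --out-dir data --seed 7 --n-genes 200
exonedge run-all --data-dir data --out-dir out --seed 7
```

which writes per-gene TSV tables (pairwise, lineage, neutrality,
trim/randomization for k ∈ {10, 20, 30}, correlation matrices) and a
`manifest.json` with the seed, thresholds, and a sha256 per table;
reruns with the same seed are byte-identical.

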