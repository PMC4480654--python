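# Methods

## The estimation problem

Exon edges — the first and last codons of each exon, flanking intron
junctions — tend to be more conserved than the rest of the coding
sequence because they harbour splicing enhancers, and that conservation
acts on synonymous as well as non-synonymous sites. Both dN/dS and
McDonald–Kreitman-style statistics assume synonymous changes are a clean
neutral yardstick, so edge conservation can bias per-gene estimates and,
through them, the correlations between evolutionary rate and gene-level
covariates such as expression. This package quantifies those effects by
(i) re-estimating rates after removing codons from exon edges, against a
matched random-removal null, and (ii) replacing composite pairwise rates
with per-branch rates polarized by an outgroup.

## Estimators

**Pairwise divergence** uses Nei–Gojobori-style counting with
equal-weight pathway averaging. Expected synonymous sites per codon are
`S = Σ_pos (synonymous single-nucleotide neighbours)/3` with mutations to
stop codons counted as non-synonymous; for a codon pair differing at d
positions, Sd/Nd average over all d! orderings of single-step paths,
excluding paths through stop codons (falling back to all paths if none
avoids a stop). Proportions pS = Sd/S and pN = Nd/N are corrected with
Jukes–Cantor, `d = -(3/4)·ln(1 - 4p/3)`. Codon columns containing any
gap or ambiguity in either species are skipped whole, keeping site and
difference bookkeeping consistent. A maximum-likelihood codon model
(YN00/codeml style) would additionally weight transitions and codon
frequencies; the counting estimator is used here because every number it
produces can be checked against exhaustive enumeration, and the
estimator sits behind a small interface (`CodonProfile`) that an
external-tool adapter could replace. This substitution is deliberate and
is the main caveat when comparing absolute rate values with
ML-based analyses; the package's claims are about within-pipeline
contrasts (trimmed vs. untrimmed, pairwise vs. lineage-specific), which
the substitution preserves.

**Lineage-specific rates** place a single internal node on the unrooted
trio `((ingroup1, ingroup2), outgroup)`. Per gap-free codon column the
most-parsimonious ancestral codons are found by exhaustive search over
the 61 sense codons (branch cost = nucleotide Hamming distance); branch
difference counts average uniformly over tied ancestors, and per-branch
site counts come from the tip codons. Branches with dS < 0.02 (too
little signal), dS > 2 or dN > 2 (saturation / non-orthology) are
flagged invalid, as are genes under 150 usable bases. Parsimony
understates multiple hits relative to ML ancestral reconstruction; at
the simulated divergences (per-branch dS ≈ 0.1–0.35) the bias is small
and symmetric across ingroup branches, which is what the branch-contrast
analyses rely on.

**Neutrality index.** `NI = log[(2Ds+1)(2Pn+1) / ((2Dn+1)(2Ps+1))]`,
natural log by default (the base only rescales; every downstream use is
sign- or rank-based). Divergence counts are the raw pathway-averaged
Sd/Nd, not JC rates — fractional counts are fine, the formula is defined
for non-negative reals. SNPs are classified independently against the
reference codon (phase is unavailable in SNP tables); edits creating or
destroying stops are unclassifiable and counted in neither class.

## Trimming and the randomization test

Eligibility mirrors the alignment requirements: an exon enters the
trimming analysis only if it is fully aligned (no gaps in any species
inside the block), in frame, and a multiple of three long. All
estimates for a gene — untrimmed, sequentially trimmed, randomly
trimmed — are computed on the same eligible-exon concatenation, so
treatment contrasts are never confounded by exon selection.

Sequential removal takes k codons from *each* edge of each eligible exon
(`both_edges`, the default); `internal_edges_only` exempts the gene's 5′
and 3′ termini since splice enhancers flank intron junctions, not gene
ends. The matched null removes exactly the same number of codons
uniformly without replacement. With q the count of replicates in the
direction of interest (sequential > random for dN, dS, ω; < for NI; ties
never count), `p = (s - q + 1)/(s + 1)`, which lies in (0, 1] and equals
1/(s+1) at its sharpest. One random-removal stream per gene is shared
across statistics within a replicate so the dN/dS and NI nulls are
paired. If more than 10% of replicates yield an invalid estimate the
result is flagged unreliable, and the p-value is computed over the valid
replicates only.

Genes whose post-trim concatenation falls below 150 bases leave the
trimmed subset entirely — the same inclusion rule as everywhere else.

The correlation-strength variant computes Spearman's rho between a
per-gene covariate and the sequentially trimmed statistic, then re-draws
one random trim per gene per replicate and counts replicates with
|rho_sequential| < |rho_random|: a small p says edge removal attenuates
the correlation more than matched random removal can explain.

## Statistical battery

Spearman correlations use average ranks with the t-approximation
p-value and pairwise-complete deletion. Partial Spearman ranks all three
variables and applies the first-order partial-correlation formula with
df = n − 3. Two dependent correlations sharing a variable are compared
on Fisher-z transformed values with Steiger's pooled-covariance form,
referred to t with df = n − 3 (the variant is named in the output).
The proportion of genes with ω > 1 before vs. after removal is compared
with a 2×2 chi-square without continuity correction, reported as
not-applicable when a margin is zero. Distribution shifts use
Kruskal–Wallis with tie correction. Raw p-values are reported
throughout; no multiplicity correction is applied by default.

## Splicing index

Alternative-splicing events are detected from EST intron chains by a
minimal two-signature rule: overlapping introns with mismatched
boundaries (counted once per interval pair), and an intron spliced by
one chain but covered exonically by another within both mapped extents
(intron retention). Chains are compared only over their shared extents —
absence of evidence outside an EST's mapping is not evidence. This
detector is deliberately simple; the part implemented exactly is the
transcript-number normalization: the per-gene index is the mean event
count over 100 uniform subsamples of 10 mapped ESTs, and genes with
fewer than 10 ESTs are excluded. The subsampling makes the index
invariant, in expectation, to how deeply a gene happens to be sampled.

## The synthetic study conditions

The simulator generates what the analysis assumes about real data, with
every latent quantity recorded:

* **Structure:** exon count geometric with mean 5; exon lengths
  lognormal with median 53 codons (σ_log = 0.6, floor 2 codons) — a
  compact, intron-rich gene architecture. No indels are simulated
  (alignment construction is upstream of this package); an optional
  gap-injection switch corrupts a stated fraction of blocks to exercise
  the eligibility flags.
* **Divergence:** attempt-and-accept per branch. Attempts ~
  Poisson(rate × 3L) with branch rates (0.12, 0.12, 0.36) attempts per
  site — pairwise ingroup dS ≈ 0.2, ingroup–outgroup ≈ 0.5, echoing a
  13-vs-43 My divergence contrast. Each attempt picks a uniform site and
  alternative base; stop-creating attempts are rejected; synonymous
  attempts are accepted with probability φ(site), non-synonymous with
  ω_g × ψ(site). This is not a rate-matrix exponential, but at these
  divergences it is an adequate and exactly countable stand-in.
* **Gene effects:** ω_g lognormal with median 0.2 (σ_log = 0.6),
  clamped only through acceptance probabilities; a Gaussian copula ties
  ω_g to a lognormal latent expression level at Spearman −0.4 (the
  rank-correlation target is hit exactly in expectation via
  r = 2·sin(πρ/6)). Tissue matrices multiply the latent level by
  per-gene tissue profiles of varying specificity plus lognormal noise.
* **Edge constraint:** within 10 codons of each exon edge, synonymous
  acceptance drops to φ_edge = 0.3. The non-synonymous edge multiplier
  is additionally coupled to the gene's expression percentile,
  ψ_g = ψ_edge × (1 − u_expr): highly expressed genes carry
  disproportionately strong protein-level constraint at their edges.
  This coupling is the model's expression→edge-constraint link; it is
  what makes edge removal raise measured ω and weaken the expression
  correlation, rather than only raising dN and dS. With symmetric,
  expression-independent multipliers the edge region has the same local
  ω as the interior and edge removal would leave ω and NI unchanged in
  expectation — a useful null that the configuration can also express
  (`expression_edge_coupling = 0`).
* **Polymorphism:** Ps ~ Poisson(θ_s L), Pn ~ Poisson(θ_n L ω_g) with
  θ_s = 0.03 and θ_n = 0.084 per codon; the ratio 2.8 matches the
  neutral non-synonymous/synonymous edit ratio of the genetic code, so
  the neutral configuration centres NI at 0. Positions are drawn
  uniformly among single-base edits of the required class (no edge
  structure in SNPs), and every record classifies consistently.
* **ESTs:** 30% of multi-exon genes carry a second isoform (alternative
  donor shifted 9 nt, or intron retention); ESTs sample the mixture
  50/50 with full-extent mapping.

What the simulator does *not* emulate: indel/alignment error, codon
usage and GC bias, rate variation along branches, coalescent sampling of
accessions, linked selection. Passing tests therefore demonstrate that
the pipeline recovers the signals it is built to detect under its own
assumptions — not that those assumptions hold in any real genome.

Randomness flows from one master seed through per-gene derived streams
(`default_rng([seed, stream, gene_index])`), so per-gene outputs are
reproducible independently of iteration order, and full reruns are
byte-identical.

## Numerical choices and problem sizes

Double precision throughout, no rounding before output (tables print 6
decimals). JC domain failures invalidate rather than clamp. Parsimony
ties break by uniform averaging, never by order. Degenerate inputs
(constant covariates, all-zero expression, identical groups) raise or
flag rather than silently producing numbers.

The shipped checks run at deliberately desk-scale sizes: 300 genes for
calibration and edge-recovery runs (100 random-removal replicates per
gene when pairing sequential against random removal, 200 when checking
p-value uniformity), 20 replicate gene sets of 300 genes for the
correlation-attenuation check, 200 genes for the lineage contrast, and
s = 1000 for single-gene demonstrations. These sizes keep each
distributional claim's Monte-Carlo error well below the effect being
demonstrated.

## Known limitations

* Counting estimators understate rates relative to ML at high
  divergence; absolute ω values are not comparable with codeml output.
* The NI divergence counts come from raw averaged differences, not
  corrected rates; at high divergence NI drifts conservative.
* The splicing-event detector is positional only — no motif or
  event-taxonomy awareness.
* Per-branch site counts use tip codons; for very asymmetric branches a
  midpoint convention would differ slightly.
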