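# Methods

`mirmediation` screens recombinant inbred (RI) panel data for miRNA-mediated
genetic effects on quantitative phenotypes. This note describes the model,
the decision procedure, the synthetic-data generator that the test suite
runs against, and the numerical and design choices that were genuinely open.

## Data model and preprocessing

The analysis operates on four strain-indexed tables: a binary genotype
matrix coded by parental origin, miRNA expression on a variance-stabilized
scale, gene expression on a log2 scale, and one or more quantitative
phenotypes. Upstream processing (read mapping, quantification,
normalization, batch correction) is out of scope; the pipeline consumes
already-normalized values.

*Informative SNPs* are those whose two parental alleles differ and whose
calls are complete; calls are recoded 0/1 by parental origin. SNPs with
bit-identical strain vectors are in complete linkage disequilibrium — no
recombination separates them in any strain — and collapse into one **strain
distribution pattern (SDP)**, the genetic marker unit of all downstream
statistics. Complementary vectors are *not* merged: in a two-parent RI panel
a complemented pattern would require a recombination between the SNPs in
every strain. An SDP whose member SNPs span several chromosomes (possible by
chance) keeps a per-chromosome span and is assigned to the majority
chromosome for locus grouping, with a logged warning.

Expression replicates are collapsed to strain means. Per phenotype, the
strain set is the intersection of all sources with a non-missing phenotype
value (no imputation); every correlation and likelihood below uses that
aligned set of n strains.

## Cohesive screening

A triplet (SDP, miRNA, gene) is *cohesive* when all three pairwise Pearson
correlations (point-biserial for the SDP) are nominally significant at
p < 1e-3 (two-sided t test on n − 2 df). A cohesive quadruple adds a
phenotype associated with each component at p < 0.05. No multiple-testing
correction is applied at this stage; stringency comes from the
network-scoring filters. The staged search (SDP–miRNA pairs, then SDP–gene,
then miRNA–gene among survivors) returns exactly the brute-force result
because cohesion is a conjunction of pairwise conditions. Both thresholds
are configuration values (`triplet_p`, `quadruple_p`). Triplet correlations
are computed on each phenotype's aligned strain subset by default (the
strains actually analysed for that phenotype); computing them once on the
full genomic intersection is a supported variant.

## Hybrid Gaussian network scoring

Candidate explanations of a quadruple are DAGs over the four nodes under two
role constraints: edges at the SDP point away from it (genotype is a causal
anchor, by Mendelian randomization), and edges at the phenotype point into
it (behaviour cannot alter expression measured in naive animals). Exactly
**96** DAGs satisfy these constraints for one SDP, one miRNA, one gene and
one phenotype. Binary nodes are never children, so each continuous node is a
linear-Gaussian regression on its parents and the SDP contributes only its
Bernoulli marginal; the log-likelihood decomposes over families.

Structures are compared with

    BIC = log L̂ − (d/2)·log n        (natural logs; higher is better)

with d the total parameter count: parents + 2 per continuous node
(intercept, slopes, ML residual variance RSS/n) and 1 per binary root. The
residual variance uses the ML convention, not RSS/(n − k), so log L̂ is the
true maximized log-likelihood. Exact BIC ties are broken toward fewer edges,
then the lexicographically smallest edge list, for reproducibility.

## Mediation decision

For each cohesive quadruple all 96 structures are scored. **Step 1**
partitions them by whether the miRNA lies on a directed SDP→…→phenotype
path; the quadruple passes when best(mediated) − best(non-mediated) > 2 (a
deliberately conservative margin) and the overall best structure is itself
mediated. **Step 2**, evaluated among mediated structures only, compares the
best structure with the gene also on a directed SDP→phenotype path against
the best with only the miRNA in the path; the gene is included under a
non-inferiority margin, difference > −1. "In the path" uses the same
path-membership definition for the gene as for the miRNA. Both thresholds
are configurable (`bic_delta_mediation`, `bic_delta_gene`).

A structural property of this test is worth stating plainly: when the truth
is the pure chain S→M→G→P, the non-mediated structure
{S→M, S→G, G→M, G→P} is a strict superset of the chain's model family with
exactly one extra parameter, so the Step-1 margin cannot exceed
(1/2)·log n ≈ 2.05 at n = 60 unless the data favour a direct miRNA→phenotype
edge. The ΔBIC > 2 rule therefore passes a gene-routed chain only in the
minority of samples where BIC prefers P | M over P | G; mediation through a
*direct* miRNA→phenotype effect (S→M→P) is detected with high power
(≈ 90% at a standardized 0.8/0.7 chain, n = 60). This conservatism is
inherent to the decision rule, not an implementation artefact.

## Locus expansion and bootstrap averaging

Passing quadruples that share a phenotype are pooled when their SDPs lie on
one chromosome within a 40 Mb window (single-linkage on SDP span midpoints,
so chains of sub-window gaps merge). Each pooled node set is re-learned as a
single network: exhaustively for ≤ 5 nodes, otherwise by greedy BIC
hill-climbing over single-edge additions, deletions and reversals (empty
start, strict improvement, deterministic tie order: additions, reversals,
deletions, then lexicographic). At a single-move local optimum the search
probes score-neutral covered-edge reversals one step ahead and accepts one
when it unlocks a strict improvement; this deterministic equivalence-class
escape resolves the classic trap where an early orientation tie freezes the
search one step from the optimum, and makes random restarts unnecessary in
practice (a restart facility would add nondeterminism for no measured
benefit).

Stability: the structure search is repeated on `n_boot` (default 500) strain
resamples drawn with replacement (strains are the exchangeable unit).
Degenerate resamples (a node with zero variance) are redrawn, at most 10
times. An edge is retained when its presence frequency exceeds 0.5
*strictly*, and its winning direction also exceeds 0.5 among the replicates
containing the edge (`direction_denominator="edge_present"`; the
unconditional variant is available). Exactly half is not enough. If retained
edges would form a cycle — possible because frequencies are marginal — edges
are admitted in decreasing presence frequency, skipping cycle-closers, with
a log message. Nodes left without retained edges are dropped from the final
network.

## Intervention prediction

On a final structure, every continuous node is refit by OLS and the network
becomes a linear structural-equation model. The predicted phenotype change
for raising a miRNA or gene from its first to third quartile
(`two_quartile`) or minimum to maximum (`four_quartile`, quantiles from the
training strains, linear-interpolation convention with a nearest-rank
option) uses do-style intervention semantics: the target is set, effects
propagate only to descendants, and nothing back-propagates to the genotype.
For a linear system this equals Δinput × Σ(paths target→…→phenotype)
∏(edge coefficients); the implementation computes both the forward
propagation and the path-product sum and verifies agreement to 1e-10 on
every call. Conditioning semantics (observing rather than setting the
target) would additionally move the target's ancestors and was rejected as
an account of an experimental manipulation.

## Synthetic data generator

The generator provides ground truth for every stage.

* **Genotypes.** RI strains are mosaics of two parental genomes: per strain
  and chromosome, parental origin follows a two-state Markov chain along SNP
  order with switch probability `flip_prob` per interval (default 0.005,
  initial state Bernoulli(0.5)). At 60 strains this leaves an inter-SNP
  interval unbroken panel-wide with probability ≈ 0.74, producing multi-SNP
  LD blocks and heavy SNP→SDP compression as in real two-parent RI panels.
  SNP counts are apportioned to chromosomes by length; positions are uniform.
* **Quadruples.** Five wiring scenarios: `full_mediation` (S→M→G→P),
  `mediation_no_gene` (S→M→P, gene independent), `direct_only` (S→P only),
  `null` (no edges), `reverse_gene_to_mirna` (S→G→M→P). Effect sizes are
  *standardized* path coefficients (defaults 0.8 / 0.9 / −0.7 for the
  mediation chain, the range where pairwise associations clear the screening
  thresholds reliably at n ≈ 60); raw coefficients and residual SDs are
  derived so every continuous node has unit marginal variance. Expression is
  emitted at replicate level (3 replicates, within-strain SD 0.3 — about 9%
  of signal variance after averaging, a realistic sequencing-replicate
  scale); the phenotype is generated from strain-level values.
* **Panels.** Background features are independent standard Gaussians;
  embedded quadruples are wired onto randomly chosen SDP loci whose minor
  allele is carried by ≥ 25% of strains (an uninformative anchor cannot
  carry signal). One integer seed drives everything through numpy
  `SeedSequence` spawning; outputs are byte-identical across runs.

What the generator does *not* emulate: realistic recombination maps,
epistasis, count-level (negative-binomial) expression noise, batch effects,
non-Gaussian phenotypes, and LD between background features and embedded
loci beyond what the Markov genotypes induce. Passing tests therefore show
that the procedure behaves as designed under its own model class, not that
it is robust to violations of it.

## Numerical and degenerate-input choices

Zero-variance vectors are rejected in correlation and likelihood fits
(degenerate marker / flat expression). During structure search, families
with collinear parents or zero residual variance score −∞ and are simply
avoided; the public single-structure scorer raises instead. Sample
correlations within 1e-12 of ±1 report p = 0. The hill-climb accepts only
improvements > 0 (escape pairs > 1e-9), so it terminates on the finite
structure space.

## Problem sizes used by the shipped checks

The operating-characteristic suite uses n = 60 strains, 200-seed Monte Carlo
for decision rates, 500 bootstrap replicates for the strong-chain stability
run (100 for the 20-run null batch), and 50-seed end-to-end panels with 60
miRNAs, 60 genes and 200 SNPs; the consistency checks for prediction use
n = 5000. These sizes make every rate estimate's Monte-Carlo error small
relative to the asserted margins.
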