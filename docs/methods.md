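# Methods

This note documents the models, algorithms and design choices behind
`orthoclock`, and what its synthetic-data tests do and do not demonstrate.

## Scope

The package re-implements, as one tested pipeline, the desk-scale core of a
comparative transcriptomics study: translate assembled nucleotide contigs
into protein products, detect one-to-one orthologs against a reference
proteome by reciprocal best hits, concatenate per-family alignments into an
ungapped supermatrix, infer trees and substitution models, test each gene
for a rate shift on a focal lineage under a molecular clock, and profile
GO annotations with hypergeometric enrichment. Upstream steps that depend
on sequencing hardware or live databases (read assembly, BLAST against nr,
GO mapping itself, multiple sequence alignment) are input boundaries:
contigs, proteomes, aligned families, ontologies and annotation tables are
consumed, never computed.

## ORF selection

Contigs are translated in all six frames under the standard genetic code;
codons containing `N` translate to `X`, and `X` never acts as a start or
stop. Two candidate sets compete per contig: complete ORFs (in-frame ATG to
the next in-frame stop) and 5'-truncated fragments (the prefix of a frame up
to its first stop, eligible only if no in-frame ATG precedes that stop). The
longest complete ORF wins unless the longest fragment is strictly longer —
the fragment rule recovers transcripts whose start codon was lost upstream
of the contig. Contigs under 10 nt yield no product. Ties break
deterministically: complete over fragment, forward strand over reverse,
lower frame, smaller forward-strand start. The stop codon is included in the
reported nucleotide span but excluded from the protein.

## Orthology

Similarity is the exact Smith–Waterman local-alignment score under BLOSUM62
with affine gaps costing 11 + k for a gap of length k (protein-BLAST default
penalties), computed by Biopython's `PairwiseAligner`. Raw score replaces
the E-value as the ranking statistic: it is deterministic, needs no database
size, and exact alignment dominates heuristic seeding in accuracy at this
scale. A hit below `min_score` (default 40) is discarded; this cutoff plays
the role of BLAST's significance filter and its default was chosen as a
score that random ~100-residue protein pairs essentially never reach. Ties
break toward the lexicographically smaller subject id. A pair survives iff
each gene is the other's best hit, and a reference gene founds an ortholog
group only when it has a reciprocal partner in every species.

## Supermatrix

Family alignments are concatenated in a fixed species order with per-family
column spans recorded (1-based, inclusive). Filtering removes every column
containing `-` in any species — the strictest no-gaps behavior of block
filters — because the downstream substitution models have no insertion or
deletion process. `X` survives filtering and is treated as missing data by
the likelihood machinery. The retained fraction is reported as a percentage
rounded half away from zero to one decimal.

## Substitution models and likelihood

Five empirical amino-acid exchangeability sets ship as plain-text files in
the PAML `.dat` layout: WAG, JTT, LG, Dayhoff and Blosum62. The rate matrix
is Q[i,j] = s[i,j]·π[j], rescaled to one expected substitution per site at
stationarity; reversibility gives an exact symmetric eigendecomposition, so
P(t) = exp(Qt) is computed exactly and Q satisfies detailed balance by
construction. Rate variation across sites uses a proportion of invariant
sites (+I), a 4-category discrete gamma (+G) whose category rates are the
conditional means of equal-probability slices (preserving the unit mean
exactly), or both, with the +I+G mixture renormalized to mean rate 1.
`+F` replaces model frequencies with observed ones (19 extra free
parameters).

Log-likelihoods use Felsenstein pruning with site-pattern compression,
per-node rescaling to avoid underflow, and all-ones partials for `X`. The
implementation is checked against exhaustive summation over ancestral state
assignments on every tree shape with ≤4 taxa and ≤3 sites.

## Distances, NJ, branch lengths, model choice

The neighbor-joining stage uses Poisson-corrected distances
d = −ln(1 − p), with p the mismatch fraction over unambiguous sites and
clamped at 0.95 so saturated pairs stay finite (d ≤ −ln 0.05 ≈ 3.0). NJ
itself is scikit-bio's Saitou–Nei implementation with negative branch
estimates clamped to zero afterwards. Branch lengths on a fixed topology are
optimized coordinate-wise by bounded Brent search on [0, 20] expected
substitutions per site, cycling until a full round improves lnL by less than
1e-6. Model selection ranks candidates by AIC = −2 lnL + 2k, where k counts
branch lengths plus model free parameters; alpha and p_inv are profiled by
alternating 1-D optimization with branch-length rounds. AIC was chosen as
the ranking criterion; AICc/BIC would need only a different penalty.

## Bayesian MCMC

A single Metropolis–Hastings chain samples unrooted topologies (uniform
prior), branch lengths (Exponential prior, mean 0.1 substitutions/site),
and, when present, the gamma shape (Uniform(0, 200)) and invariant
proportion (Uniform(0, 1)). Moves: NNI on a random internal edge (applied
in place and undone on rejection), a branch-length multiplier with the
standard Hastings correction, and reflected sliding windows for alpha and
p_inv. Samples are taken every `sample_freq` generations; a burn-in
fraction (default 0.25) of samples is discarded. Clade posteriors are split
frequencies among retained samples; the consensus is the majority-rule set
of splits (frequency > 0.5). With zero-length data the chain reproduces the
uniform topology prior (the three 4-taxon topologies each at 1/3 ± 0.05
over 100k generations), and on strong-signal simulations it concentrates on
the true tree. This sampler is deliberately modest — no Metropolis
coupling, no parallel chains — and is validated by these properties, not by
numerical agreement with any particular external program.

## Clock rate tests

Each family is fit twice on the fixed rooted species topology. Ages are
parameterized top-down: the root age is 1, every other internal node's age
is a logit-transformed fraction of its parent's, leaves are at age 0 — this
enforces ultrametry with no explicit constraints. A free scale converts age
durations into expected substitutions per site. The local model multiplies
the focal species' terminal branch by a free rate r. Free parameters are
(n_internal − 1) ages + 1 scale globally, plus r locally, hence 10 vs 11 on
an 11-taxon rooted binary tree and df = 1 always. Optimization is L-BFGS-B
with numerical gradients; the local fit warm-starts at the global optimum
with r = 1, so lnL_L ≥ lnL_G by construction and the clamp on
D = −2(lnL_G − lnL_L) only absorbs round-off. Raw p-values come from the
chi-squared df = 1 upper tail; family-wise significance uses the Bonferroni
threshold alpha/m. Significant families are classified accelerated (r̂ > 1)
or decreased (r̂ < 1). Only the focal terminal branch carries the local
rate; extending the local clock to the focal stem would keep df = 1 but is
not implemented.

Under strict-clock simulations (5 taxa, 500 sites) the empirical null D is
indistinguishable from chi-squared df = 1 by a Kolmogorov–Smirnov test at
200 replicates, and the raw type-I rate at 0.05 stays near nominal. Power
at a 4× focal rate with 2000-site families is essentially complete; at a
few hundred sites, power depends strongly on the length of the focal
terminal branch in the sampled tree.

## GO analysis

The OBO parser (obonet-backed) keeps id, name, namespace, `is_a`, `alt_id`
and drops obsolete terms; cycles raise an error. A term's level is 1 plus
the length of its shortest `is_a` path to its namespace root (roots are
level 1); shortest-path was chosen over longest-path because it matches
level-plot conventions, and the choice only relabels levels, not topology.
Annotations propagate upward through `is_a` only. Level distributions use
namespace-specific denominators (genes with at least one propagated term in
that namespace). Enrichment and diminishment of each background-annotated
term are two one-sided hypergeometric tail tests (P(X ≥ k) and P(X ≤ k));
all (term, direction) p-values are adjusted jointly by Benjamini–Yekutieli,
which controls FDR under the arbitrary positive dependence that propagated
term counts exhibit. When study and background universes differ, k is
capped at K; the hypergeometric model is approximate in that case. BY is
conservative: observed null false-discovery fractions are far below the
nominal level, which is the accepted price of dependency-proof control.

## Synthetic data

The generator produces every input with known ground truth:

* **Species trees** are pure-birth (Yule) samples — waiting times
  Exp(k·birth_rate) between births, plus a final Exp(n·birth_rate) segment
  so terminal branches are strictly positive — then rescaled to a chosen
  height (default 0.5 substitutions/site, a moderate-divergence regime
  where orthology and topology recovery are expected but not trivial).
* **Alignments** evolve site-independently and gap-free: root states from
  the model's equilibrium, branch transitions from exact P(t), an optional
  rate multiplier on one focal terminal branch. Long branches demonstrably
  converge to equilibrium composition (chi-squared goodness of fit at
  10,000 sites). Gaps exist only via an explicit injection helper used to
  test the column filter.
* **Contigs** embed each protein behind a start codon, a uniform synonymous
  codon choice, a random stop codon and {C,T} untranslated flanks (that
  alphabet admits no start or stop codon on either strand), on a random
  strand. A configurable fraction is emitted 5'-truncated: the contig keeps
  the protein's tail after its last methionine, so the start-less,
  stop-terminated fragment is genuinely the recoverable product. Each
  emitted contig is verified against the selection rule and re-drawn until
  the planted product is the unique winner — the truth table is exact by
  construction, which is what makes a 100% round-trip criterion meaningful.
  Contigs shorter than 10 nt (decoys, or tiny planted proteins) are emitted
  unverified since they are excluded from translation by design.
* **Proteomes** share one species tree across families. Decoy paralogs
  diverge on an extra branch (default 0.6) placed before the family root;
  deletions hit non-reference species with probability `missing_rate`; a
  `shifted_fraction` of families carries the focal rate multiplier, and the
  truth table records each family's rate class.
* **GO fixtures** build a three-namespace DAG with a guaranteed chain to
  the requested depth, 1–2 parents per term, obsolete terms and an alt_id
  to exercise the parser, Poisson-ish direct annotations, and planted
  terms: study sets are drawn without replacement with gene weights
  odds^(carries enriched term) × odds^(−carries diminished term). Planted
  terms are picked at level ≥ 3 with background prevalence near 20% so
  both tails have room to move.

All randomness flows through numpy Generators seeded from the scenario;
identical scenarios give byte-identical FASTA/OBO/Newick text.

What the synthetic tests do **not** show: real transcriptomes have indels
(the families here are gap-free by construction, so the gap filter is
exercised only through injected gaps), compositional heterogeneity across
lineages, domain-level homology that confounds RBH far more than clean
paralog duplications, assembly artifacts beyond start-codon truncation, and
GO annotations whose errors correlate with sequence length. Passing these
tests shows the algorithms are implemented correctly and calibrated under
their own model assumptions, not that the assumptions hold for real data.

## Numerical choices and degenerate inputs

* Rounding of every reported percentage/mean: half away from zero, at the
  printed number of decimals.
* Transition matrices clip tiny negative eigen-reconstruction round-off
  to 0; pruning rescales partials per node and sums the rate mixture in
  log space.
* Zero-width alignments have lnL = 0 (used for prior-only MCMC checks);
  zero comparable sites make a distance undefined (error).
* Branch lengths live in [0, 20]; p-distances clamp at 0.95; negative NJ
  branch estimates clamp to 0; D clamps at 0.
* Empty candidate sets, unknown taxa, unrooted trees where rooted ones are
  required, gapped matrices in likelihoods, inconsistent hypergeometric
  counts and cyclic ontologies all raise typed errors
  (`PhyloError`, `ClockError`, `OntologyError`, ...).

## Problem sizes used in the shipped tests

Unit and acceptance tests run on desk-scale scenarios chosen to exercise
every code path with comfortable statistical margins: 3–11 taxa, 4–50
families of 80–2000 residues, 200 null LRT replicates at 500 sites, 25
power replicates at 2000 sites, 100–200 GO study redraws on 60-term/500-gene
fixtures, and an 8000-generation MCMC on a 6-taxon, 2000-site matrix. These
sizes are the package's chosen simulation design points; the generators
accept arbitrary sizes.
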