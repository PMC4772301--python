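# Methods

This note documents the models and procedures implemented in `holocompare`,
the parameter choices that matter, what the synthetic generators do and do
not emulate, and the numerical conventions used throughout.

## Gene-origin tagging (E/P/X)

Each predicted gene is tagged from its homology hits: **E** if any hit to a
eukaryotic sequence has e-value strictly below the threshold (default 10⁻⁴),
otherwise **P** if any prokaryotic hit is below the threshold, otherwise
**X**. Tagging is total: every query receives exactly one tag. Hits to taxa
outside the eukaryote/prokaryote dichotomy (viruses, unplaced sequences) are
dropped with a warning at table construction — the rule only defines the
binary split, and such hits are rare enough in practice that neither tag is
defensible for them.

## Domain repertoire comparison

Occurrence counts (how many times a domain appears in a genome) are the
primary statistic; the number of distinct domain-bearing genes is carried as
a secondary statistic. Expansion calls between species `a` and `b` use the
inequality form `count_a ≥ t · count_b` (default t = 1.5) rather than a
ratio, which handles zero denominators cleanly: any positive count against
zero is an expansion, and a domain absent from both species is never
reported. The form is antisymmetric — swapping the species swaps the call
directions exactly.

Over/under-representation of a domain in a focal genome is ranked against a
background panel of eukaryote genomes by `z = (x − μ)/σ`, with μ and σ the
sample mean and (S−1)-denominator standard deviation across the S panel
species. The panel is treated as a sample, not a population. Domains with
σ = 0 or absent from the panel are flagged unscorable instead of receiving
infinite scores. Keyword selection of immune/symbiosis domains is
case-insensitive substring matching over all annotation strings of a domain
(description and GO-term names alike); the default keyword list is
"symbio", "innate immunity", "antimicrobial peptides", "antibacterial".
Substring semantics are strict — "innate immunity" does not match "innate
immune response" — so keyword lists should include the lexical variants the
annotation source actually uses.

## Co-occurrence networks

A protein containing k distinct selected domains contributes one count to
each of its C(k,2) unordered domain pairs, per species — presence-based, so
multiple copies of a domain within one protein do not inflate edge weights,
and homotypic pairs are excluded. The default edge filter retains a pair
observed ≥ 5 times in ≥ 1 species. Node size is the number of retained
incident edges (degree). The invariant Σ_pairs w_s = Σ_proteins C(k_p, 2)
is used as a conservation check in the tests.

## Markov clustering (MCL)

Both clustering stages (SRCR families, metatranscriptome homology groups)
use the same dense MCL implementation. Self-loops are added with weight
equal to each node's maximum incident edge weight (1 for isolated nodes),
the adjacency matrix is column-normalised, and the iteration alternates
expansion (matrix power, default 2) with inflation (elementwise power r,
column renormalisation) and pruning of entries below 10⁻⁵ (guarded so a
column is never emptied), until the max-norm change falls below 10⁻⁸ or 200
iterations. Clusters are read off the attractor structure: nodes with
positive return flow are attractors, attractors exchanging flow form one
attractor system, and every other node joins the system of its
largest-probability attractor (ties broken by smallest node id), which makes
the output deterministic. Non-convergence returns the current
interpretation with a `converged=False` flag.

Inflation defaults: 2.0 generally (the canonical MCL default, used for the
SRCR family stage where no value is dictated by the analysis design) and
3.6 for metatranscriptome homology-group construction. On graphs whose
components are cliques, MCL reproduces connected components for any
inflation > 1 — the basis of the oracle test. The dense implementation is
appropriate for the graph sizes this pipeline sees (≤ a few thousand
nodes); it is not an out-of-core MCL.

## Sequence alignment and the homology criterion

All-vs-all comparison of domain instances uses exact Smith–Waterman local
alignment (Biopython's `PairwiseAligner`, which implements the affine-gap
DP exactly) with BLOSUM62, gap open 11 and extend 1 (a gap of length L
costs 11 + L), the standard protein defaults. The ambiguity residue X
scores 0 against everything. Raw scores are converted to bit scores with
the standard gapped Karlin–Altschul constants λ = 0.267, K = 0.041. Where
several local alignments are co-optimal, the aligner's first traceback is
used — deterministic, and immaterial to scores; the positives fraction of
near-identical domain pairs is insensitive to the choice.

Two domains are called homologous when ≥ 90% of the *shorter sequence*
aligns with positive substitution scores. The denominator matters: relative
to aligned columns only, the optimal local alignment between two unrelated
sequences can be a 3–5 residue perfect-scoring segment with a positives
fraction of 1.0, so an alignment-length denominator admits spurious
homology edges between any sequences sharing one high-scoring tripeptide.
The coverage-aware form (positives / shorter-sequence length) requires the
match to span the domain and cleanly separates family members from
background; the alignment-column denominator (the convention of BLAST's
"Positives" percentage) remains available via the `denominator` switch.
Homology edges are weighted by bit score and fed to MCL; clusters with ≥ 5
members are retained, ranked by size (ties by smallest member id), and
smaller clusters are reported separately rather than dropped.

## Multiple alignment and conservation profiles

Retained clusters are aligned with center-star progressive alignment: the
center is the member with the maximal summed pairwise global-alignment
score (same scoring model), every other member is aligned to the center,
and gaps are merged under "once a gap, always a gap". For the short,
high-identity domain instances this pipeline clusters, center-star is an
adequate substitute for iterative refinement aligners; it is exact for two
sequences and its error is bounded relative to the optimal sum-of-pairs
alignment. It is not a general-purpose MSA tool for divergent sequences.

Per-column profiles report the frequency of each residue and of the gap
symbol (summing to 1 per column), conservation (maximum amino-acid
frequency, gap excluded) and cysteine conservation (frequency of C) — the
quantity that exposes the conserved cysteine scaffold over a variable
background that characterises SRCR-like domains. Lineage-expansion tables
count members per species per cluster; a species is flagged dominant when
its share strictly exceeds 0.5, so an even split has no dominant lineage.

## Metatranscriptome pipeline

Reads matching an rRNA reference at ≥ 90% alignment coverage **and** ≥ 90%
identity are removed (thresholds inclusive). Retained reads are assigned to
MCL homology groups through their best-hit reference; reads whose best hit
falls outside every group are tallied in an explicit unassigned bucket so
read counts are conserved.

Quantile normalisation forces all samples onto the common distribution of
rank means: each rank's value is replaced by the cross-sample mean of the
values at that rank, and tied values within a sample receive the mean of
the reference values across their tied rank range (the same tie policy as
limma's `normalizeQuantiles(ties=TRUE)`, against which the implementation
is cross-checked). With ties, sorted columns are identical only up to the
tie-averaging; for tie-free data they are exactly identical and the
transform is idempotent.

### Differential expression

The default caller is an empirical-Bayes moderated t-test on
log2(scaled count + 1):

1. Size factors are median-of-ratios (each sample's median, over groups
   observed in all samples, of count / group geometric mean). This is
   robust to composition shifts: when a minority of groups is strongly
   up in one community, total-count scaling (and rank-based quantile
   mapping) systematically biases all other groups, which inflates false
   positives; the median ratio does not.
2. Per-group pooled variances are shrunk towards a common prior whose
   scale and degrees of freedom are estimated by moment-matching the
   marginal scaled-F distribution of the sample variances; the t
   statistic uses the posterior variance with augmented degrees of
   freedom. With the few replicates typical of metatranscriptome designs,
   raw per-group variance estimates are the dominant noise source;
   moderation restores power without anticonservative calibration.
3. Benjamini–Hochberg step-up across tested groups; DE iff q ≤ 0.05.
   Groups with zero counts everywhere are excluded from testing.

When a community has no replicates the caller falls back to an exact
conditional rate test: given the two summed community counts x₁, x₂ and
library totals T₁, T₂, x₁ is tested against Binomial(x₁+x₂, T₁/(T₁+T₂)),
two-sided. This conditional form is exact under Poisson sampling but blind
to biological overdispersion — it is the honest option only when replicates
are unavailable (the no-replicate setting is also the natural use case of
single-library fold-change callers). An externally produced DE list can be
injected via `injected_differential` and flows into enrichment unchanged.

The quantile-normalised table is retained as the cross-sample-comparable
expression matrix for reporting and heat maps (log2 with pseudocount 1);
the test statistic itself uses the size-factor-scaled counts for the
composition-robustness reason above.

### Domain enrichment

For each domain present in at least one DE group: N = homology groups in
the universe, K = universe groups carrying the domain, n = DE groups in the
universe, k = DE groups carrying the domain; p is the upper hypergeometric
tail P[X ≥ k], and q the BH-adjusted value (enriched iff q ≤ 0.05). The
default universe is the annotated groups (≥ 1 domain): unannotated groups
carry no information for a domain-level test and only dilute N; the full
universe is available via `universe="all"`. The test is at group-level
presence, not domain-instance counts, because the homology group is the
expression unit. The same machinery applies to any group-level labels (e.g.
GO terms) by relabelling.

## Synthetic data generators

All generators are pure functions of their spec (seed included) and return
truth labels alongside the data. Negative-binomial counts are parameterised
by mean μ and dispersion α with variance μ + αμ² (Gamma–Poisson mixture);
α = 0 degenerates to deterministic counts, which the tests use for
noise-free baselines.

**Domain-count panel.** Per-domain baseline means are drawn log-uniformly
from 100–1000 (typical occurrence counts of common, broadly distributed
domain superfamilies). Focal-genome dispersion defaults to 0.01 (~10%
biological CV between comparable, well-annotated genomes for unexpanded
families — at the 1.5-fold calling threshold, cross-species dispersion much
above this makes fold-change calling inherently unreliable, which is a
property of the method, not the simulation). The background panel spans
diverse eukaryotes and uses dispersion 0.3. Planted expansions multiply one
(species, domain) baseline by a fold ≥ 1.

**SRCR-like clusters.** Each cluster draws per-column residue
distributions over the 19 non-cysteine residues from a symmetric
Dirichlet(1/κ), where κ (`variable_column_concentration`, default 240) is
the conservation strength: expected within-cluster per-column identity is
(1+κ)/(19+κ) ≈ 0.93 at the default, while independent scaffolds keep
between-cluster identity near chance. κ → ∞ gives identical members;
κ → 0 gives uniform noise. A shared set of cysteine columns carries C with
probability `cysteine_retention` (default 0.95). The default calibration
places within-cluster pairs comfortably above the 90%-positives homology
criterion and between-cluster pairs far below it; with 10-member clusters,
roughly 3% of seeds still produce one member deviant enough to detach as a
singleton — visible as an adjusted Rand index of ≈ 0.975 instead of 1.0 in
the acceptance summary. The generator emits gapless fixed-length instances:
it models the conserved-cysteines-over-variable-background signature, not
indel variation, domain truncation, or length heterogeneity of real SRCR
repertoires — passing recovery tests therefore demonstrates the clustering
machinery, not robustness to alignment-length variation.

**Metatranscriptome counts.** 500 homology groups, two communities with 4
replicate samples each (a realistic replicate count for such designs),
group means log-uniform in 50–500, dispersion 0.1 (strong biological
overdispersion: variance ≈ 20–50× Poisson at these means). Planted DE
groups multiply the second community's mean by 2^log2_fold. Domains are
assigned to groups at a background presence of 0.1; planted enriched
domains are present in 0.8 of DE groups. The generator does not model
between-sample library-size variation beyond what the NB noise induces,
nor correlated group abundances (taxonomic structure); calibration results
transfer to real data only insofar as residual variation is roughly
NB-like after normalisation.

## Numerical conventions

- Coordinates: 0-based half-open internally; annotation files are 1-based
  inclusive (converted on read).
- MCL: column sums renormalised after every inflation and pruning step;
  convergence in max-norm at 10⁻⁸.
- Quantile normalisation ties: mean of reference values over the tied rank
  range; stable sort.
- Degenerate DE rows (zero variance everywhere): p = 1 when the community
  means are equal, p = 0 otherwise (only reachable in the unmoderated
  fallback; the moderated test always has positive posterior variance).
- Hypergeometric p with k = 0 is exactly 1; k > min(K, n) is a fatal
  inconsistency.
- Cluster and clustering orderings are fully deterministic (size
  descending, then smallest member id) so "top ten largest clusters" is
  well-defined.

## Known limitations

- The aligner scores are exact Smith–Waterman, not BLAST heuristics: no
  composition-based statistics, no e-values; the homology criterion is a
  positives-coverage threshold, not an e-value cut.
- Center-star MSA has no iterative refinement; profiles of divergent or
  indel-rich clusters would be less reliable than MAFFT-class alignments.
- The moderated t-test assumes roughly log-scale-homoscedastic NB noise
  shared across groups; heavy-tailed contamination or strongly
  mean-dependent dispersion would call for trend-fitted priors.
- GO-term enrichment is supported only by relabelling groups with GO
  annotations; no ontology propagation is performed.
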