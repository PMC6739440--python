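# Methods

This note records the statistical definitions the package implements, the
behaviour of the synthetic-data generator, and the judgement calls made where
a published convention does not pin down every detail.

## Compositional statistics

**Codon counts and GC by position.** All statistics are computed over sense
codons of validated CDS (in frame, unambiguous alphabet, no internal stop; a
terminal stop is trimmed and recorded — the only repair ever applied). GCk
is the fraction of G or C at codon position k over all sense codons, Met and
Trp included; GC12 is the mean of GC1 and GC2. A GC3s variant restricted to
degenerate families is available (`synonymous_only=True`) because published
analyses are often silent about which convention they use; the default is
the all-codon version for simplicity and reproducibility.

**RSCU.** For codon j of an amino acid with family size k,
RSCU = observed count ÷ (family total / k). Uniform within-family usage
gives 1 for every codon. Families with zero observations are *missing*
(NaN), never zero — a zero would claim evidence of avoidance that the data
do not contain. Met and Trp (single-codon families) are excluded, leaving 59
entries under the standard code.

**ENC.** Wright's estimator. Per amino acid with n ≥ 2 observations the
codon homozygosity is F = (n·Σp² − 1)/(n − 1); F values are averaged within
degeneracy classes (2-, 3-, 4-, 6-fold), and
ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, the leading 2 counting the
single-codon amino acids. When the lone 3-fold amino acid (Ile) is
unobserved, F̄₃ is imputed as (F̄₂ + F̄₄)/2, Wright's convention. The result
is clipped into [20, 61]; with finite counts the raw estimator overshoots 61
slightly even under perfectly even usage (at 100 copies of each sense codon
it evaluates to ≈61.4 before the ceiling), so the cap is part of the
estimator, not a cosmetic. Estimates are missing when any required class
mean is undefined or non-positive.

**Neutrality regression and the ENC expectation.** GC12 is regressed on GC3
by ordinary least squares across genes (or across species super-genes for
the pooled "pseudo" plot). Slope ≈ 1 is the mutation-driven limit; slope ≈ 0
indicates selective constraint on positions 1–2. The mutation-only ENC
expectation is ENC_exp(s) = 2 + s + 29/(s² + (1 − s)²).

**Codon–GC3 correlations.** Per codon, the Pearson correlation across genes
between per-gene RSCU and per-gene GC3, dropping genes with a missing
family pairwise and requiring at least three informative genes. Pearson on
RSCU is the common heatmap convention; Spearman is available. RSCU is a
per-codon linear rescale of within-family frequency, so correlations are
identical under either usage measure and no separate frequency mode is
needed.

## Orthology

Best hits per query keep the lowest e-value (discarding e-values strictly
above the cutoff — a hit *at* the cutoff is significant), breaking ties by
bitscore and then subject id so results are deterministic on any input
ordering. A reciprocal best-hit pair must be best in both directions.
Multi-species groups are built either anchored on one species (default:
alphabetically first; needs only k−1 table pairs) or as full reciprocal
cliques (every within-group pair must itself be an RBH pair; needs all
pairs). Published "restrictive one orthologue per species" selections rarely
state which variant they used, so both ship and the choice is recorded in
the output; on conflict-free data they agree (tested).

## Alignments and super-sequences

Back-translation requires the ungapped protein row to equal the translation
of the CDS exactly — mismatches abort with species, family and position,
because silently skipping codons would desynchronise every downstream
orthologous-position count. Degapping removes any column with a gap in one
or more species. Families shorter than 35 amino acids after degapping are
dropped ("less than 35" read strictly: 35 survives, 34 does not — the
boundary is tested). Retained families are concatenated in ascending family
id regardless of input order; concatenation order affects nothing
statistical but must be reproducible.

## Substitution analysis

Matrices are oriented rows = first-named species. Two chi-square tests use
the same two-cell form: observed (c₁, c₂), expected e = (c₁+c₂)/2,
χ² = (c₁−e)²/e + (c₂−e)²/e with df = 1 and no continuity correction. Usage
deviation compares an amino acid's row total (species 1) with its column
total (species 2); reciprocal asymmetry compares A[Z][X] with A[X][Z].
Cells with expected count < 5 are flagged and left untested — a standard
validity guard that published descriptions of this test usually omit.
Benjamini–Hochberg adjustment is applied across the tested set; raw p
values are always reported so readers can apply their own correction.

**Two-hit summary.** For each ordered amino-acid change Z→X and each source
codon c, observed target codons partition into single-step (1 nt from c)
and multi-step (≥2 nt). The baseline is a deliberately conservative
single-step-favouring model: given that Z→X happened at source c, the
target *would have been* a minimal-nucleotide-distance codon of X (ties
split equally — all tied codons share the same distance, so the baseline
multi-step fraction is 0 or 1 per cell). The reported `excess` (observed −
baseline multi-step fraction, count-weighted for the aggregate) is
therefore 0 for any data that a pure minimal-path substitution process
could generate, and positive only when substitutions overshoot the minimal
path. This operationalisation is a modelling choice of this package; the
underlying hypothesis it quantifies is qualitative.

## Clustering, ordination, preferred codons

Species RSCU vectors (dense, from concatenated super-genes) are clustered
under a settings grid — Euclidean distance × {complete, average, Ward}
linkage by default; the exact grid used in published analyses is typically
unstated, so this one is a documented choice, not a reproduction. Every
dendrogram is reduced to its clade set; clades present in strictly more
than half of the settings form the majority-rule consensus (strict majority
guarantees pairwise compatibility), with clade frequency as support. The
consensus is computed directly on rooted dendrogram clades rather than
through unrooted-split machinery, which is the matching operation for
ultrametric hclust trees.

Ordination is PCA of the gene × codon-frequency matrix by default, with
correspondence analysis (SVD of the chi-square standardised residuals) as
an alternative mode — descriptions of this analysis alternate between the
two, so both ship and neither is asserted as canonical.

Expression strata are exclusive: high means strictly above the 90th
percentile, low strictly below the 10th, with thresholds taken at observed
data values so the stratification is invariant under monotone transforms of
expression (RPKM vs log-RPKM cannot change the calls). Genes without an
expression value are excluded, not imputed. The per-codon test is a
two-sided Mann–Whitney rank-sum on per-gene RSCU between strata — chosen
for robustness to the strong skew of small-count RSCU — with BH adjustment
across the 59 codons; a codon is *preferred* only if additionally its
high-stratum mean exceeds its low-stratum mean. A pooled-count chi-square
mode is provided as an alternative.

## The synthetic-data generator

The generator emulates the data regime the analysis assumes: k species
(default 6) sharing n families (default 100) of mean length 300 codons,
with species GC3 targets spanning 0.30–0.70 by default — comparable to the
spread between AT-rich and GC-rich genomes in phylum-scale surveys
(transcript GC roughly 0.30–0.59, with a wider GC3 range). Defaults:
`aa_sub_rate` 0.05 per site per species, `two_hit_theta` 0.7 (double
substitutions common, matching the qualitative picture the two-hit
hypothesis describes), `gap_rate` 0.03 per column with 5% of families
heavily gapped (70–95% of columns) so the 35-aa filter does real work,
log-normal expression (log-mean 2, log-sd 1.5, i.e. median ≈ 7 RPKM-like
units), and an expression–preference coupling of 0.27, which shifts the
planted preferred codon's RSCU by about +0.8 in the high stratum for a
4-fold family.

Mechanism per family: an ancestral protein is drawn i.i.d. from a fixed
typical proteome composition and assigned codons at an ancestral GC3 tilt
of 0.5. Each species independently attempts a substitution per site with
probability `aa_sub_rate`; a substitution replaces the ancestral codon with
one of its *single-nucleotide neighbours* encoding a different amino acid
of the same conservative class ({G,A,V,L,I}, {S,T}, {N,Q,H}, {D,E,K},
{F,Y,W}; P, M, C and R only vary synonymously). With probability
`two_hit_theta` the codon is then re-drawn from the species' GC3-tilted
distribution over the new family (two hit); otherwise the neighbour codon
itself is kept (single hit). Synonymous variation enters at fully conserved
columns, where every species re-draws its codon from its tilted family
distribution; at columns where any species substituted, conserved species
keep the ancestral codon.

Two non-obvious consequences are deliberate:

* **The θ = 0 null of the two-hit excess is exact.** Single-hit pairs sit at
  nucleotide distance 1 by construction, and within the chosen substitution
  classes the minimal codon path between families is symmetric in both
  viewing directions (verified exhaustively over the code table in the test
  suite). Classes were *selected* for this property: pairs like Lys↔Arg or
  Ala↔Ser — which real data do show, and which the analysis module handles
  fine — have asymmetric geometry through the AGR/AGY codons and would
  build a positive excess into the null by construction.
* **GC3 targets are hit by calibration, not hope.** The deterministic sites
  (frozen ancestral codons and single-hit neighbours) are tallied first and
  the third-position G/C probability of the re-drawn sites is solved so the
  species-wide expectation equals the target; infeasible targets are
  rejected with the achievable range. Realised GC3 lands within binomial
  noise of the target (±0.02 is comfortably met at 100 × 300 codons).

Hit tables give every true orthologue pair a mutual best hit at e-value
10^−U(20,80), with decoy hits at least 100-fold weaker, so RBH recall on
the truth set is exactly 100% — the orthology stage is exercised, not
stress-tested. Expression re-tilting swaps codons only within families
(proteins, and therefore alignments, are untouched).

What the generator does **not** emulate: tree-shaped evolution (all species
are independent draws from one ancestor — adequate for every pairwise
statistic in scope, wrong for phylogenetic inference), indel realism (gaps
are noise columns, not evolutionary events), paralogy (no duplicate genes,
so orthology recall tests say nothing about paralog confusion), genuinely
asymmetric-geometry substitutions (see above), and any correlation between
expression level and protein conservation. Passing tests on synthetic data
therefore validate the bookkeeping and the statistics, not the biology of
any particular genome.

## Numerical and degenerate-input conventions

Missing is NaN throughout and is propagated, never silently zeroed.
Zero-variance inputs are explicit: the neutrality regression returns a
flagged missing slope, correlations return NaN, all-equal expression is
rejected. Ties are broken deterministically everywhere (alphabetical
subject ids in best hits, sorted family ids in concatenation, fixed
neighbour enumeration order in the generator), and all randomness flows
from a single integer seed, so identical configurations reproduce
byte-identical outputs — re-running a pipeline config is the supported way
to verify an analysis.

## Problem sizes used in the test suite

The acceptance-style tests run the generator at 100 families × 300 codons ×
6 species for parameter recovery, 60 families × 200 codons × 2 species ×
70 replicates for the two-hit comparisons, and 100–200 families for the
preferred-codon calibration and recovery checks. These sizes give the
statistics comfortable power (e.g. the planted-GCC rank-sum p ≈ 10⁻³–10⁻⁴)
while keeping the whole suite under a couple of minutes.
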