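# Methods

This note documents the models, defaults and numerical choices behind
`quinrep`, and what the synthetic-data tests do and do not establish.

## Hit selection and annotation

A profile hit is retained when either condition holds:

* the profile ships a GA (gathering) bit-score cutoff and the domain bit
  score reaches it, or
* no GA cutoff exists and the independent domain e-value is below 10⁻³ *and*
  the query coverage (alignment length ÷ query sequence length) exceeds 0.5.

Both inequalities on the fallback branch are deliberate: the e-value bound is
strict (`<`), the coverage bound is strict (`>`), and a hit with a defined GA
cutoff is judged by the cutoff alone. A second policy
(`HitFilterPolicy.reductase()`, i-evalue < 10⁻⁵ and coverage > 0.5, ignoring
GA) matches the stricter convention used for O₂-reductase profile
collections. When several profiles match one protein, the lowest i-evalue
wins; exact ties break to the lexicographically smallest profile name so the
result is independent of input order.

The coverage denominator is the *query sequence* length. For hit tables that
report profile coverage instead, recompute `seq_length` accordingly before
filtering; the rule itself is unchanged.

Genome bookkeeping: MIMAG quality keeps genomes with completeness > 90% and
contamination < 5% (strict at both boundaries; missing values fail, which is
the conservative reading). One genome per species is selected with priority
NCBI reference > representative > seeded uniform draw; the draw is taken over
lexicographically sorted genome ids so a fixed seed reproduces the selection
regardless of input order.

## Pathway presence

A pathway's gene count is the number of *distinct* pathway gene labels in a
genome; paralogs count once for presence but are recorded as multi-copy.
Presence thresholds come in two forms:

* hard definitions — the O₂-independent UQ pathway requires all three of
  `ubiT`, `ubiU`, `ubiV`; RQ requires `rquA`;
* `"auto"` — inferred from the bimodality of the count distribution.
  The integer count histogram is scanned for local maxima; the two highest
  modes are kept and the threshold is one plus the deepest valley strictly
  between them (leftmost bin on ties). Unimodal distributions fall back to
  ⌈|genes|/2⌉ with a logged warning.

The default gene memberships (Men: menF/D/H/C/E/B/I/A + ubiE; futalosine:
mqnA–E; UQ O₂-dependent: core ubiA/B/C/D/E/G plus hydroxylases
ubiF/H/I/L/M/N/coq7) are an editable convention — users with curated profile
collections should pass their own `PathwayDefinition`s. Genes shared between
pathways (notably `ubiE`) count toward every pathway that lists them; this is
why auto thresholds, not count > 0, are the presence criterion.

## Gene context

Two genes are *contiguous* when the intergenic gap (bases strictly between
the nearer feature ends; overlapping features → 0) is strictly below 500 bp.
The contiguity score of a gene pair is (#genomes with a contiguous copy
pair) ÷ (#genomes containing the rarer gene) ∈ [0, 1].

The degree of synteny compares the observed proximity frequency `f` with the
probability `p` of proximity under uniform random placement:

    D = f ln(f/p) + (1 − f) ln((1 − f)/(1 − p)),

the Kullback–Leibler divergence of Bernoulli(f) from Bernoulli(p), with the
0·ln 0 ≡ 0 convention. Proximity on a replicon of length L means an
intergenic distance below d = p·L/2 (p = 0.02 by default, so 50 kb at 5 Mb,
5 kb at 500 kb); the threshold is evaluated per replicon, and copies on
different replicons of the same genome are never proximal. The denominator of
`f` is the number of genomes containing both genes — conditioning on
co-presence separates *synteny* from *co-occurrence*, which is measured
separately by the indicator covariance matrix (population normalization, so
diagonal entries are Bernoulli variances ≤ 0.25). A flag switches to an
all-genomes denominator. Distances are linear by default; circular
wrap-around is opt-in because replicon topology is rarely recorded reliably.

### ubiTUV architectures

Each complete (T, U, V) occurrence is canonicalized to the transcription
frame of the U–V pair (which must be adjacent, same strand, V following U).
Classes: **1** T adjacent upstream, same strand; **2** T adjacent
downstream, same strand; **3** T adjacent upstream on the opposite strand
(divergent from U, the shared-promoter geometry); **4** U–V adjacent but T
beyond the 500 bp cutoff or on another replicon. Everything else —
non-adjacent or misordered U–V, convergent downstream T, overlapping T — is
`other`. Classification is invariant under translation and reverse
complement; the numeric labels are cosmetic, the geometry names are the
stable identifiers. Multi-copy genomes are resolved by assigning copies to
occurrences so as to minimize the total genomic span (exhaustive over the
tiny assignment space). We make no claim about the size of the full
combinatorial space of strand/order arrangements; the classifier's partition
(1/2/3/4/other) is its own canonical enumeration.

## FNR-box scanning

Upstream windows cover up to 450 bp 5′ of the translation start on the
gene's coding strand, truncated only at replicon boundaries — intervening
genes do **not** truncate the window. The motif model is a position-weight
matrix; the default is the 14-bp palindromic FNR-box consensus
TTGATNNNNATCAA (N columns uniform), a configuration default rather than a
claim about any particular dataset, and PWMs built from aligned sites can be
re-symmetrized by averaging with their reverse complement. Because the motif
is palindromic, scanning the coding strand suffices.

P-values are exact: the log-odds score (bits, against a 0-order background
estimated from the scanned set by default) is discretized into 10⁻³-bit bins
by flooring per column, and the full distribution of the discretized score
under the background is computed by dynamic programming; the reported
p-value is the survival function at the observed (floored) score. Flooring
both the observed score and the distribution support biases p-values upward,
i.e. conservatively. Benjamini–Hochberg q-values are pooled over every
scanned position of the run (the FIMO convention), and a match requires
p < 10⁻⁵ and q ≤ 0.05. Offsets are reported for the match's 5′-most base,
signed relative to the translation start (−450 … −1).

## Association statistics

**Permutation test** (repertoire × metabolism): the statistic is G =
2 Σ O ln(O/E) over the cross-table — chosen over Pearson X² for its
behaviour on sparse R×C tables, and pluggable. One trait's labels are
permuted; p = (1 + #{G* ≥ G}) / (1 + N), bounded below by 1/(N+1). Default
N = 1000.

**Phylogenetic signal**: the statistic is the Fitch parsimony score of the
categorical trait on the rooted tree; the null shuffles tip values (default
10 000 randomizations); signal means fewer changes than random, so the test
is one-sided on the low side. With a heavily tied discrete statistic the
permutation p-value is valid but conservative: its null distribution is
super-uniform, which the calibration test checks in the defensible direction
(rejection rate ≤ α plus binomial slack).

**Coevolution LRT**: the independent model is two 2-state Markov (Mk)
processes (4 free rates); the dependent model is a 4-state chain over joint
states 00/01/10/11 with 8 single-change rates and simultaneous double
changes forbidden. Likelihoods use Felsenstein pruning — closed-form 2-state
transition probabilities, eigendecomposition of the 4-state rate matrix with
a matrix-exponential fallback, per-node rescaling — with a uniform root
prior by default (stationary frequencies are an option). Rates are optimized
in log space with box bounds [10⁻⁶, 100] (on branch-length-scaled rates) by
L-BFGS-B from 10 starting points by default. The dependent optimizer is
always seeded with the embedded independent MLE, which guarantees
logL_dep ≥ logL_indep up to optimizer tolerance (the models are nested and
the embedding is exact — the test suite verifies the factorization to
10⁻¹⁰). The statistic 2·ΔlogL is referred to χ² with 4 df.

## Synthetic data

The generator emulates the inputs of the whole pipeline with the planted
truth recorded: genomes as single 500 kb replicons of 0-order random DNA
(GC 0.5) carrying pathway gene cassettes; presence probabilities default to
the frequencies reported for the surveyed phylum (O₂-dependent UQ 0.98,
O₂-independent 0.39, Men 0.20, RQ 0.02, futalosine 0); ubiTUV laid out in
architecture classes with frequencies (0.5, 0.3, 0.15, 0.05) and geometric
intergenic gaps (mean 120 bp, capped below 500); FNR boxes planted upstream
of ubiU / ubiT at rates 0.75 / 0.64 with offsets uniform in [−200, −40];
hit tables with strong true hits and decoys that each fail exactly one
recorded criterion; metadata drawn to pass MIMAG; a Yule species tree
(birth rate 1, tip edges extended by the exponential time to the next birth
so every branch length is strictly positive); metabolism drawn conditional
on the repertoire. Everything derives from one seed; identical scenarios
give byte-identical files.

What the generator does *not* emulate: multi-replicon genomes,
rearrangements and HGT histories, higher-order sequence composition, real
FNR-motif variability across classes, annotation noise (split genes,
frameshifts), or phylogenetic autocorrelation of gene content (presence
draws are independent given the clade). Exact-recovery tests on this
generator therefore establish the *correctness of the computations* — that
filtering, counting, thresholding, classification and scanning implement
their definitions — not robustness to the messiness of real assemblies.

## Problem sizes and numerical defaults

The test suite runs everything at desk scale, chosen as the smallest sizes
at which each property is informative: oracle equivalences on trees of ≤ 6–8
tips (100/60 replicates), LRT calibration on 200 independent replicates at
100 tips and power on 200 dependent replicates at 200 tips (gain-rate ratio
20), permutation-test calibration on 1000 null datasets of 100 genomes, and
end-to-end recovery on a 200-genome noise-free scenario. The calibration
and power tests pass `n_starts=2` to the LRT: with the independent-MLE
start, additional random restarts change the fitted likelihoods only at the
10⁻⁶ level on these simulated datasets, and two starts keep 400 fits inside
a few minutes. Score discretization is 10⁻³ bits; optimizer bounds and
restart counts are stated above; permutation/randomization p-values always
carry the +1 correction.

## Known limitations

* The antimode threshold assumes a genuinely bimodal count distribution;
  gradual pathway decay (symbionts) produces intermediate counts that the
  fallback handles bluntly.
* Fitch parsimony on multifurcating nodes is computed by pairwise folding,
  which can overestimate the minimum change count off binary trees.
* The exact-p scanner assumes a 0-order background; low-complexity or
  GC-skewed upstream regions inflate scores relative to a higher-order null.
* The coevolution LRT's χ²(4) reference is asymptotic; on very small trees
  the permutation/parametric-bootstrap alternative (not implemented) would
  be preferable.
* Circular-replicon distances are opt-in and default off.
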