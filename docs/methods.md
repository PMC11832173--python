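# Methods

This note documents the models, conventions, numerical choices and
known limitations of the `mechanomics` package. Formal notation: a view
is a gene × sample matrix X with two-class labels; V⁰, V\*, V are the
raw, normalized and processed PC loadings; c is the gene–gene Pearson
matrix; g_comb the combinatorial-marker score; T the number of JVT
resamplings; Z the common-gene-pool size.

## Data model and normalization

Datasets are gene-major matrices with unique, upper-cased gene symbols
(case-folding is the only cross-species mapping performed; orthology
beyond symbol case is out of scope). Duplicate rows for a symbol —
typical of multi-probe microarrays — are averaged per sample before
anything else. Missing values are rejected, never imputed.

Three normalizations are provided, each applicable once to a raw
dataset: `log10` (x → log₁₀(x + pseudocount), default pseudocount 1 so
that zero counts map to zero), `log1p` (natural log, x → ln(x + 1)),
and `zscore` (per-gene, sample standard deviation with n − 1
denominator; constant rows map to zeros with a warning rather than
failing, since a constant gene carries no information either way). The
log base in marker normalization is immaterial: it rescales every gene
by the same constant and cannot change correlations, alignment flags,
or rank-based AUCs.

When several views are analysed jointly they are first restricted to
their common gene set, rows sorted lexicographically so that matrices
align across views by construction.

## PCA and loading processing

PCA treats genes as features: each gene row is centered across samples
(no variance scaling — scaling belongs to the upstream normalization
choice) and the centered samples × genes matrix is factorized by SVD.
Loadings are unit-norm right singular vectors; sample scores are their
projections. Two deterministic sign rules remove the SVD sign
ambiguity: each component is oriented so its largest-|loading| gene is
positive, and when class labels are in play the component is further
flipped so the mean score of the positive (stiff) class is ≥ that of
the other class, ties keeping the current sign.

Loadings are processed in two steps: log-compression
V\*ᵢ = sgn(V⁰ᵢ)·log₁₀(1 + |V⁰ᵢ|/⟨|V⁰|⟩), then an affine rescaling of
the magnitudes onto [0, 1] with signs restored, so that the most
important gene has |V| = 1 and the least important |V| = 0. Degenerate
cases: an all-zero loading vector is an error; when all |V\*| are equal
the rescaling denominator vanishes and all magnitudes are set to 1
(equal importance). sgn(0) = 0 throughout, which forces every PC-corr
involving a zero-loading gene to zero.

## PC-corr scoring, combination, thresholding

PC-corrᵢⱼ = sgn(cᵢⱼ)·min(|Vᵢ|, |Vⱼ|, |cᵢⱼ|), diagonal zero. Pairs
involving a constant gene row (undefined correlation) are set to zero
with a warning. Combination across N views: the magnitude is the mean
or the minimum of the per-view |PC-corr|; the sign is the mode of the
per-view signs, with a strict majority of nonzero signs required —
pairs without consensus are masked to zero, which for N = 2 is exactly
"opposing signs are masked". Thresholding keeps pairs with
|PC-corr^comb| ≥ cutoff (inclusive by default; a strict mode exists
because published node/edge counts can hinge on inclusivity). Cutoffs
may be absolute or a percentile of the |combined| distribution over all
unordered pairs; the pipeline default is the 99.9th percentile.

## Component selection

Three strategies:

- `fixed(k)` — use component k (the classical choice is PC1 when the
  phenotype dominates the variance).
- `auto` — the component whose sample scores maximize the two-sided
  AUC-ROC against the class labels, ties to the smallest index.
- `joint` (pipeline default for multi-view prediction sets) — choose
  one component per view simultaneously, maximizing the mean of the top
  10 combined PC-corr magnitudes the choice would generate (sign-
  agreeing pairs only, combined with the configured method). Two views
  are searched exhaustively over all component pairs; additional views
  are added greedily.

The joint strategy exists because per-view selection is statistically
fragile at small n: with 6 + 6 samples and a dozen candidate
components, some noise component frequently separates the classes as
well as the component carrying the true module, and AUC at n = 12 is
too coarse (granularity 1/36) to tell them apart. What noise cannot do
is produce the *same* strong gene pairs in independent views; scoring
component combinations by their conserved top edges exploits exactly
the cross-view consistency the combination step is built on. On the
reference synthetic design this raises planted-module recovery from
roughly three quarters of seeds to ~95% (measured on two disjoint
20-seed ranges). The top-edge count (10) matches the edge count of a
5-gene clique, the module scale the pipeline seeks; it is not
performance-critical (5 behaves equivalently).

## Module selection

When no marker gene list is configured, the module is the **largest
clique** of the thresholded network (ties broken by total edge
magnitude, then lexicographically). A clique is the graph-theoretic
form of "strongly interconnected module": every pair co-expressed and
discriminative in all views. The alternative — largest connected
component — is not robust at permissive cutoffs, where chains of
borderline edges attach dozens of background genes to the module; and
at the strictest possible cutoff it degenerates to the two endpoints of
the single strongest edge. Clique finding uses networkx's
Bron–Kerbosch enumeration; the thresholded networks are small (tens of
nodes), so exhaustive enumeration is cheap.

## Combinatorial marker

Fitted on one designated inference dataset: the reference gene is the
module gene with the highest average pairwise Pearson correlation to
the others (ties to input order); genes with correlation < 0 to the
reference get an alignment flag (strict inequality — zero correlation
leaves a gene unaligned; constant rows get correlation 0 with a
warning). Scoring any dataset: flagged genes are reflected about their
mean *on the dataset being scored* (align(g) = 2ḡ − g, an involution
that preserves the mean and negates all correlations), then the
per-sample mean over module genes is g_comb. Flags are frozen at
inference and reused on validation data; recomputing them per dataset
would let validation data influence the marker definition.

## AUC-ROC and multiview reduction

AUC is computed from midranks (Mann–Whitney): tied scores contribute ½
per tied cross-pair, exactly matching brute-force cross-pair averaging
(property-tested to equality). The two-sided variant max(AUC, 1 − AUC)
is the default because marker direction can invert between biological
systems; one-sided mode (positive class = group A) is available.
Multiview reduction across comparisons defaults to the minimum — the
conservative "weakest view" summary — with mean and median available.

## JVT

The observed statistic is the marker's multiview score. Null draws:

- *single-gene* — one gene uniform from the Z-gene common pool, scored
  identically. The pool's per-gene multiview scores are precomputed
  once (vectorized rank transform), so the test is O(Z + T); the null
  sample just indexes them.
- *combinatorial* — m distinct genes per draw; each draw rebuilds the
  **entire** marker (reference selection, alignment fit on the
  inference dataset, per-dataset compression). Compressing null draws
  with a bare mean would handicap them against the aligned tested
  marker.

The tested gene/set is not excluded from the pool, the conservative
reading of "sample at random". p = (# null ≥ observed)/T, inclusive, so
p can be 0; the smoothed (1 + #)/(1 + T) value is reported alongside.
When the number of distinct draws (Z, or C(Z, m)) is ≤ T the null is
enumerated exhaustively instead of sampled, recorded in the result.
Per-iteration RNG states are derived from a single integer seed via a
seed sequence keyed by iteration index, so results are reproducible and
independent of any batching of iterations. Defaults: T = 10,000 for
real analyses; the test suite and acceptance script use T = 500–1,000
to stay fast at their smaller pool sizes.

## Synthetic study generator

A Gaussian latent-factor model, chosen over a count model because every
downstream statistic (Pearson, PCA, rank AUC) operates on
already-normalized expression; a log-normal wrapper produces positive
"raw" values when the log normalizers need exercising. For sample s
with class code y_s ∈ {−1, +1} and planted gene g in view k:

  x = √ρ·f_s + √(1−ρ)·ε_gs + a_gk·(d/2)·y_s,

f_s a shared per-sample factor (within-class pairwise correlation ρ),
ε iid unit noise, d the class-mean separation in noise-sd units, and
a_gk ∈ {−1, +1} the per-gene per-view effect direction, flipped with
probability `flip_prob` to emulate markers whose direction differs
between systems. Background genes are iid standard normal; the class
effect enters planted genes only. Including the class term, the
population correlation between two same-direction planted genes is
(ρ + d²/4)/(1 + d²/4) — 0.8 at the defaults — and each planted gene's
population two-sided AUC at d = 2 is Φ(√2) ≈ 0.92. The null variant
forces d = 0 but keeps the correlated module, so specificity tests can
target a coherent, non-discriminative gene set. Views are generated
from per-view substreams of one seed; studies are bit-reproducible.

Default design (two views, 500 genes, 5-gene module, d = 2, ρ = 0.6,
6 + 6 samples, no flips) is the reference condition for all
seed-replicated properties. What the generator does *not* emulate:
count noise, library-size and batch effects, probe-level artifacts,
gene-length biases, or modules with internal substructure. Passing
tests demonstrate the statistical machinery behaves as designed under a
clean factor model, not performance on any particular real platform.

A useful exact benchmark used by the tests: under the null at 6 + 6
samples the mean of the two-sided AUC over iid genes is 0.640
(enumeration over all C(12,6) label splits), not 0.5 — the two-sided
statistic is biased upward by construction; only the one-sided AUC
averages 0.5.

## Pipeline and reproducibility

The YAML-driven pipeline stamps every bundle with a config hash and
seed; per-test seeds are derived from the base seed and the hypothesis/
marker indices through seed sequences (kept below 2³¹). Re-running a
config is bit-identical; the CLI is a thin layer over the same
functions and is tested to produce identical numbers. A stage failure
aborts with a stage-named error and removes partial outputs.

Problem sizes in the shipped analyses and acceptance script — 20 study
seeds per rate, 200 calibration genes over ten 2,000-gene null studies,
T = 500–1,000 — were chosen as the smallest designs at which the
binomial noise on the reported rates is clearly smaller than the
margins being checked.

## Known limitations

- Gene matching across species is by symbol case-folding only; a real
  human–mouse analysis may want explicit ortholog mapping, and
  published gene-intersection counts may not reproduce without it.
- The thresholded network depends on cutoff inclusivity and on whether
  PCA centering matches the original analysis; both are configurable
  but published node/edge counts may be sensitive to them.
- JVT p values are reported raw, with no multiple-testing correction
  across markers or hypotheses.
- The joint component selector assumes the views share one conserved
  module; with several competing conserved modules it returns the
  strongest and ignores the rest.
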