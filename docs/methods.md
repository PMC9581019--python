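# Methods

## The model

A gene expression matrix *G* (m samples × n genes, positive intensities) is
turned into a weighted gene co-expression network and clustered into modules.
The package implements four pipelines that differ only in how the similarity
matrix is built; every later stage is shared, so differences in output are
attributable to the similarity choice.

**Calibration.** Each gene column is transformed by
s = logistic((g − μ)/σ²) with the gene's own mean μ and *variance* σ²
(sample variance, divisor m−1, switchable to the population variance via
`ddof`). The variance — not standard-deviation — divisor is intentional and
pinned by a regression test: it gives the transform units of 1/intensity, so
rescaling a gene column changes its calibrated shape. Low-variance genes are
sharpened toward {0, 1}; high-variance genes are flattened toward 0.5.
Outputs are clamped to (ε, 1−ε), ε = 10⁻¹², so strict positivity survives
floating point at any z. A zero-variance (constant) gene is a hard error by
default (`variance_policy="error"`); `"drop"` removes it with a warning.
Silent loss is never the default because pipelines must stay comparable on
the same gene set.

**Similarity.** Three variants, all exactly symmetric (upper triangle
computed and mirrored, asserted bitwise):

* inner product: S′ = SᵀS, then m_ij = (s′_ij − min_ij)/(max_ij − min_ij)
  where min/max range over the union of the 2n entries of row i and column j
  of S′ (diagonal included — the literal reading; a `scope="global"` toggle
  normalizes by the global extremes instead). Because S′ is symmetric the
  row/column-union scope is symmetric in (i, j), so the output is symmetric.
  The normalization attains 0 and 1 exactly at scope extremes; endpoints are
  kept, not clipped, and the diagonal is overwritten to 1 before any network
  step (the adjacency stage re-zeroes it, so the diagonal never influences
  results).
* cosine: m_ij = ⟨S_i, S_j⟩/(‖S_i‖‖S_j‖); strictly positive off-diagonal
  because calibrated coordinates are strictly positive; invariant to positive
  rescaling of a calibrated column, which the inner-product variant is not.
* Pearson baseline: pairwise correlation of the *raw* gene columns, mapped
  into [0, 1] with the same row/column-union min-max rescaling (not the
  conventional (1+r)/2 — the min-max form is the one the calibrated variants
  use, keeping the comparison controlled).

Raw values are used as deposited: no log transform, quantile normalization or
other preprocessing is applied before calibration, and none is assumed.

**Soft threshold.** The similarity matrix is powered elementwise by an
integer β (β = 1 is a bit-exact passthrough, usable as the
"drop scale-freeness" ablation). β is chosen as the smallest value in the
grid (default 1..20) whose weighted degree distribution passes the
scale-free fit: degrees binned into 10 equal-width bins, empty bins dropped,
OLS of log₁₀ frequency on log₁₀ mean bin degree, pass iff R² ≥ 0.85 (grid,
bin count and cut all configurable; at least 3 usable bins are required and
an all-equal degree sequence is an error). When *no* power passes, the
report is flagged not-scale-free and a fallback power is used: by default
the long-standing sample-count convention for unsigned networks (< 20
samples → 9, 20–29 → 8, 30–39 → 7, ≥ 40 → 6). The alternative fallback
(`fallback="argmax"`, the best-R² candidate) is available but not the
default: on a genuinely non-scale-free network the R² landscape is flat
noise, its argmax is arbitrary, and it frequently lands on β = 1, where the
geometric similarities have almost no contrast and the downstream TOM
degenerates. The best-R² candidate is always recorded in the report.

**TOM.** ω_ij = (ℓ_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij) with
ℓ_ij = Σ_{u≠i,j} a_iu a_uj and k_i = Σ_{u≠i} a_iu — the standard convention
(zero diagonal, self terms excluded; including the diagonal would break
ω ≤ 1). Implemented as one matrix product; equivalence with a verbatim
triple-loop implementation is asserted to 10⁻¹⁰ on random instances up to
n = 30.

**Clustering.** Dissimilarity d = 1 − w (w = TOM for `gamma`/`wgcna`, the
powered adjacency for `alpha`/`beta`, which stop before TOM), UPGMA tree
(scipy; deterministic), then an in-package dynamic tree cut with defaults
min_module_size = 30, cut_height = 0.99, deep_split = 2:

1. *Branch detection* — one bottom-up pass over the merge sequence. A merge
   finalizes its two sides when its height exceeds the static cut
   (cut_height is relative: q05 + cut_height·(h_max − q05), q05 the 5th
   percentile of merge heights) or when two module-sized sides join with a
   height gap above both sides' running-mean internal heights. Anything
   merging into an already-finalized component is finalized immediately, so
   genes that attach diffusely near the top of the tree cannot swallow the
   clusters below them (co-expression dendrograms are "ladders" near the
   top; a plain static cut cannot descend through them).
2. *Refinement* — a branch with ≥ 2·min_module_size genes is bisected by a
   Ward 2-cut of its sub-dissimilarity; the split is kept only if the halves
   are *distinct*. Distinctness uses the same admission radius as assignment
   (below): two gene sets are fragments of one module only when the mean
   cross dissimilarity lies within both radii.
3. *Trim/attach* — every gene joins the nearest module among those whose
   admission radius admits it, else label 0 (unassigned). The radius is a
   robust envelope of member-to-module distances, median + nmads·(scaled
   MAD), with nmads mapped from deep_split (0..4 → 1.0..3.0). A clear-margin
   rule additionally admits a gene whose best distance is at most half its
   second-best: such a gene unambiguously belongs even if it sits past the
   envelope.
4. *Fragment merge* — mutually-admitting module pairs are merged (closest
   first) and assignment is repeated; modules falling below the size
   threshold dissolve.

Labels are renumbered by decreasing size, 0 = unassigned; the whole
procedure is deterministic, and permuting gene order permutes labels
consistently (ARI = 1). A pure tree-shape variant (`hybrid=False`) skips
stages 2–4. The gap fractions and the nmads table are internal design
constants; they were fixed by requiring robust planted-module recovery
across many generator seeds of the synthetic benchmark and are not exposed
as user parameters (deep_split selects among them).

**Enrichment and quality.** For a module of size n in a universe of N genes
(default universe: all genes in the assignment; optionally intersected with
the annotated genes), every term with K ≥ 1 universe genes is tested in its
namespace in both directions: over-representation P(X ≥ k) and
under-representation P(X ≤ k), X ~ Hypergeometric(N, K, n), exact tails (no
normal approximation — p-values are strictly positive). Across the six
batteries (BP/CC/MF × over/under) the five smallest p-values are retained —
deduplicated by (term, direction) pair by default, term-level dedup
switchable — with ties broken by term id for determinism. No
multiple-testing correction is applied before the selection; the score ranks
raw p-values by design. Module quality is Q = −(Σ log₁₀ p_i)/5; with fewer
than five testable terms all available p-values are used, the divisor
shrinks accordingly and the module is flagged. Pipeline quality Q̄ is the
unweighted mean of Q over modules (label 0 excluded). The summation index in
the printed source formula is a typo (it reuses the module index for the
p-value index); the implemented sum is over the five retained p-values of
the module, following the accompanying prose.

## The synthetic benchmark

`SyntheticSpec` defaults: 1000 genes × 50 samples, five planted modules of
150 genes (250 background genes), within-module correlation ρ = 0.7. Member
genes of module m are baseline_j + √ρ·z_m + √(1−ρ)·e with a shared latent
sample profile z_m ~ N(0, I) and i.i.d. noise e, so same-module genes have
correlation ρ in expectation and between-module/background correlations are
0. Baselines are Uniform(5, 9) per gene (log₂-microarray-like intensities);
the matrix is shifted (never truncated — truncation would distort the
planted correlations) if any value is ≤ 0. The annotation plants one term
per module at precision = recall = 0.9 against the planted membership plus
30 uniform decoy terms of 20–60 genes spread across the three namespaces.
Everything is bit-deterministic given the spec seed.

What the generator does *not* emulate: probe/batch effects, heavy-tailed
intensity distributions, correlated background structure, overlapping or
nested modules, and — importantly — scale-free topology. The planted design
is strongly modular, so no soft power passes the R² cut and the pipelines
exercise the flagged fallback path; passing tests therefore demonstrate
correct mechanics and recovery on modular data, not performance on networks
that genuinely satisfy the scale-free criterion. Real-data behavior
(preprocessing sensitivity, probe collapse) is out of scope.

## Numerical choices and degenerate inputs

* Calibration clamp ε = 10⁻¹²; logistic computed via a sign-branched form
  so exp never overflows.
* Min-max normalization errors when an entry's scope is constant
  (degenerate matrix) rather than dividing by zero.
* Exact hypergeometric tails are asserted against an integer-arithmetic
  factorial-sum oracle for every (N, K, n, k) with N ≤ 60 at 10⁻¹².
* The scale-free regression requires ≥ 3 non-empty bins and non-constant
  degrees; candidates failing it are recorded with `r2 = None` and skipped
  by the power selection.
* Matrices with fewer than 2 rows or columns, duplicate identifiers,
  missing values (`NA`) and non-numeric cells are rejected at load with
  positioned error messages; missing-value imputation is deliberately not
  silent (a `drop` policy exists only for constant genes at calibration).

## Known limitations

* The dynamic tree cut is an in-package implementation of the dynamic
  hybrid idea, not a port of the reference R implementation; its module
  boundaries can differ from the reference tool's on the same tree, though
  both respect min_module_size, the relative cut height and deterministic
  output.
* Q̄ comparisons on the synthetic benchmark are tight (all pipelines find
  highly enriched planted terms); the Q̄ ranking between pipelines is
  meaningful mainly through seeded repetition, which is how the package's
  comparison script reports it.
* The enrichment universe treats unannotated genes as part of N by default;
  with sparse annotations this makes over-representation p-values smaller
  than an annotated-only universe would give. The flag exists because both
  conventions are in active use.
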