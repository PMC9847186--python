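# Methods

This note documents the statistical procedures implemented in `triomics`,
the defaults they ship with, the design choices that were genuinely open,
and what the synthetic-data tests do and do not demonstrate.

## Data model and normalization

Matrices are features × samples with a layer tag (`counts`, `cpm`, `fpkm`,
`abundance`, `log_abundance`). CPM is counts × 10⁶ / raw library size
(column sum; no size-factor rescaling enters CPM, which is defined on raw
library size). FPKM additionally divides by gene length in kb. The
low-expression filter keeps a gene iff CPM ≥ 10 in at least `min_samples`
samples; the boundary is inclusive and `min_samples` defaults to the
smallest replicate-group size of the design. Whether such a filter should
be applied per sample or on group means is a genuine ambiguity; the
per-sample rule is explicit, configurable and idempotent.

Matrix TSVs are tab-separated UTF-8 with a literal `feature_id` header
cell; floats are written at `repr` precision and read back with pandas'
round-trip parser, so write→read→write is byte-stable.

## Differential testing for counts

The NB Wald test is deliberately self-contained and oracle-checkable:

- **Size factors**: median-of-ratios over genes nonzero in every sample,
  rescaled to geometric mean 1; library-size factors as fallback when no
  gene qualifies.
- **Dispersion**: per-gene method of moments, α̂ = (s² − μ̂)/μ̂² per group,
  pooled across the two groups by degrees of freedom and floored at 1e-8.
  No shrinkage — power at 3 replicates is bought with the planted effect
  sizes, not with information sharing.
- **Statistic**: log₂FC of normalized group means with a delta-method
  standard error, SE² = [(μ_a + αμ_a²)/(n_a μ_a²) + (μ_b + αμ_b²)/(n_b μ_b²)] / ln²2.
- **Reference distribution**: Student t with n_a + n_b − 2 degrees of
  freedom. This is the package's small-sample calibration: the plug-in
  variance at 3v3 has ≈4 degrees of freedom, and a normal reference
  roughly doubles the nominal type-I error (measured ≈0.12 at α = 0.05 in
  the Monte-Carlo used by the test suite), while the t reference holds
  ≈0.045. The acceptance suite asserts the [0.035, 0.065] band.
- **Zero handling**: a 0.5 pseudocount is added to a group mean only when
  that mean is zero; genes all-zero in both groups get log₂FC = 0, p = 1.
- **Calls**: up iff FDR < 0.3 and FC ≥ 1.5; down iff FC ≤ 1/1.5 — the
  fold-change cut is interpreted as reciprocal fold change on the linear
  scale.

BH adjustment is the step-up rule implemented directly (q ≥ p always;
discoveries monotone in the cut); NaN p-values propagate as NaN.

## Metabolite testing

Metabolites are scored with VIP from a NIPALS PLS1 discriminant fit on
autoscaled log₂(x+1) abundances, VIP_j = √(p · Σ_a SSY_a w²_aj / Σ_a SSY_a),
which forces mean VIP² = 1. The orthogonal variant of the discriminant
analysis is simplified to plain PLS-DA: the VIP threshold, not the
orthogonal rotation, drives the calls. Significance comes from a Welch
two-sample t-test — biological replicates of different genotypes carry no
natural pairing, so a paired test is only available as an opt-in that
pairs replicates by index. A metabolite is called at VIP > 1 (strict) and
FDR < 0.05. The gene/metabolite FDR asymmetry (0.3 vs 0.05) is kept as
designed, not harmonized.

## Mid-parent comparison

MPV pseudo-replicate i is (female replicate i + male replicate i)/2 on the
normalized scale, pairing by replicate order with min(#F, #M) pseudo-
replicates. This construction yields a replicate-level MPV sample so the
same testing machinery applies. Because averaging breaks count
distributions, the F1-vs-MPV test is a Welch t on log₂(x+1) rather than a
count-model contrast, with BH across features and the same FC/FDR calls.

## The 12-type classifier

Inputs per feature: directional calls for H-vs-F, H-vs-M, F-vs-M at
identical thresholds, plus the three group means. The decision table is in
`inheritance.py`; "similar to a parent" is the absence of a significant
call, not an equivalence test, so low power inflates the ELD and
unclassified bins — a property shared by any absence-of-call criterion.

Two conventions were open and are now fixed:

- **Additivity requires both hybrid–parent contrasts significant** and the
  parents significantly different, with the hybrid mean strictly between.
- **Sub-splits within type pairs**: I vs II is keyed to the female parent
  being the higher parent; VII vs IX and X vs XII follow the stated
  male-higher/female-higher rule; III vs IV and V vs VI are keyed to
  whether the *matched* (dominant) parent is the higher parent. The last
  choice is what makes the classifier exactly label-equivariant under a
  parental swap (III↔V, IV↔VI rather than III↔VI), and it is the only
  convention under which a gene whose hybrid tracks the same inbred line
  in both reciprocal crosses lands in the mirrored pair (type V in one
  cross, type III in the other). Ties in the parent means fall to the
  second member of each pair; with continuous data they have measure zero.

Categories: I–II additive; III–IV ELD-M; V–VI ELD-F; VII–XII
overdominant; non-additive = ELD + overdominant.

## Mid-parent heterosis

MPH = 100 × (F1 − A)/A computed on group means (matching a
three-replicate averaging protocol), scale-invariant, defined only for
A > 0. Class-level summaries use a two-sided one-sample t against 0;
a zero-variance class reports p = 1 with a flag rather than a
significance claim; classes smaller than 2 are emitted untested.

## Co-expression networks

Unsigned adjacency a_ij = |cor|^β by default (the signed variant is
available); β defaults to 18 for genes and 17 for metabolites. TOM_ij =
(Σ_{u≠i,j} a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij) with unit diagonal.
Clustering is average linkage on 1 − TOM with a **static** branch cut at
0.99 of the tallest merge, a minimum module size of 30, and iterative
merging of modules whose eigengenes are closer than 0.25 (1 − r) — a
deterministic simplification of dynamic hybrid tree cutting that keeps the
pinned merge height and is directly testable on planted-block
constructions. Eigengenes are the leading right singular vector of the
standardized member matrix, unit-norm, sign-oriented toward positive mean
member correlation. Module–trait relations use Pearson r of the eigengene
against a binary parents=0/hybrids=1 trait, significant at |r| > 0.6 and
P < 0.05; reported values are signed correlations throughout (quantities
sometimes labelled R² in the literature carry signs and are treated as r).
A scale-free-fit helper (R² of log p(k) vs log k over 10 degree bins)
is provided for choosing β but never auto-applied.

## Enrichment

Upper-tail hypergeometric p per term with ≥1 study hit; BH across tested
terms is emitted but filtering follows the raw-p reporting convention
(GO P < 0.05, KEGG P < 0.01, strict). The default universe is the features
surviving the expression filter — not the whole annotation — to guard
against detection bias; this is configurable.

## Synthetic data

The generator emulates the reference design: genotypes B73, Mo17, BM, MB
under conditions Dk/FR/R/B with 3 RNA and 6 metabolome replicates. Counts
are negative binomial (dispersion 0.05) around mode-determined genotype
means scaled to a 10⁶ library; metabolites are log-normal with CV 0.2.
Defaults: planted parental separation and hybrid deviations of log₂
effect 2.0, gene base means log₂-uniform on [4, 10], a shared per-condition
log-normal effect (SD 0.15 log₂ units), and reciprocal hybrids identical in
expectation (parent-of-origin shifts opt-in, applied to alternating genes
so library scaling cannot absorb them). Biomass tables draw parent weights
around 0.9/1.1 g with multiplicative normal noise and set the hybrid mean
to mid-parent × (1 + MPH/100); the default planted MPH of 55% matches the
magnitude of seedling biomass heterosis reported for such crosses.

What passing tests show: the classifier, tests and network code recover
exactly the structure planted under their own model assumptions, at the
stated replicate counts. What they do not show: robustness to
misspecification present in real data — outliers, batch effects,
count–length biases, correlated noise between genotypes, metabolite
identification errors — none of which the generator emulates.

## Problem sizes and numerics

The test and acceptance runs use 5,000-gene single-condition designs for
mode recovery, 10,000 null genes for calibration, 80-feature planted
networks, and 200-run biomass recovery ensembles — sizes chosen so that
Monte-Carlo bounds are tight while a full run stays in seconds. Numerical
conventions worth knowing: dispersion floor 1e-8; TOM symmetrized and
clipped to [0,1]; eigengene sign fixed by mean member correlation;
constant-response ANOVA returns F = 0, p = 1; Welch with two zero-variance
samples returns p = 1 on equal means and p = 0 (with a warning) otherwise;
module labels are size-ordered color names with `grey` reserved for
unassigned features.

## Known limitations

- The NB test has no dispersion shrinkage or covariates; it is calibrated
  for the small balanced designs it targets, not a general DE engine.
- The static-cut + merge module detection can split long dendrogram arms
  that dynamic hybrid cutting would keep together; for the module sizes
  and separations this pipeline targets the two agree.
- Inheritance classification inherits the power asymmetry of
  absence-of-call ELD definitions: additive genes bleed into
  `unclassified` at low replication (reported by the recovery tables, not
  hidden).
- GO term graphs are not propagated; enrichment treats terms as flat sets.
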