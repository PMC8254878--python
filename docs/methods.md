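# Methods

## Somatic calling and filtration

Each candidate site carries paired read counts (ref/alt in normal and
tumor). The calling statistic is the Fisher exact test on the 2×2 table
[(normal_ref, normal_alt), (tumor_ref, tumor_alt)]. Conditional on the
margins, the tumor alt count is hypergeometric, so the one-sided p-value
toward tumor alt-enrichment is its upper tail; this is the default because
somatic callers test for enrichment in tumor, not mere difference. A
two-sided variant (`fisher_alternative="two-sided"`) delegates to
`scipy.stats.fisher_exact`. Zero depth in either tissue makes the test
undefined: batch calling records `NaN` and fails QC rather than raising.

The cascade runs QC → (P, S) → F:

* **QC**: p < `qc_p_max` (0.05, strict), depth ≥ 10 in both tissues,
  normal alt ≤ 1, tumor alt ≥ 3, normal VAF ≤ 0.03, tumor VAF ≥ 0.05.
  Boundary comparators are exactly as stated — ties at a threshold follow
  the printed comparator.
* **P (rare)**: every non-missing one of the four East-Asian population
  frequencies (1000G, ExAC, GnomAD genome, GnomAD exome) is strictly
  below 0.005. Missing is treated as frequency 0: absence from a
  population database is the strongest rarity evidence, and the canonical
  recurrent driver is precisely a never-observed allele.
* **S (severe)**: frameshift, stop gain/loss, start loss and splice
  variants qualify by consequence class; missense variants need at least
  `severe_tool_min` = 2 of {CADD-phred ≥ 30, SIFT damaging, PolyPhen-2
  damaging}, with a missing prediction counting as not damaging. SIFT and
  PolyPhen-2 are consumed as binary damaging calls, since the filter is
  defined on the letter-code predictions, not the raw scores.
* Synonymous variants are discarded before any filtering; the severity
  filter refuses them outright (reaching it indicates an upstream bug).
* **F = P ∩ S**, so F ⊆ P ⊆ QC and F ⊆ S ⊆ QC by construction, and
  tightening any threshold can only shrink the sets. Output order is
  canonical (sorted by variant key), making all results invariant to
  input permutation. Multi-allelic VCF records are split into one
  candidate per alt allele before testing.

## Co-expression network

Unsigned adjacency a_ij = |r_ij|^β with zero diagonal; the analysis
default is β = 12. `pick_soft_threshold` implements the scale-free fit
index — connectivity k is binned (10 equal-width bins), log10(frequency)
is regressed on log10(mean k), and R² is reported signed negative when the
slope is positive — choosing the smallest power reaching 0.85, else the
argmax. On the synthetic world described below the planted equal-size
blocks make the connectivity distribution bimodal rather than scale-free,
so the 0.85 target is never reached at 12 samples and the argmax fallback
engages (typically landing at 14–20); the pipeline therefore uses the
configured power 12 rather than the data-driven pick.

TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij) with
L_ij = Σ_u a_iu a_uj and TOM_ii = 1, computed as one matrix product. The
denominator is ≥ 1 − a_ij > 0 whenever a_ij < 1, and a_ij = 1 forces
min k ≥ 1, so no division by zero is possible.

Modules come from average-linkage hierarchical clustering on 1 − TOM with
a **static** cut at height 0.4. The named single cut height is the static-
cut signature, so static cutting is the implemented and tested mode;
clusters below `min_module_size` (default 30) are relabelled grey, and a
cut height of 0 degenerates to all-grey (every gene a singleton). Modules
are named M1, M2, … by decreasing size. No merge-by-eigengene step is
performed. Average linkage is the field default; the source analysis does
not state its linkage.

The module eigengene is the first right-singular vector of the
gene-standardized (z-score per gene, ddof = 1) module submatrix, scaled to
unit sample variance, with its sign fixed so it correlates positively with
the module's mean standardized expression. The sign rule makes "module
down-regulated in tumor" map deterministically to a negative eigengene
shift in tumor samples, hence a negative module–trait correlation.
Module–trait association is the Pearson correlation of the eigengene with
the binary trait (normal = 0, tumor = 1), with the two-sided p-value from
t = r√(n−2)/√(1−r²) on n−2 degrees of freedom. kME is the signed
correlation of each gene with each eigengene; hubs are module members of
maximal |kME| (anti-correlated hubs stay visible through the sign).

## GO over-representation

Terms with fewer than `go_min_genes` = 10 genes (within the background)
are not tested. For a query of n genes out of N background genes, a term
with K genes and k overlapping genes gets the upper-tail hypergeometric
p-value P(X ≥ k) — the observed k included. BH adjustment is the step-up
q_(i) = min_{j≥i}(p_(j)·m/j), capped at 1. Among terms with adjusted
p ≤ 0.05, any term that is an ancestor of another significant term is
dropped; "parent" is read transitively (the stricter reading — the only
one guaranteeing no kept term subsumes another), with a direct-parent-only
switch. Only is_a-style relations are consumed; the structure must be
acyclic and is validated on construction. The background defaults to all
annotated genes but can be supplied explicitly.

## Integration and the two-hit test

Final mutations are mapped onto modules; genes absent from the expression
data are labelled "absent" and retained in reports. The sub-network around
an anchor module (the module of maximal |module–trait r|) contains every
mutated gene present in the expression data plus every anchor-module gene
with TOM ≥ 0.15 to at least one mutated gene; edges join **all** node
pairs at the threshold, not only mutated-to-neighbor pairs — large
connected components around non-mutated hubs require neighbor–neighbor
edges. Mutated genes outside the anchor module are included as nodes but
recruit no neighbors of their own, which is why passenger mutations
typically surface as isolated, zero-degree nodes.

The VAF-ordering test selects the candidate first hit as the final-
mutation gene shared by the most patients (ties: highest mean tumor VAF,
then lexicographic). VAF is tumor_alt/(tumor_alt+tumor_ref); no purity
correction is applied. Per patient, the ordering holds iff the first hit's
tumor VAF **strictly** exceeds every other anchor-module final mutation's
VAF (a tie refutes the ordering). The cohort verdict is "two-hit
consistent" iff every evaluable patient has ≥ 2 anchor-module final
mutations and the ordering holds in each; a patient lacking the first-hit
variant is excluded from the verdict and flagged. This is a VAF comparison
only — no clonal deconvolution is attempted.

## Synthetic world

`SimulationPlan` defaults state the world once:

* **Variants** — 4 patients; one shared first-hit site (fixed coordinates,
  damaging missense, absent from all frequency databases) at tumor VAF
  0.35; 2 secondary sites per patient in disease-module genes at VAFs
  uniform in [0.05, 0.25]; background final mutations (stop-gains in
  unassigned genes); and five passenger sites per patient each failing
  exactly one named criterion (normal depth 9; normal VAF 0.05 via 1 alt
  read at depth 20; population frequency 0.05 in all databases; benign
  predictions; synonymous consequence). Depths are Poisson(150) truncated
  at `qc_depth_min`+5; tumor alt reads are Binomial(depth, VAF); normal
  alt reads Binomial(depth, 0.002) model sequencing error. Sites destined
  to pass QC are rejection-sampled until they do (the acceptance
  probability is near 1 at depth 150; the dominant rejection is ≥ 2
  error reads in normal, ~4%), so the truth table's intended fates are
  realized exactly and cascade counts are analytically known.
* **Expression** — x_gs = 0.9·f_{m(g),s} + ε_gs with ε ~ N(0, 0.1²) for
  module genes (three modules of 60 genes out of 300; within-module
  correlations ≈ 0.99, the tight-module regime a static 0.4 cut
  presumes) and unit noise for the 120 background genes; factors are
  standard normal per sample, independent across modules; the disease
  module's factor mean drops by 5 SD in the 6 tumor samples (against 6
  normals), putting the population eigengene–trait correlation near the
  0.93 magnitude the analysis targets.
* **GO** — one 20-gene term with 80% of its genes from the disease
  module, a strict-superset parent (+10 genes), six size-matched random
  terms.

Everything is driven by `numpy.random.default_rng(seed)` (expression uses
seed+1, GO seed+2 so the three generators are independently reproducible);
identical plans give byte-identical outputs.

What the world does **not** model: mutational signatures, copy number,
tumor purity, array batch effects, correlated noise, scale-free topology
of real transcriptomes, or realistic GO DAG depth. A green recovery test
therefore establishes that the machinery is correct on well-posed planted
structure, not that the original study's counts would be reproduced; the
study's headline numbers depend on raw sequencing data and expression
matrices that are not desk-available and are deliberately not asserted.

Two quantitative notes on the stated world, measured rather than assumed:
at depth 150 the *within-patient* first-hit/secondary VAF ordering blurs
in ~4/100 seeds (binomial overlap), while the cross-patient comparison
(cohort-wide min first-hit VAF vs max secondary VAF) blurs in ~7/100 —
ordering is a within-tumor notion and the tests treat it as such. And for
independent background genes at 12 samples the null median |r| is 0.216
(= t_{10,0.75}/√(t²+10)), which the generator's background matches.

## Numerical choices

* Fisher p and hypergeometric tails via `scipy.stats.hypergeom.sf(k−1, …)`;
  tests verify them against exact integer-arithmetic enumeration (1e-10 /
  1e-12).
* TOM is validated against an O(n³) triple loop at 1e-12; clique-of-ones
  and zero adjacency hit 1 and 0 exactly.
* Eigengene extraction uses SVD on the standardized submatrix (never the
  gene×gene covariance, which is singular for modules wider than the
  sample count); tests cross-check against an eigendecomposition of the
  sample-space Gram matrix.
* 1 − TOM is clipped at 0 before clustering to absorb float round-off.
* BH is monotonicity-enforced and capped at 1; cross-checked against
  statsmodels.
* Edge lists write each undirected edge once, smaller node first, TOM to
  six decimals; expression round-trips are bit-identical (`%.17g` +
  round-trip float parsing).

## Known limitations

* Static tree cut only (no dynamic tree cut); module counts on real,
  loosely correlated data will differ from dynamic-cut implementations.
* `pick_soft_threshold` needs enough distinct connectivity values to bin;
  degenerate inputs yield NaN fit entries and are skipped.
* The sub-network recruits neighbors only from the anchor module.
* Enrichment assumes the supplied term sets are the analysis universe;
  no GO release is bundled.
* Single-block network computation: fine to a few thousand genes, not
  intended for >20k-gene matrices.
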