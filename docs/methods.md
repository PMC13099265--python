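# Methods

This note documents the models and procedures implemented in `cellodeg`,
the defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the numerical conventions that matter for
reproducing results.

## Genome-level cellulolytic screening

Complete cellulose hydrolysis requires the concerted action of three
enzyme classes, so a genome is called a **candidate** cellulose degrader
only when its CAZyme repertoire covers all three:

| component | CAZy families | call |
|---|---|---|
| endoglucanase | GH5, GH8 | ≥ 1 copy across the group |
| exo-acting / processive cellulase | GH48, GH6, GH7, GH9, GH16 | ≥ 1 copy |
| β-glucosidase | GH1, GH3 | ≥ 1 copy |

Candidates receive a baseline score of 1; three bonus criteria add one
point each: LPMO presence (AA9/AA10), endoglucanase redundancy (≥ 2 copies
across GH5+GH8) and exoglucanase redundancy (≥ 2 copies across the exo
group). Bonuses are confidence-enhancing features layered on the baseline,
so non-candidates score 0 even when they carry LPMOs; the alternative
(bonuses without the baseline requirement) is exposed as
`bonus_requires_baseline=False` for sensitivity analysis. Redundancy is
counted across families within a category — GH5=1 plus GH8=1 satisfies
endoglucanase redundancy — because the redundancy idea is functional, not
family-specific. Subfamily labels (`GH5_2`) collapse to the base family;
at this screen's resolution subfamilies share the base family's activity
class. A gene annotated with k families contributes one copy to each
(multi-domain genes therefore count toward several categories; exact
duplicates of a (genome, gene, family) triple are counted once). E-value /
coverage filtering of the annotations is assumed done upstream.

## Enterotyping

Samples are clustered on **Bray–Curtis dissimilarity of untransformed
relative abundances** with Partitioning Around Medoids; the number of
clusters is selected over k = 2–6 by the **Calinski–Harabasz index
computed from k-means on the Hellinger-transformed table** (square-root
abundances, Euclidean geometry), best of `n_init` (default 100) k-means
initializations per k. Mean silhouette width from the PAM solution is
reported for every k. These are deliberately two different spaces — the
final labels live in Bray–Curtis/PAM space while CH is a k-means/Euclidean
diagnostic — and this surprises users often enough to deserve emphasis
here. k is the CH argmax; a warning is emitted when the silhouette argmax
disagrees, and `low_support_` is set when the best silhouette is below
0.25, the conventional weak-structure threshold.

### PAM

No k-medoids implementation ships with the installed scientific stack, so
PAM is first-party. Small instances (C(n, k) ≤ 10,000 medoid sets) are
solved **exactly** by enumeration; larger instances use the classic
deterministic BUILD phase followed by best-improvement SWAP iterations.
The exact mode exists because single-swap descent provably stalls in local
optima even on 7-point instances, while exhaustive enumeration is
instantaneous at these sizes; at survey scale (hundreds of samples, small
k) BUILD+SWAP behaves as usual. Both paths are deterministic (ties broken
by smallest index), so a `seed` passed to `pam()` is accepted only for
interface symmetry.

### Stability and core taxa

Bootstrap stability resamples samples with replacement B times (default
500), reclusters each resampled dissimilarity matrix with PAM, matches
every original cluster to its maximum-Jaccard counterpart (Jaccard over
resample positions) and averages over resamples — the subsetting scheme of
the familiar `clusterboot` approach, without dissolution bookkeeping
beyond the mean Jaccard. Core taxa are species present (abundance
> 0.01%, i.e. > 1e-4 as a fraction) in strictly more than 70% of samples;
presence is evaluated per sample, and the mean abundance is reported so a
mean-based criterion can be applied post hoc. Abundance rows not summing
to 1 are renormalized with a warning rather than rejected.

### Group comparisons

`kw_dunn` runs the Kruskal–Wallis omnibus (tie-corrected, via scipy),
then Dunn's pairwise z-tests on pooled mean ranks with the tie correction
T = Σ(t³ − t)/(12(N − 1)), BH adjustment across pairs, and a compact
letter display (insert-and-absorb over the significance graph,
deterministic group ordering). Letters are driven by the BH-adjusted Dunn
p-values without gating on the omnibus; under a 3-group null this keeps
the any-unique-letter rate near 1–2%, comfortably below nominal.

## Barcode species assignment

A barcode's identity is the species with the highest classified read
fraction; that maximum fraction is its **purity**. The ≥ 50% retention
rule is read inclusively (purity exactly 0.50 is kept). Ties at the
maximum are resolved to the lexicographically smallest species id and
flagged — ties are rare in real read tables but must be deterministic.
Cells with fewer than 15 detected genes (UMI count > 0) are removed before
expression analysis; exactly 15 is kept. Reads unclassified at species
level are excluded from the purity denominator.

## Per-cell expression programs

Counts are log-normalized per cell: `ln(1 + 10_000 · count / total)`.

**Module scores** follow the binned-control convention: genes are ranked
by mean normalized expression across cells and cut into `nbin = 24`
equal-frequency bins (ties broken by feature id, so the binning is
deterministic); for each set gene, `ctrl = 100` control genes are sampled
from its bin excluding all set genes — without replacement when the bin is
large enough, with replacement otherwise — using a fixed seed (default 1);
the score is the per-cell mean over set genes minus the mean over all
sampled controls. Adding a constant to the whole expression layer cancels
exactly, and a fixed seed makes scores bit-reproducible.

The **O₂ score** is `module_score(O₂⁺) − module_score(O₂⁻)` with the
aerobic set {cyoA–D, sdhA–D, icd, sucA–D} and the anaerobic/fermentative
set {cydA/B/X, frdA–D, narG–J, nrfA, pflB, ldhA, adhE}. Each set must map
to at least three features of the matrix (feature ids carry
`GenomeID|GeneID` prefixes; symbols map by suffix, or through an explicit
symbol→feature table when the same symbol appears in several genomes —
unmapped symbols are reported). The score is z-standardized over all
scored cells pooled (population SD), not per sample. Swapping the two sets
negates the score exactly. The score is a *relative* descriptor of
respiration-associated vs fermentative transcriptional state, not an
oxygen concentration estimate.

The **rank score** is a UCell-style alternative: within each cell, genes
are ranked by expression descending (midranks on ties), ranks capped at
`r_max` (default 1500, configurable; the cap matters only when the feature
space is larger), and the score is
`1 − (Σ ranks − n(n+1)/2)/(n·r_max)` ∈ [0, 1]. It is invariant under any
strictly monotone per-cell transform, which makes it a useful robustness
companion to the binned-control score; its O₂⁺ − O₂⁻ contrast is expected
to correlate strongly (ρ ≥ 0.8 on planted data) with the module-score
version.

Cluster-level filters retain clusters with ≥ 100 cells observed in ≥ 2
samples (99 cells, or a single sample, drop). Marker genes are one-vs-rest
Wilcoxon rank-sum per gene with BH adjustment within cluster; the fold
change is log2 of mean expm1-expression with a 1e-9 pseudocount (the common
single-cell convention, flagged as such), and markers require
log2FC > 0.25 and adjusted P < 0.05. The LPMO contrast splits cells at
detectable (> 0) LPMO expression and compares scores by rank-sum (exact
null when both groups are ≤ 10 and untied). Correlation panels use
Spearman on pairwise-complete observations per pair, BH across the upper
triangle, distance `max(0, 1 − (ρ + ρᵀ)/2)` and average-linkage
clustering; constant columns have undefined ρ and are excluded from the
clustering greedily. Covariate diagnostics report Spearman of the z-score
against nFeature/nCount, OLS residualization on their logs, and the
Spearman correlation of cluster-mean orderings before vs after adjustment.
Cell cluster labels themselves are an input; a documented stand-in
(PCA + k-means, fixed seed) exists for synthetic tests only.

## Isolate assays

The DNS standard curve is an OLS fit of A₅₄₀ on glucose concentration
(design range 0.125–2 mg/ml, ≥ 3 points, positive slope required).
Released glucose is `(ΔA₅₄₀ − intercept)/slope × dilution`, floored at 0
with a below-blank flag. Residual CMC is `(m₁ − m₀)/recovery` with
negative results flagged; simple division by the recovery fraction is
used (a regression on spiked controls is a documented extension). No
standard enzyme unit is imposed: results are reported as glucose released
per assay, with conversion to µmol·min⁻¹·ml⁻¹ left to the caller's
incubation time.

**Paired signed-rank test**: zero differences are dropped (Wilcoxon's
reduce-n convention, reported); for n ≤ 25 the null distribution of W⁺ is
exact over all 2ⁿ sign assignments of the midranks, computed by
generating-function convolution (midranks doubled to integers, so ties are
handled exactly); beyond that, a normal approximation with continuity
correction and midrank-implicit tie correction. Two-sided p-values are
`min(1, 2·min(P(W ≤ w), P(W ≥ w)))`. The **rank-sum test** is exact
(Gaussian-binomial DP for the Mann–Whitney U distribution) when the
smaller sample is ≤ 10 and there are no cross-sample ties, tie-corrected
normal otherwise. The oxygen-gradient report runs all pairwise level
comparisons paired by strain, BH-adjusts across comparisons, and also
keeps unadjusted p-values since gradient assays are often reported
unadjusted. TPM is `(count/length)/Σ(count/length) × 10⁶`.

## Synthetic-data generators

The generators emulate the statistical structure the pipeline consumes;
they are first-class tested code, and every dataset ships with its planted
truth, which no pipeline stage reads.

* **Communities**: one dominant species per planted enterotype, its
  fraction drawn Beta(κf, κ(1−f)) around `dominant_frac` (default 0.45,
  within the 0.38–0.63 range of dominant-taxon medians seen in real
  enterotyped gut communities; κ = 60 keeps the draw concentrated), the
  rest split by a symmetric Dirichlet (concentration 0.5, giving the
  right-skewed background typical of species profiles). Default 3 clusters
  × 40 samples × 40 species — enough samples per cluster for k-selection
  to be well-posed, small enough to keep repeated runs cheap.
* **Barcodes**: per barcode, a majority species and a Beta(2, 1.5) purity
  (median ≈ 0.61, mass on both sides of the 0.5 threshold). Background
  species shares are Dirichlet draws capped at 0.9·(1−purity) per species
  with the excess redistributed, and reads are allocated by
  largest-remainder rounding. The cap plus deterministic rounding make two
  planted properties hold by construction: no background species can cross
  the 0.5 retention threshold or overtake the majority, so (i) the planted
  majority is exactly recoverable whenever planted purity > 0.5, and (ii)
  the kept fraction tracks the planted purity distribution. Multinomial
  read noise would break both near the boundary, which is why the
  allocation is deterministic; the cost is that read-count noise around
  the composition is not modeled.
* **UMI matrices**: negative-binomial counts (dispersion 0.3) on
  heterogeneous log-normal gene base rates and a per-cell log-normal
  library-size multiplier (σ = 0.35). Program genes are amplified by
  2^`effect_log2fc` in cells of the matching program. LPMO-like markers
  couple to aerobic membership through a latent Gaussian copula with
  target correlation `coexpression_rho` (default 0.6): the latent normal
  mixes the standardized program indicator with independent noise, and its
  normal CDF scales the markers' log2 amplification — an association
  model, deliberately mechanism-free. The default universe is one genome
  with the 13 aerobic markers, 15 anaerobic markers, 5 LPMO-like markers
  and 250 background genes.
* **CAZyme genomes**: Poisson copy counts per family at user rates; truth
  scores come from an independent plain restatement of the screening rules
  kept inside the simulator.
* **Assays**: per-strain random intercepts plus a deterministic oxygen
  effect profile (default: flat to 2%, step of +0.3 at 4%, mild gains to
  21%) and Gaussian noise — the paired, step-at-microoxic structure the
  gradient statistics must detect.

What the generators do **not** emulate: read-level errors and ambient
contamination, cross-genome symbol collisions, compositional coupling
between the community and barcode layers, batch effects, zero-inflation
beyond what the NB provides, and real CAZyme co-occurrence structure.
Passing recovery tests on these data therefore demonstrates correctness of
the implemented procedures under their stated models, not robustness to
every artifact of real sequencing data.

## Problem sizes and determinism

Recovery suites run at deliberately modest sizes chosen for statistical
power per unit time: 120-sample communities over 20 seeds for enterotype
recovery, 500 cells per program over 10 seeds for the O₂ score, 10,000
barcodes for purity calibration, 1000 replicates for the Dunn type-I
bound. All randomness flows through `numpy.random.default_rng` seeds;
clustering, binning and control sampling are seeded or deterministic, so
every reported number is bit-reproducible.

## Known limitations

* PAM's SWAP phase is best-improvement local search; optimality is
  guaranteed only in the enumeration regime (C(n, k) ≤ 10,000).
* The compact letter display is one of several valid minimal letterings;
  letters are stable given group order but not canonical across orderings.
* Module-score control sampling reproduces the standard binned-control
  scheme, not any specific external implementation's RNG stream; scores
  agree in distribution and ranking, not bitwise, with other tools.
* The exact rank-sum path requires untied pooled samples; midrank ties
  always route to the corrected normal approximation regardless of n.
* `EnterotypeModel` selects k by CH alone when CH and silhouette disagree;
  there is no composite index.
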