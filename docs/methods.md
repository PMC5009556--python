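# Methods

## Model and assumptions

`cogsyn` predicts the synergy of a drug pair from the *similarity of the two
drugs' single-agent perturbation signatures*. The underlying assumption is
that synergistic drugs reinforce each other by hitting the same biological
functions (gene sets) or the same genes within those functions; the method
cannot, by construction, detect synergy arising from complementary but
disjoint mechanisms, and it is known to be a poor predictor of antagonism.

Inputs are (a) a normalized genes × samples expression matrix in which each
treated sample is a single drug at one concentration and at least one column
is the DMSO vehicle control, (b) a gene-set collection (GMT), and (c) for
evaluation, a gold-standard table of per-pair mean excess over Bliss (EOB)
and its standard error. No microarray preprocessing is performed: the matrix
is assumed gene-level and normalized, and EOB values are taken as given
rather than re-derived from dose–response surfaces.

## Pipeline

1. **Delta z-scores.** Each gene is z-transformed across *all* samples
   (treated and control together) and the z-transformed control is
   subtracted. Using the global μ_j, σ_j means a strong treatment inflates
   σ_j and shrinks its own delta z-score slightly; this is inherent to the
   statistic. σ_j uses the n−1 (sample) denominator by default, with a
   population mode available; the z-transform makes the profile invariant to
   positive affine rescaling of a gene's row. Genes with σ_j = 0 are dropped
   (a z-score is undefined for them), rows with missing values are dropped,
   and duplicate gene rows are collapsed by their mean, each with a log
   message. When several control columns exist their z-transformed values
   are averaged before subtraction.
2. **Gene-level significance.** A gene is called significant when the
   two-sided standard-normal tail probability of its delta z-score is
   *strictly* below α (default 0.05, i.e. |Z| > 1.96). The default null
   variance is 1, treating the delta z-score itself as standard normal; a
   `null_variance=2` mode models it as the difference of two independent
   standard normals, which is the better-calibrated choice under a pure
   noise model (the variance-1 convention calls ≈17 % of null genes at
   α = 0.05, the variance-2 mode ≈5 %). The parametric-normal call is a
   design choice; with one array per (drug, concentration) no
   sample-permutation alternative exists.
3. **Gene-set redundancy clustering.** Cohen's kappa of the binary
   membership vectors is computed over the universe = (union of collection
   members) ∩ (study genes), fixed before clustering. Sets with κ ≥ 0.5
   (configurable) are joined by single-linkage connected components; each
   cluster keeps its largest bound set, ties broken by lexicographically
   smallest name, making the output independent of input order. The
   threshold and algorithm are package choices — simple, and verifiable
   against brute-force component enumeration. Clustering is performed
   jointly across the whole collection rather than within categories.
4. **Enrichment.** S_l is the mean delta z-score of the set's bound
   members. The permutation null shuffles gene labels of the z vector
   (equivalently: random gene sets of equal size); one batch of B shuffles
   is shared across all sets via running means, which leaves the null for
   each size exactly the distribution of a without-replacement draw.
   P-values are two-sided with the +1/(B+1) correction, so p ∈ [1/(B+1), 1]
   and p = 0 is impossible; numerically equal null and observed scores count
   as ties (tolerance 1e-9 relative). B defaults to 1000. BH adjustment is
   applied per profile across the collection. A set is *enriched* iff
   p_adj < 0.05 AND informative (|S_l| > 1.96/√N_l); the conjunction makes
   the filter order immaterial.
5. **Pair scores.** co-gene, co-GS and co-gene/GS as defined in the README.
   N_l in the co-gene/GS denominator is the set size bound to the study
   universe, consistent with the enrichment statistic. A pair with no
   co-enriched set scores 0 (the 0/0 case is defined as 0), ranking below
   any pair with overlap. With several concentrations per drug every
   instance pair is scored and the pair is represented by the most
   synergistic (maximum) instance per score column; a mean rule is
   available. Ranks are 1 = highest score with deterministic
   (drug_a, drug_b) tie-breaks, so each rank column is a permutation.
6. **Evaluation.** c-index counts concordant pair-of-pairs (ties 0.5);
   the PC-index replaces the 0/1 indicator by
   ½ ± ½·erf((EOB_q−EOB_r)/√(sem_q²+sem_r²)), which tends to the c-index as
   sems → 0 and satisfies PC(v) + PC(reverse v) = 1. PC_max/PC_min are the
   PC-index of the EOB-descending/ascending orders and define the
   normalized PC-index. Significance of a PC-index is the upper-tail
   fraction over B = 10,000 (configurable) permuted rankings with the
   +1/(B+1) correction. SNR classes: synergistic if EOB/sem > 2 and
   EOB > 0, antagonistic if |EOB/sem| > 2 and EOB < 0, else additive
   (strict inequalities). ROC curves sweep top-i calls in rank order
   (reversed order for antagonism) with trapezoidal AUC; zero-sem pairs
   with equal EOBs contribute 0.5 to the PC-index (logged).

## Synthetic data

The generator encodes the method's own hypothesis as ground truth: each
drug perturbs a window of gene sets, and a pair's "true" synergy is the
Jaccard overlap of the two windows. Passing the recovery tests therefore
shows the implementation can detect planted signature overlap — it says
nothing about whether real synergy follows the hypothesis.

Defaults (the package's reference design): 2,000 genes with an N(8, 2)
baseline, 100 gene sets of 15–25 uniformly drawn genes, 8 drugs, 20 sets
per drug assigned by a sliding window of step 8 (adjacent drugs share 12
sets, next-nearest 4, the rest 0 — a graded spectrum a ranking must
resolve), effect size δ = 2 delta-z units with a random ± sign per set
(overlapping shifts add), i.i.d. N(0, 1) sample noise, one control and one
concentration per drug (two reproduce the paired-dose layout), B = 200
permutations. The gold standard sets EOB = 10 × Jaccard + N(0, 0.5) with
sem reported as the noise sd (single-draw convention). Not emulated:
gene–gene co-expression, probe/batch effects, dose–response shape, and any
real biology of EOB; simulated noise is i.i.d., so permutation nulls are
exactly calibrated here and only approximately so on correlated real data.

Under this design the co-gene/GS ranking attains Spearman ≥ 0.7 against the
planted overlap ordering with PC-index permutation p < 0.05 on every tested
seed, and under δ = 0 the FDR-adjusted set-level false-positive fraction
stays below the nominal 5 %.

## Numerical choices and degenerate inputs

- Strict inequalities throughout (p < α, |S| > band, SNR > 2), so boundary
  values do not reject.
- Degenerate kappa (p_e = 1): 1 for identical sets, else 0, logged.
- `normalize_pc` raises on pc_max = pc_min (degenerate gold standard);
  c-index requires n ≥ 2; ROC requires both classes present.
- All randomness flows from one seed; per-profile generators are spawned
  from it deterministically (`numpy` SeedSequence), so results are
  independent of sample iteration order and byte-identical across reruns.
- Permutation-free quantities (co-gene scores, kappa clustering) are fully
  deterministic; only enrichment flags near the FDR threshold can flip
  between seeds.

## Problem sizes

The test suite and the acceptance script run the reference design (2,000
genes × 100 sets × 8 drugs, B = 200) and smaller fixtures; a full-scale
screen (thousands of profiles, B = 1000, 5,000+ sets) uses the same code
paths and scales linearly in profiles × permutations × genes.

## Known limitations

- The enrichment statistic is an unweighted mean: gene-gene topology and
  the direction of change are ignored, and up/down agreement between drugs
  is not required for a gene or set to count as shared (directional
  refinement is a natural extension).
- Antagonism prediction is weak by design — shared-signature similarity is
  a synergy hypothesis.
- The kappa threshold (0.5) and representative rule are conventions, not
  fitted quantities; clustering depends on the study universe and is
  re-done per study.
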