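# Methods

`raredx` re-implements, as a tested and fully synthetic-data-exercisable
pipeline, the computational analyses used in national-scale exome-sequencing
programs for ultrarare disorders: phenotype encoding and embedding,
diagnostic-yield prediction, multimodal phenotype-driven gene prioritization,
candidate-gene evidence scoring and cohort-level genetic-architecture
statistics. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic generators do and do not emulate.

## Phenotype ontology and similarity

Phenotypes are sets of terms from a DAG-structured ontology (HPO-style).
Information content is corpus-based: `ic(t) = -ln(n_t / N)` where `n_t`
counts corpus entities annotated to `t` or any descendant (annotations
propagate to ancestors). The corpus defaults to the gene/disease annotation
catalog plus, when available, the cohort's own term sets; it is configurable.
Terms annotating no corpus entity have undefined IC and are assigned the
maximum observed IC (flagged on the index) so downstream similarities stay
finite.

Pairwise term similarity is Resnik's measure, the IC of the most informative
common ancestor; set-to-set similarity is the symmetric best-match average
(for each term the best match in the other set, the two directional means
averaged). The upstream tooling this emulates does not pin down a similarity
configuration, so Resnik + symmetric BMA was fixed as the deterministic,
oracle-testable default; Lin or Jiang–Conrath variants would be drop-in
replacements but are not shipped.

Group assignment maps each patient to 49 curated phenotype subcategories and
12 higher-order groups: an indicator is set iff at least one patient term
maps to the subcategory. Terms missing from the curated table are assigned
via their nearest mapped ancestor (breadth-first upward, lexicographic
tie-break) so that terms newer than the table do not silently drop patients;
exact-match behaviour is available with `use_closure=False`. Obsolete terms
are excluded at parse time and `alt_id`s resolve to primary ids. Structural
defects — cycles, references to undeclared parents, zero or multiple roots —
are hard errors.

## Phenotype space

Patients and reference diseases are treated uniformly as term-annotated
entities. The pairwise similarity matrix is converted to a dissimilarity by
`D = max(S) - S` (the alternative `1/(1+S)` is available), the diagonal is
forced to zero, and the entities are embedded in four dimensions with UMAP on
the precomputed distances (`n_neighbors = 15` clamped to `n - 1`,
`min_dist = 0.1`, fixed seed; all recorded in the result object together with
a SHA-256 of the distance matrix). Only the first two dimensions are normally
plotted; all four are exported because downstream consumers may use them.

Reproducibility caveat: umap-learn's spectral-initialization failure fallback
is not seed-reproducible on tie-heavy distance matrices (many identical term
sets). `embed()` detects the failure warning and refits with the seeded
random initialization, restoring byte-identical runs at a fixed seed. For
very small inputs (n ≤ dims + 2) random initialization is used directly
because spectral initialization needs `dims + 1` eigenvectors.

## Diagnostic-yield model

Solved status is regressed on the 49 subcategory indicators with an L1
penalty; age class, sex, sequencing-site one-hots (first level dropped) and
the image-analysis consent flag enter unpenalized, so variable selection acts
on the phenotype groups only. The objective is

    -(1/n) loglik(beta) + lambda * sum_j w_j |beta_j|

with `w_j = 1` on the penalized block, `0` elsewhere. The solver is proximal
Newton: an IRLS outer loop (working weights floored at 1e-5) around cyclic
coordinate descent with active-set cycling, warm-started along a descending
grid of 100 log-spaced lambdas from `lambda_max` (computed from the KKT
conditions at the confounder-only fit, inflated by 1e-6 so the first grid
point is exactly the all-zero penalized solution) down to `1e-3 lambda_max`.
Convergence is declared at a relative objective change below 1e-9
(comfortably inside the 1e-7 contract); KKT violations along the path stay
below ~1e-9 in practice. Complete separation is detected either by runaway
coefficients or by every case sitting on the correct side with margin > 10;
the path is then truncated and flagged. Binary indicators are left
unstandardized so coefficients stay interpretable on the log-odds scale.

Lambda is tuned by stratified tenfold cross-validation on out-of-fold
binomial deviance (plain k-fold when k = n, i.e. leave-one-out). Two
selection rules are provided: minimum mean deviance (the default, prediction-
optimal) and the one-standard-error rule (`rule="1se"`, the standard choice
when the goal is support recovery, since the min-deviance lasso deliberately
trades false positives for predictive accuracy). On planted models with
independent indicators (8 of 49 effects, |beta| = 1, n = 2,000), the 1-SE
rule recovers the support essentially perfectly (F1 ≈ 1.0 across seeds) while
the min rule admits 10–20 correlated noise features (F1 ≈ 0.55). On cohorts
from the synthetic generator, whose indicators are correlated within
higher-order groups by construction, recovery degrades (1-SE F1 ≈ 0.75–0.8);
this is a known property of the lasso under correlated designs, not a solver
defect, and it is why the recovery benchmark uses the planted independent
design.

Prediction imputes any unsupplied confounder — and any site level unseen in
training — with the training-cohort mean of the corresponding design column.
Evaluation uses the ROC AUC as the tie-corrected Mann–Whitney statistic with
a case-level percentile bootstrap (B = 2,000). The discriminatory AUC of a
single binary term indicator uses the closed form
`(sensitivity + specificity) / 2`. Coefficient paths are exported for
penalized features that are nonzero in the selected model and had training
prevalence ≥ 5%. A convenience splitter reproduces the reference cohort
shape: 1,577 cases at the published ratio give 1,256 training and 321 test
cases.

## Multimodal gene prioritization

Three per-gene evidence channels over a fixed vocabulary (816 disease genes
by default):

* **Gestalt.** Each imaged patient carries 12 unit-norm 512-dimensional
  facial phenotype descriptors (model ensemble + test-time augmentation).
  The distance between two patients is the mean of the 12 *index-matched*
  cosine distances (12 pairs, not 144; the pairing is part of the published
  protocol). A gene's score is `1 - min` distance over that gene's gallery
  patients (max-similarity aggregation; mean-of-top-m is available).
* **Molecular.** Variants are filtered at allele frequency ≤ 0.01
  (configurable) and each gene takes the maximum remaining deleteriousness
  score.
* **Feature.** Best-match-average similarity of the patient's terms against
  each gene's phenotype annotations; externally computed scores can be
  plugged in instead.

Each channel is min–max normalized to [0, 1] within a patient; missing
scores become 0 *after* normalization, so absent evidence is a neutral floor
that can never rank a gene below a no-evidence gene; a constant channel
normalizes to 0. The fused score is an equal-weight sum by default — the
originally published combiner is a trained model whose formula is not
reproducible here, so the combiner is an explicit plug point. Ranking is by
descending fused score with ties assigned the worst rank of the tie group
(conservative: a tied causal gene is counted as if it ranked last among its
ties). Benchmarks report top-k accuracy with case-level percentile-bootstrap
CIs (B = 1,000); causal genes outside the vocabulary count as never hit and
are flagged.

## Candidate-gene evidence score

Candidates must pass four mandatory criteria (no prior robust disease
association; no alternative causative explanation; allele frequency below the
cutoff or absent in controls; inheritance consistent with the family).
Eligible candidates are graded with nine weighted criteria to a maximum of 8
for autosomal dominant candidates. Three criteria — confirmed de novo status
and the two gnomAD constraint metrics — apply only under AD inheritance and
contribute nothing for recessive candidates; X-linked candidates are scored
with the recessive mask. Classification: AD high ≥ 4, medium 1–3 (0 is
flagged); AR/XL high ≥ 3, medium below.

The per-criterion weights are configuration data, not code. Nine strictly
positive integers cannot sum to 8, so the shipped default assigns weight 1 to
the eight actionable criteria and records the ninth (animal-model support)
unscored at weight 0; any replacement table with the same columns loads
without code changes, and the loader validates that the AD maximum equals 8.
The 57-candidate table used in the class-partition check is a synthetic
stand-in generated from the published class counts (34 high / 23 medium);
the real per-candidate criterion table is not distributable.

## Cohort statistics

Yields are compared with two-sided Fisher exact tests over all pairwise 2×2
tables, Bonferroni-corrected over the number of pairwise tests. The MOI
spectrum is computed over diagnoses (dual diagnoses count twice). Cases split
into autozygosity strata at 2% (high is strictly greater; cases exactly at
the threshold are low). The recessive burden statistic is

    R = (AR / de novo)_high / (AR / de novo)_low

on MOI fractions, with AR = homozygous + compound-heterozygous; the de novo
rate is the normalizer because de novo mutation counts depend on parental
age, not autozygosity. Carrier-screening amenability of a recessive
diagnosis: homozygous variants qualify if archive-classified P/LP or
predicted loss-of-function without predicted NMD escape; compound
heterozygotes require *both* variants individually P/LP (the strict reading
of the published rule; an OR-variant accepting the LoF rule per variant is
available by flag). Archive classes are inputs frozen at a reference date,
never live lookups.

Disease genes rank by descending P/LP submission count (secondary-findings
genes excluded first); each gene spans an interval of the cumulative
submission fraction and is assigned to the quartile containing its interval
midpoint, with boundary midpoints falling to the lower quartile — a single
gene holding all submissions therefore lands in Q2, which is flagged as a
degenerate case. Year-of-first-association distributions are compared with
the two-sample two-sided Kolmogorov–Smirnov test; decade-style histograms are
provided for reporting.

Percent formatting follows the cohort-reporting convention: one decimal below
5%, integers otherwise.

## Synthetic data

The generators define the study conditions; their defaults are anchored to
the reference cohort: 1,577 cases, target yield 32%, mean five phenotype
terms per case, consanguinity 144/1,577 (autozygosity 0.021 + Exp(0.03) for
consanguineous cases, U(0, 0.015) otherwise, so the 2% threshold separates
them cleanly), image-analysis consent 224/1,577, dual diagnoses 11/499 of
solved, parental mosaicism 3/228 of de novo diagnoses, novel-gene rate 12%,
targeted therapy 1% of solved, and a low-stratum MOI composition of
AD 0.15 / de novo 0.50 / AR-hom 0.03 / AR-comp-het 0.17 / XL 0.12 / mt 0.03.
Only the de novo and homozygous percentages of the stratum compositions are
published; the remaining masses were fixed once so that the high-stratum
composition is derived from the low one by multiplying the combined recessive
odds against de novo by an explicit `recessive_multiplier` (default 7,
matching the published sevenfold burden) and shifting the recessive mass
toward homozygous diagnoses (`hom_share_high = 0.9`). The ratio R is then
exactly the multiplier in expectation.

The ontology generator builds a single-rooted random DAG hosting 12
higher-group anchors and 49 subcategory anchors (capacity-checked against the
branching factor), fills subtrees with terms (occasional second parent inside
the same subtree keeps the subcategory mapping single-valued), and draws
per-gene annotation sets from a home subcategory. Solved status follows a
planted logistic model on the subcategory indicators with the intercept
calibrated by bisection to the target yield. Facial descriptors are Gaussian
perturbations of a per-gene latent unit center, renormalized — a cheap
stand-in for a von Mises–Fisher draw that is adequate for ranking tests.
Variant tables give every vocabulary gene one variant with a controlled
common-allele-frequency fraction (0.3), and the causal gene an extra rare
variant with a boosted score when the molecular channel is informative. In
the no-information configuration the causal gene is drawn uniformly,
descriptors come from an unrelated center, no molecular boost is added, and
the gallery's gene composition is drawn independently of the benchmark's
causal genes — without that last point the benchmark would be biased because
gallery genes dominate the top ranks after normalization.

What the generators do *not* emulate: real HPO depth and annotation
redundancy, inter-site phenotyping style differences, realistic variant-level
allele-frequency spectra, facial-descriptor geometry of a trained CNN, and
archive submission dynamics beyond a Zipf(1.5) tail with recency-skewed
years. Passing tests therefore demonstrate correctness of the statistical
machinery under the planted structure, not real-data performance; the
published real-cohort figures (AUC 0.67/0.72, top-10 82%/83%) require the
original, non-shareable data and trained image models and are out of scope.

## Problem sizes used in the test suite

Monte-Carlo checks run at the smallest sizes that keep the bands meaningful:
support recovery at n = 2,000 × 10 seeds; burden recovery at n = 5,000 × 10
seeds with stratum compositions pooled across seeds before forming R (a
single seed yields only ~190 high-stratum diagnoses, so per-seed R has
Monte-Carlo spread of roughly ±2 around 7; pooling is the natural
multi-replicate estimator); prioritization comparisons at 25 benchmark cases
× 10 seeds and a 200-case null; UMAP checks at 20–40 entities. Every
generator and every stochastic procedure is seeded, and all reported numbers
are recomputed at run time.
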