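# Methods

This note records the models the package implements, the assumptions
behind them, the defaults and why they were chosen, and what the
synthetic-data tests do and do not demonstrate about real data.

## Labeling kinetics

**Model.** During a heavy-amino-acid pulse, a peptide's relative isotope
abundance RIA(t) = H/(H+L) rises from 0 toward a plateau. Per protein,
all peptide points (peptides grouped by leading razor protein, evidence
rows for one peptide at one time point intensity-summed before the ratio)
are pooled into one nonlinear least-squares fit of

    RIA(t) = A · (1 − exp(−k t)),   k ≥ 0,  0 < A ≤ 1.

The free plateau A absorbs incomplete labeling (pre-existing light
protein, incomplete precursor-pool enrichment). Only peptides quantified
at ≥3 of the 4 collection times (1, 2, 6, 24 h) enter a fit.

**Identifiability and model selection.** Far from plateau (k·t ≪ 1 at
every observed t), RIA ≈ A·k·t: the data determine only the product A·k,
and a free-plateau fit can wander along this ridge, trading a small A for
a large k. Because the classification statistic is k itself, that ridge
can push a slow-labeling protein across the cutoff. The package therefore
fits both the pure first-order form (A fixed at 1) and the free-plateau
form, each from five deterministic restarts around a log-linear initial
rate (k₀ from regressing −log(1 − RIA/Â) on t, Â = max observed RIA;
restart multipliers 0.2×–5×; bounds k ∈ [10⁻⁶, 10] h⁻¹, A ∈ [10⁻³, 1]),
and keeps the free plateau only when a partial F-test at α = 0.05 says it
significantly improves the fit. RSS ties between restarts break toward
the smaller k — on the ridge, the smaller rate is the conservative
representative. Optimizer tolerances are set to 10⁻¹³ so that noiseless
model-generated data are recovered to ~10⁻¹³ relative error. Degenerate
inputs (all-zero RIA, <3 distinct time points, no converged restart)
yield an unclassified protein with a reason, never an exception.

**Classification and flux.** A protein is secreted iff k strictly
exceeds the cutoff (default 0.01 h⁻¹); the boundary value goes to the
intracellular class, keeping the secreted call conservative. Flux is
P × k with P the difference in mean total peptide abundance (H+L)
between the 24 h and 6 h collections; units are intensity·h⁻¹. Negative
P (abundance loss) is retained in tables but excluded from log-flux
displays, never sign-flipped. A missing 6 h or 24 h collection leaves
flux undefined while the protein remains classifiable by k.

## Enrichment validation

Secreted and intracellular subsets are tested for GO cellular-component
over-representation against the full identified background using the
one-sided hypergeometric tail P(X ≥ k), with Benjamini–Hochberg step-up
adjustment across tested terms (per namespace when the annotation table
carries one). Only terms annotating ≥1 background protein are tested. No
GO-graph ancestor propagation is performed — a protein counts toward
exactly the terms it is directly annotated with — so results with
propagated annotation files will differ from results with leaf-only
files; the choice is deliberate and keeps the test family explicit.
Annotation is user-supplied data (two-column TSV), not a bundled
database.

## Label-free workflow

- **Missingness filter:** proteins missing in *more than* 30% of samples
  are removed (a protein at exactly 30% stays).
- **Imputation modes:** `none` = complete-case (drop any protein with a
  missing value); `protein` = observed row mean; `sample` = seeded draws
  from Normal(μ_s − 1.8σ_s, 0.3σ_s) in log2 space of each sample's
  observed values, back-transformed — the widely used down-shifted
  low-abundance rule for values missing because they fell below
  detection. The down-shift (1.8 SD) and width (0.3 SD) are the common
  tooling defaults, exposed as parameters.
- **PCA** runs on log2-transformed, per-protein standardized values;
  variance fractions sum to 1.
- **Age-ordered profiles:** duplicated samples (same tissue, sex, age)
  are averaged, columns ordered by ascending age, rows standardized to
  mean 0, SD 1 (sample SD, ddof = 1; constant rows dropped with a
  warning). Age bins are half-open [0,5), [5,10), …, left edge at 0; a
  warning flags bins with <3 samples.
- **Fuzzy c-means** (default 16 clusters, fuzzifier 2.0) alternates
  centroid/membership updates to tolerance 10⁻⁶ (max 1000 iterations);
  memberships sum to 1 per protein; initialisation is seeded.
- **DTW clustering** (default 8 clusters) is k-medoids under the classic
  dynamic-programming DTW with symmetric steps, no window constraint,
  squared local cost (absolute available); seeded medoid initialisation.
- **NMF consensus:** per rank in 2..6, 30 random-start factorizations by
  Lee–Seung multiplicative updates (Frobenius objective, ≤2000
  iterations, relative-change tolerance 10⁻⁶); samples hard-assigned by
  argmax coefficient; the consensus matrix is the co-assignment
  frequency, summarised by the cophenetic correlation of its
  average-linkage dendrogram; the recommended rank maximises the
  cophenetic coefficient (smallest rank on ties; an all-identical
  consensus is trivially perfect and scored 1). Rank-stability via
  plain-NMF consensus stands in for the non-smooth NMF variant: stability,
  not the smoothing matrix, is the rank-selection criterion. NMF input is
  raw LFQ scaled to unit total per sample (non-negativity is required);
  the other analyses use log2 intensities.
- Every stochastic step takes an explicit seed; the package default
  is 17 and each pipeline run records its seed and config hash in the
  manifest.

## Donor-effect models

Per-protein Gamma GLM with log link: abundance is positive and
right-skewed, and the log link makes coefficients scale-free (a global
intensity rescaling moves only the intercept) and directly
interpretable as log fold changes. Predictor coding: age continuous in
years (uncentered), sex reference F, tissue reference ASC — so β_tissue
is BMSC relative to ASC, matching the log2 fold-change orientation
(BMSC/ASC mean ratio, M/F for sex). Dispersion is estimated by the
Pearson statistic; Wald tests use the t reference with n − p degrees of
freedom (computed explicitly; the IRLS default normal reference is
slightly anticonservative at n = 30). Samples missing a protein's value
are excluded for that protein only and the per-protein n is reported. BH
adjustment is applied per predictor across proteins. Reported tiers:
p < .05 nominal, q < 0.05 confirmed, q < 0.2 suggestive. A constant
response is handled as its MLE limit (intercept-only exact fit, zero
slopes, undefined p-values); <p+2 complete cases or IRLS breakdown yield
a flagged, unconverged result.

The activity assay is modelled as a Gaussian random-intercept model,
response ~ time + age + time×age + (1|donor), fitted by maximum
likelihood; when the random-intercept variance estimate is effectively
zero the model is refitted by OLS (to which it degenerates) with a
warning. Both the per-read model and the per-donor late-minus-early
delta summary are produced. The immunoassay concentration uses the same
Gamma-GLM machinery on age, sex and tissue.

## Synthetic-data generator

The generator emulates the *structure* the analysis assumes, with known
truth per protein, fully determined by (config, seed).

- **Labeling evidence** (defaults: 200 proteins, 4 peptides each,
  collections at 1/2/6/24 h): two pools with disjoint rate ranges
  straddling the 0.01 h⁻¹ cutoff — secreted k ~ U[0.05, 1.0] h⁻¹,
  intracellular k ~ U[0.0005, 0.005] h⁻¹ — plateau A ~ U[0.7, 1.0],
  secreted fraction 0.66 (roughly the two-thirds split a classified CM
  proteome shows). Secreted total abundance accumulates linearly in the
  medium (constant secretion into a fixed volume); the intracellular
  leak is near-flat. Multiplicative lognormal noise (default CV 20%) is
  applied independently to H and L; peptide response factors are
  lognormal (σ = 0.5); per-point dropout is configurable.
- **LFQ cohort** (defaults: 30 donors — 16 adipose-derived, 14 bone
  marrow-derived, near-balanced sexes, ages evenly spanning 1.5–24
  years): abundance ~ Gamma(shape 20, i.e. ~22% CV) with log-mean
  carrying planted tissue offsets, per-year age slopes and sex offsets
  on disjoint protein blocks. Default missingness is MCAR at 3% per
  cell: over 30 samples this leaves (0.97)³⁰ ≈ 44% of proteins
  complete-case, matching the fraction a real cohort of this design
  retains; at 10% per cell almost no protein is complete in all 30
  samples and a complete-case analysis would be vacuous. Proteins
  forced above the 30% missingness threshold can be planted to exercise
  the filter.
- **Assays:** activity reads at 10/20/30/40 min for 27 donors with
  per-donor random intercepts (SD 3), residual SD 5, and fixed effects
  (time 2, age 0.5, time×age −0.05 per minute·year); concentrations for
  24 donors as Gamma (shape 20) with a log-scale age slope of 0.08 per
  year.

**What passing tests show — and don't.** The generator's peptides are
exchangeable draws around a protein mean; real peptides share systematic
ionisation differences, missed cleavages and isotope-impurity structure.
Missingness in the LFQ simulator is (optionally abundance-targeted but
by default) completely at random; real LFQ missingness is largely
left-censored. Closed-loop success therefore demonstrates correctness of
the estimators under their stated model, and the calibration/FDR numbers
transfer to real data only insofar as the Gamma/MCAR working assumptions
hold.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run at the study's design
sizes: 200 proteins for kinetic classification, 30 donors × 69 proteins
with 10 planted effects for FDR control (200 replicates), 1000 null
replicates for type-I calibration, 27 donors × 4 reads × 100 replicates
for the mixed model, 40 × 20 planted-block matrices for NMF stability,
and 60 profiles for the time-course clustering checks. The enrichment
oracle enumerates every (N ≤ 12, K, n, k) combination.

## Known limitations

- Protein inference stops at the leading razor assignment made upstream;
  no isotope-impurity or missed-cleavage correction.
- The kinetic model assumes a single well-mixed precursor pool reaching
  a protein-specific plateau; biphasic labeling is not modelled.
- GO analysis does not propagate annotations up the DAG.
- No batch correction or outlier-sample handling beyond the missingness
  filter; normalisation is whatever the upstream LFQ produced.
- The mixed model supports a random intercept only; random slopes in
  time are not implemented.
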