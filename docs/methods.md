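# Methods

`mmresponse` re-implements, as a reusable and tested pipeline, a
baseline-genomics analysis of response to triplet induction therapy in
multiple myeloma: given pre-treatment expression profiles and copy-number
calls of a cohort graded into ordinal response categories (CR, nCR, VGPR,
PR, SD), it (i) discovers a low-dimensional probe signature predicting
complete response with a probe-pair quadratic-discriminant algorithm,
(ii) profiles differential expression between response groups,
(iii) compares region-level copy-number-alteration (CNA) frequencies
between groups with exact tests, and (iv) tests whether recurrent CNAs
depress the expression of the genes they cover. A synthetic cohort
generator with recorded ground truth makes every stage testable without
any external data.

## Quantile normalization

Samples are forced onto a common reference distribution — the row-wise mean
of the column-sorted matrix. Ties receive the mean of the reference values
over their tied rank positions (the common convention). The operation acts
on log2 intensities as loaded; upstream summarization is assumed to have
produced log2 values already, and the matrix is never re-logged. The
normalization is idempotent and equivariant under sample permutation, and
both properties are asserted by tests.

## Differential expression

For a binary contrast the per-probe fold change is the difference of group
means on the log2 scale (positive minus negative group) and the p-value
comes from the two-sided Welch unequal-variance t-test (pooled-variance
Student t selectable). Probes with zero variance in both groups get p = 1
when the means agree and p = 0 otherwise. The significance filter uses the
raw p < 0.05 (standard for this cohort scale in the microarray literature);
Benjamini–Hochberg q-values are computed and reported alongside but do not
gate the filter. An optional user-supplied gene list stands in for a
disease-focused annotation filter. Positional summaries count unique gene
symbols per chromosome, with unannotated genes pooled under `NA`.

## Signature discovery

### The discriminant

For class k ∈ {neg, pos} with mean μ_k, covariance Σ_k and prior π_k, the
discriminant is

    g_k(x) = ln π_k − ½ ln det Σ_k − ½ (x − μ_k)ᵀ Σ_k⁻¹ (x − μ_k)

and a sample is called positive when g_pos(x) ≥ g_neg(x) (exact ties go to
the positive class so every run is deterministic). The class covariance is
the sample covariance regularized as Σ_k + λ·(tr Σ_k / d)·I with λ = 1e-6
doubled until the matrix is positive-definite; if λ would exceed 1e-2 the
fit aborts as irreparably singular. Each class must contribute at least
d + 1 samples for d features.

**Priors are equal (½/½) by default.** With a 15-vs-103 class split,
empirical priors shift the decision threshold by ln(103/15) ≈ 1.9 and the
minority class is essentially never called: sensitivity collapses while
plain accuracy rises to the majority rate. Equal priors keep the classifier
a detector of the minority phenotype. Empirical priors remain selectable.

### Couple ranking

Every unordered probe couple is scored by leave-one-out cross-validation:
each sample is predicted by a discriminant fit on the remaining n − 1, and
the pooled confusion is summarized by a ranking score — balanced accuracy
(sensitivity + specificity)/2 by default, plain accuracy selectable. The
LOO loop is implemented by closed-form downdates of the held-out sample's
class mean and covariance (and, for the all-pairs scan, by a fully
vectorized 2×2 closed form); tests hold both fast paths exactly equal to
the literal refit-per-fold computation. Ranking order is deterministic:
score descending, then lexicographic probe pairs.

At desk scale an optional univariate screen keeps only the top m probes by
Welch p before pair enumeration; it is applied automatically above 2000
probes (m = 200) and can be set explicitly or disabled.

### From couples to candidate signatures

The top-k couples form a graph (probes as nodes, couples as edges). The
exact rule that turns such a network into a signature is genuinely open —
components, cliques and hubs are all defensible — so several labelled
variants are generated and the selection step arbitrates:

* **component** — the node set of each connected component of the full
  top-k graph; components above `max_size` are reduced by greedy growth
  from their best edge (*component-reduced*);
* **component@k** — components of every prefix graph built from the top
  1..k couples; tight clusters around the strongest couples that the full
  graph may have merged into one blob;
* **greedy** — from each component's best couple, repeatedly add the
  neighboring probe with the largest LOO-score improvement; stop at no
  improvement or `max_size`;
* **hub-n** — the n highest-degree probes of the top-k graph, n =
  2..`max_size`; a truly informative probe pairs well with many partners
  and recurs across top couples, while a noise probe that lifts one couple
  by chance rarely recurs.

The best candidate by LOO ranking score is selected; ties go to the smaller
signature, then the lexicographically earlier probe tuple.

Simulation with planted signatures showed why the variant pool matters: the
winner's curse of selecting among tens of thousands of couples on 15
positive samples systematically favors noise-admixed candidates, and
components plus greedy growth alone recover ≥3 of 5 planted probes in well
under half of cohorts. The prefix-ladder and hub variants raise recovery to
~84% at the desk-scale settings below without touching the generator.

### Desk-scale end-to-end settings

The acceptance runs (and the worked example) use: `prefilter_m=25`,
`top_k=25`, `max_size=8`, `metric="accuracy"`. Rationale: with 15
positives a 3-fold training fold holds 10 of them, so the discriminant
dimension must stay ≤ 9 (`max_size=8` leaves a margin); plain accuracy
pools all 118 samples and is ~3× less noisy than balanced accuracy, whose
sensitivity term rests on 15 samples, which measurably worsens the
selection winner's curse; and the tight univariate screen concentrates the
couple graph on probes with real marginal signal. Library defaults for the
individual operations remain the more conservative `top_k=50`,
`max_size=10`, balanced accuracy.

### Evaluation

A fixed signature is summarized by repeated k-fold cross-validation
(k = 3, 1000 repeats by default, stratified by class — an unstratified
3-fold split of 15 positives can produce positive-free test folds). Each
repeat pools its k test folds into one confusion table and reports
accuracy, sensitivity, specificity, PPV and NPV; a repeat with a zero
denominator records that metric as undefined (NaN) and is excluded from
that metric's median and range. Because the signature is selected on the
same cohort, these in-sample CV numbers retain selection optimism; see
*Null calibration* below.

### Cross-cohort application

To apply a signature to another platform, every probe of each matrix is
standardized (mean 0, sd 1 across its own samples), signature genes are
rebuilt as the mean of their mapped standardized probes, and the
discriminant trained in this standardized space predicts the external
samples. A signature gene with no mapped probe is an error that names the
gene. Standardization absorbs platform location/scale differences but not
probe-level affinity differences; external-validation numbers are expected
to degrade accordingly.

## CNA cohort comparison

Per event type (gain / loss / LOH), the genome is cut at the union of all
segment endpoints; the resulting atomic regions are covered either fully or
not at all by any segment, so per-sample presence is unambiguous. For each
atomic region the two groups' carrier frequencies are compared with a
two-sided Fisher exact test using the probability-mass rule: the p-value
sums the hypergeometric probabilities of all tables with the observed
margins that are no more probable than the observed table (relative slack
1e-7 on the comparison), computed in floating point via log-gamma. This
rule — not the tail-doubling rule — reproduces the published per-region
p-values this package's tests pin down. Benjamini–Hochberg q-values are
computed jointly across all event types by default (per-type selectable).
Group denominators are the samples of each group that have call data.

Two named filter presets select significant regions:
`broad` (p < 0.05 and ≥ 25 percentage-point frequency differential) and
`stringent` (p < 0.01 and ≥ 10 points). Both are implemented verbatim even
though their nesting is not monotone (a region can pass one and not the
other in either direction).

## CNA–expression integration

For a significant region, carriers in the positive group are contrasted
against non-carriers in the negative group over the probes whose annotated
interval overlaps the region (1-based inclusive overlap). Each side needs
at least two samples; samples in neither contrast group are ignored.
Deregulation is summarized as the fraction of covered genes moving in the
dosage-consistent direction and, of those, the fraction significant —
counted over unique gene symbols by default (a gene counts if any of its
probes does), probe-level selectable.

## The synthetic world

The generator emulates the data structure the analysis assumes, not
microarray physics. Defaults state the cohort the pipeline targets:

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 118 | cohort size |
| `class_proportions` | CR .127, nCR .118, VGPR .339, PR .356, SD .059 | published category rates (sum .999 from rounding; renormalized) |
| `n_probes` | 5000 | matrix height (tests and acceptance use 300) |
| `n_informative` | 5 | planted signature size |
| `mean_shift` | 1.0 log2 units | per-probe CR-class mean displacement, signs alternating +,−,+,… so both up- and down-regulated members exist |
| `within_class_sd` | 1.0 log2 units | shared within-class sd |
| `class_cov_distortion` | 0.5 | equicorrelation of informative probes in the CR class (0 = background law) |
| `baseline_range` | [4, 14] log2 | per-probe baseline, uniform |
| `cna_regions` | one loss (carrier 0.60 CR / 0.19 other, 16 member genes), one gain (0.467 / 0.111, 1 gene) | planted regions mirroring the most CR-associated published events |
| `dosage_effect` | 0.8 log2 units | expression drop per deleted copy in carriers; losses only by default (gains/LOH observed not to move expression) |

Category counts come from deterministic largest-remainder rounding — the
defaults yield exactly 15/14/40/42/7 — with order shuffled by seed. Each
operation draws from its own fixed-key substream of the seed, so outputs
are bit-identical given (config, seed) even when ops are called
independently. The truth record keeps the planted probe ids, the true class
laws, per-sample carrier status, the gene→probe map, and a Monte-Carlo
estimate of the Bayes accuracy of the true equal-prior discriminant (10^5
fresh points, half per class).

What the generator does **not** emulate: probe-level hybridization effects,
background-probe correlation structure, batch effects, real genomic
coordinates or gene density, subclonal CNA fractions, and missing data. A
green parameter-recovery test therefore establishes that the algorithm
recovers planted multivariate Gaussian structure at realistic sample sizes
— not that it would recover biology from a real cohort.

## Null calibration

On effect-free cohorts (zero shift, zero covariance distortion) the
discovery pipeline still produces a signature whose *in-cohort* repeated-CV
balanced accuracy is far above chance (≈ 0.76 median at 300 probes):
selection among ~45k couples on 118 samples is optimism that re-evaluating
on the same data cannot remove — the same caveat applies to any in-cohort
headline number this method reports. The package's null-calibration test
therefore evaluates the selected signature on an independent cohort drawn
from the same null generator, where its median CV balanced accuracy is
≈ 0.49, squarely at chance: the pipeline does not hallucinate
*transportable* signal.

## Numerical choices

* Discriminant ties → positive class; signature-score ties → smaller, then
  lexicographic; pair ordering → score desc, then lexicographic.
* Covariance regularization λ = 1e-6, doubled until positive-definite,
  error beyond 1e-2.
* Fisher probability-mass comparison uses 1e-7 relative slack so equal-mass
  tables are included despite floating-point log-gamma rounding.
* BH q-values via statsmodels; Welch t via scipy — both pinned by
  hand-computed oracles in tests.
* Class-proportion sums within 0.5% of 1 are renormalized (published
  percentages are rounded); worse sums are configuration errors.

## Known limitations

* With 15 positives, per-gene Welch power for the default 0.8 dosage effect
  tops out near 0.6; dosage effects are reliably detected per region, not
  per gene.
* `max_size` above 9 is incompatible with stratified 3-fold evaluation at
  15 positives (training folds would hold ≤ d positives).
* In-cohort CV summaries of a signature selected on the same cohort are
  optimistic; only evaluation on independent data removes the selection
  bias.
* The couple-network heuristics are labelled variants of an
  underdetermined construction; none is claimed to be uniquely correct.
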