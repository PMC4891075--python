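# mmresponse

Baseline-genomics analysis of response to induction therapy in multiple
myeloma. Starting from a pre-treatment log2 expression matrix, per-sample
response categories (CR, nCR, VGPR, PR, SD) and called copy-number
segments, the package:

* discovers a low-dimensional probe signature predicting complete response
  (CR) with a **probe-pair quadratic-discriminant algorithm**: every probe
  couple is ranked by leave-one-out cross-validated performance, the top
  couples are merged into candidate signatures through a probe graph
  (components, prefix-graph components, greedy growth, hubs), and the best
  candidate is evaluated by repeated stratified 3-fold cross-validation;
* profiles **differential expression** between response groups (Welch t,
  log2 fold change, BH q-values, chromosome distribution);
* compares **CNA frequencies** between groups per atomic region with a
  two-sided Fisher exact test (probability-mass rule) and FDR adjustment,
  with the `broad` (p < 0.05, 25 pp differential) and `stringent`
  (p < 0.01, 10 pp) filter presets;
* tests **CNA→expression dosage effects** by contrasting carriers in one
  response group against non-carriers in the other over the genes a region
  covers;
* generates **synthetic cohorts with recorded ground truth** (planted
  signature, planted CNA regions, dosage coupling, Bayes-accuracy
  estimate), so the whole pipeline is testable offline.

The discriminant for class k with mean μ_k, covariance Σ_k and prior π_k is

    g_k(x) = ln π_k − ½ ln det Σ_k − ½ (x − μ_k)ᵀ Σ_k⁻¹ (x − μ_k),

with x called positive when g_pos(x) ≥ g_neg(x). Priors default to equal —
with a 15-vs-103 split, empirical priors silence the minority class.
Covariances are regularized as Σ + λ(tr Σ/d)I, λ doubled until
positive-definite. See `docs/methods.md` for the full model description and
design rationale.

## Worked example

```python
import numpy as np
import mmresponse as mm

# a ground-truthed synthetic cohort: 118 patients (15 CR / 14 nCR / 40 VGPR
# / 42 PR / 7 SD), 5 informative probes planted among 300, one recurrent
# deletion carried by 60% of CR vs 19% of the rest, dosage-coupled
cohort = mm.generate_cohort(mm.SyntheticConfig(n_probes=300, seed=1))
matrix = mm.quantile_normalize(cohort.expression)
contrast = mm.make_contrast(cohort.labels, {"CR"}, {"nCR", "VGPR", "PR", "SD"})

pairs, candidates, signature = mm.discover_signature(
    matrix, contrast, prefilter_m=25, top_k=25, max_size=8, metric="accuracy"
)
print(signature.probes)
# ('P00010', 'P00041', 'P00089', 'P00256', 'P00266')
print(set(signature.probes) & set(cohort.truth.informative_probe_ids))
# 4 of the 5 planted probes

cv = mm.evaluate_signature(matrix, contrast, signature, k=3, n_repeats=1000, seed=1)
acc = cv.summary()["accuracy"]
print(f"{acc['median']:.3f} ({acc['min']:.3f}-{acc['max']:.3f})")
# 0.907 (0.831-0.958)      # vs. Bayes accuracy 0.922 of the planted law
```

The median accuracy is the repeated 3-fold cross-validation summary of the
selected signature; it sits within two points of the generator's recorded
Bayes accuracy, i.e. the discovered signature captures nearly all the
separation the planted law allows. The CNA side:

```python
calls = mm.regionize(cohort.segments, cohort.labels.index)
extreme = mm.make_contrast(cohort.labels, {"CR"}, {"PR", "SD"})
results = mm.compare_groups(calls, extreme)
print([(r.chrom, r.event, round(r.p, 4)) for r in
       mm.filter_comparisons(results, preset="stringent")])
# [('chr1', 'loss', 0.0)]          # the planted deletion, and only it
de = mm.carrier_contrast(matrix, 1, calls, extreme, cohort.annotation)  # region 1 = the loss
print(mm.fraction_deregulated(de))
# DeregulationSummary(fraction_direction=1.0, fraction_significant=0.6875)
```

All 16 genes inside the planted deletion are down-regulated in CR carriers
versus PR/SD non-carriers, 11 of them significantly at p < 0.05 — the
dosage coupling recovered end to end.

A CLI wraps the same pipeline (`mmresponse simulate|normalize|de|discover|
evaluate|cnacompare|integrate|run-all --config config.yaml --seed N
--out-dir out/`), writing per-stage TSV/JSON artifacts and a manifest with
seeds and file digests for reproducibility.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computation from scratch on a synthetic cohort:
generation, normalization, differential expression, signature discovery
with 1000-repeat 3-fold cross-validation, region-level CNA comparison
under the stringent preset, and carrier-vs-non-carrier integration,
printing a summary and writing the results JSON to `--out` (a run summary
lands next to it).
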