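# netprio

Network-module-based prioritization of candidate cancer genes, with the
clinical statistics needed to validate a candidate's prognostic value.

## The problem

Tumor-vs-normal expression studies each nominate hundreds of
differentially expressed genes (DEGs), few of which are robust across
cohorts or biologically coherent. A network-module-based screen narrows
them down in stages:

1. **Multi-study DEG screening.** Per paired cohort, each gene's
   tumor−normal log2 differences are tested with a random-variance-model
   (RVM) moderated paired *t*-test: gene precisions are modeled as
   1/σ² ~ Gamma(a, b), giving the shrunken variance
   s̃² = ((n−1)s² + 2/b) / ((n−1) + 2a) and t̃ = d̄√n / s̃ on
   n − 1 + 2a degrees of freedom. Genes with |log2FC| > 1 and BH-FDR
   q < 0.05 in (almost) every study, with one consistent sign, are the
   common DEGs.
2. **Functional-interaction subnetwork.** The common DEGs induce a
   subgraph of an undirected functional-interaction network. Hub genes
   satisfy neighborhood connectivity (mean neighbor degree) ≥ 20 and
   per-node average shortest path length ≥ 3.5.
3. **Correlation-weighted Markov clustering.** Each subnetwork edge is
   weighted by |Pearson r| of its genes' tumor expression; the Markov
   Cluster algorithm (expansion e = 2, inflation r = 5.0) partitions the
   flow into modules; modules with ≥ 3 genes and mean internal |r| ≥ 0.25
   survive, and modules of ≥ 7 genes are annotated by hypergeometric
   over-representation against GMT gene sets (BH within each module).
4. **Candidates.** Hub genes inside the highest-correlation module.
5. **Clinical validation.** The marker is dichotomized at the median
   (High = strictly above), associated with clinicopathological features
   by uncorrected Pearson χ², and tested for prognostic value with
   Kaplan–Meier curves, the log-rank test, and Cox proportional-hazards
   models (Breslow ties; all covariates entered jointly for the
   multivariable model).

A synthetic-data generator plants known DEG effects, latent-factor
co-expression modules, dense network subgraphs, and a marker-driven
hazard, so every stage is testable offline against ground truth.

## Worked example

`examples/` holds one short script per capability. The end-to-end run
(`examples/04_modules_and_candidates.py`) simulates five paired cohorts of
2000 genes, screens them, clusters the DEG subnetwork, and prints:

```
module 0: 11 genes, mean |r| = 0.934 <- contains planted marker
module 1: 10 genes, mean |r| = 0.628
module 2: 10 genes, mean |r| = 0.686
candidates (hubs in the top module): G0327, G0417, G0453, G0529, G0967, ...
planted marker G0327 recovered: True
```

Module 0 wins the average-correlation ranking because the generator gives
the marker's module the tightest co-expression; the planted prognostic
marker survives to the candidate list. The clinical half
(`examples/06_clinical_validation.py`) recomputes the bundled published
90-patient cohort statistics and fits a Cox model on a simulated cohort:

```
histologic_differentiation: X2 = 6.897, df = 2, p = 0.032
hub genes inside the top-correlation module: AHR, AOX1, GBP2, IFITM1, RSAD2
Cox: HR = 1.86 (95% CI 1.42-2.43), p = 5.85e-06  [true HR = 2.0]
```

The χ² p-values reproduce the published associations to the printed
precision, and the Wald interval covers the planted hazard ratio.

A thin CLI mirrors the library (`netprio simulate|deg|network|modules|
enrich|prioritize|clinical|run`), working from plain-text formats
(expression TSV, sample CSV, edge TSV/SIF, GMT, clinical CSV).

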