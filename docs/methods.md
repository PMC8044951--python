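# Methods

## Moderated differential expression

Each study is a paired tumor/normal log2 expression matrix. Probe
filtering drops any row with a missing value and collapses duplicate gene
symbols to the highest-variance row (the usual probe→gene convention when
no platform annotation is available). Batch adjustment is a gene-wise
location/scale map: within each study, every gene is standardized and
rescaled to its pooled cross-study mean and SD. This exactly removes
additive per-study shifts, is invertible, and is the minimal model matched
to the generator's batch structure; it is deliberately not an
empirical-Bayes ComBat — the shrinkage there addresses small batches,
which these cohort-sized batches are not.

The per-gene test is the random-variance-model moderated paired *t*:
precisions 1/σ² ~ Gamma(a, b), so the observed sample variance satisfies
s²·a·b ~ F(n−1, 2a). The prior is fitted by maximum likelihood over all
genes (Nelder–Mead on (log a, log b), method-of-moments start, ≥ 50
positive variances required; degenerate inputs fall back to moments with a
warning). The moderated statistic uses
s̃² = ((n−1)s² + 2/b)/((n−1) + 2a) with df = n − 1 + 2a; setting the prior
to the (a→0, 1/b→0) limit recovers the classical paired *t* exactly, which
the tests verify to 1e-9. Cutoffs are strict (|log2FC| > 1, q < 0.05);
BH adjustment is the step-up procedure via statsmodels.

"Common DEGs" defaults to presence in all studies with one consistent
sign; `min_studies` is exposed because a gene missing one cohort's cutoff
by noise is usually still of interest (the synthetic benchmark uses
all-but-one).

## Network topology and hubs

The subnetwork is the induced subgraph of the interaction network on the
common DEGs; genes absent from the network are reported, genes present but
isolated are kept as degree-0 nodes. Per node we compute degree,
neighborhood connectivity (mean neighbor degree), and the node's average
unweighted shortest path length to everything it can reach — the
Cytoscape per-node "AverageShortestPathLength" convention. Hub thresholds
are inclusive (≥), only nodes in components of size ≥ 2 qualify, and
distances ignore edge weights and annotations.

The default thresholds (NC ≥ 20, path length ≥ 3.5) presume a
genome-scale network inducing a subnetwork of hundreds of nodes. The
synthetic benchmark's subnetwork is ~100 nodes built around size-10
planted modules, where those numbers are unattainable;
`PipelineConfig.sim_scale` therefore sets nc_min to half the expected
in-module degree (0.5·(module_size−1)·retention) and aspl_min to 1.0.
This is a data-scale choice, not a change of definition.

## Markov clustering and modules

Edges are weighted by |Pearson r| across the tumor samples of one
designated study (the first, by default); which samples fed the original
module correlations is not recoverable, so the choice is exposed. MCL is
the canonical dense iteration: self-loops equal to each node's maximum
incident weight (1 for isolated nodes) to damp parity effects, column
normalization, then alternating expansion (matrix square) and inflation
(entrywise power r, default 5.0) with pruning below 1e-5 and column
renormalization, until the flow changes by less than 1e-6 or 200
iterations (non-convergence clusters the current flow with a warning).
Clusters are read off the attractors (nodes retaining diagonal flow);
attractor systems sharing a column's support are merged, and each node
joins the attractor receiving its largest flow, ties broken by gene order
so output is deterministic and independent of node input order.

Module average correlation is the mean |r| over module-internal edges
(consistent with edge-level weighting; an all-pairs variant would penalize
modules for pairs the network never claimed were linked). Filters are
inclusive: size ≥ 3, mean |r| ≥ 0.25. Candidates are the hubs inside the
module with maximal average correlation (ties: larger module, then lower
id); per-module overlaps are always reported alongside.

## Enrichment

Standard over-representation: upper hypergeometric tail of the overlap,
universe = measured genes that appear in the collection (a collection-wide
universe is available). BH is applied within each module's family of
tests, since each module is annotated separately; modules under 7 genes
are skipped. The scipy implementation computes the tail stably; tests pin
it to exact enumeration of all draws for universes up to 12.

## Clinical statistics

Marker dichotomization is strictly-above-median → High (ties at the
median go Low). Association tables use the uncorrected Pearson χ² — no
Yates correction and no Fisher fallback, matching the convention that
reproduces the bundled cohort's printed p-values (0.808, 0.839, 0.032,
0.512); correction is available by flag in scipy if wanted, but not here.
Kaplan–Meier is the product-limit estimator with the median defined as
the smallest event time with Ŝ ≤ 0.5; the log-rank test uses the
hypergeometric variance–covariance at each distinct event time with a
pseudo-inverse for the (g−1)-dimensional quadratic form.

Cox regression maximizes the partial likelihood by Newton–Raphson
(covariates centered, step-halving, gradient tolerance 1e-8, 50
iterations) with Breslow tie handling by default — the SPSS convention —
and Efron available; the Efron path is cross-checked against lifelines in
the tests, and the score test at β = 0 is checked against the log-rank
statistic on binary covariates (an exact identity without ties).
Standard errors come from the inverse observed information; CIs are Wald
on the log scale with z = 1.959964. "Enter method" means all supplied
covariates fitted jointly with no selection. |β| > 15 triggers a monotone-
likelihood warning. Ordinal covariates (stage, grade, nodal status) are
encoded as numeric scores, one hazard ratio per variable.

## The synthetic benchmark

What it emulates: several paired tumor/normal cohorts with planted
±δ log2FC effects (δ = 2 by default, 5% of 2000 genes), gene variances
drawn from the same inverse-Gamma family the test assumes (a = 2, b = 1),
per-study additive (N(0,1)) and multiplicative (LogNormal(0,0.2²)) batch
effects, latent-factor co-expression blocks (gene = λf + √(1−λ²)ε with
λ = √ρ, so expected pairwise r = ρ), a background Erdős–Rényi network
(density 0.002) with planted near-clique modules (edge retention 0.9),
and a 90-patient cohort whose exponential hazard doubles above the marker
median (baseline median survival 20 months, uniform censoring calibrated
to a 25% censoring fraction, stage/grade covariates tilted toward
high-marker patients).

Choices worth stating:

- **Module scale.** Three modules of 10 genes, drawn from the planted
  DEGs so they appear in the DEG subnetwork; this matches the 7–19-gene
  modules such screens produce.
- **A clearly-top module.** The marker's module is built at ρ = 0.95 and
  the others 0.25 lower. The emulated setting is a study where one module
  carries an essentially perfect average correlation and wins the
  ranking; with all modules at equal ρ the "highest-correlation module"
  rule would be decided by sampling noise and the benchmark would test
  nothing but luck.
- **Marker placement.** The marker is a planted DEG inside that module,
  so end-to-end recovery exercises every stage.
- **Seeding.** One root seed spawns independent substreams per study (and
  for network/clinical/gene-set generation), so adding a study never
  perturbs earlier ones and identical configs are bit-identical.

What it does not emulate: probe-level artifacts, platform normalization,
heavy-tailed or count-based expression, unpaired designs, network false
edges beyond the uniform background, informative censoring, or covariates
that causally affect the hazard. Passing the benchmark shows the
machinery is correct and well-calibrated under its stated model, not that
the thresholds are optimal for any particular real cohort.

Problem sizes for the recovery experiments: screening recovery uses 20
generator seeds at 2000 genes × 20 pairs; module recovery 20 seeds at the
default network scale; Cox recovery 50 seeds at 300 patients; end-to-end
marker recovery 20 seeds of the full five-cohort default. These sizes
give Monte-Carlo error comfortably inside the acceptance margins while
keeping a full run in well under a minute.

## Bundled published cohort

`netprio.published` carries the printed outputs of the original
pancreatic-cancer IFITM1 screen: the eight topology hubs, the six modules
with their average correlations, and the internally consistent
90-patient contingency tables (the printed age, first-TNM, nodal, and
metastasis rows do not sum to the stated cohort and are excluded). These
are inputs, not recomputations: the expression cohorts and the interaction
network release behind them are not redistributable, so pipeline-level
counts (e.g. the 483-DEG screen) are out of scope; everything derivable
from the printed tables — the χ² statistics, the 76.7% high-expression
fraction, the five-gene hub∩module overlap — is recomputed by the package.

## Known limitations

- The batch adjustment assumes location/scale batch structure; nonlinear
  batch effects pass through.
- MCL is dense (O(n³) per iteration) and intended for subnetworks of up
  to a few thousand nodes, not genome-scale graphs.
- The RVM fit assumes a common prior across genes; strong
  variance–intensity trends would call for a trend-aware model.
- Cox standard errors are Wald; no robust/sandwich option and no
  proportional-hazards diagnostics.
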