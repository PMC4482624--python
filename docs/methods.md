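# Methods

## Problem and model

A miRNA binding its target mRNA accelerates the target's degradation or
represses its translation, so across a set of samples profiled on both
platforms a genuine miRNA→target pair tends to show a *negative* association
between the two expression profiles. `mirborda` treats target prediction as
a per-miRNA ranking problem: each method produces, for every miRNA, a total
order over all genes (best candidate first), and an ensemble is formed by
Borda count election over those orders. Rankings — not raw scores — are the
common currency, which makes methods with incomparable score scales
(a correlation, a regression coefficient, a causal effect, an information
coefficient) combinable.

All methods assume complete, already-normalised (log-scale) expression
matrices over identical samples; loading fails on missing values rather than
imputing silently (an explicit median-imputation helper can be added by the
caller). Probe-level features are kept as-is: duplicate probes mapping to
the same gene are *not* collapsed, and identifiers are normalised only
deterministically (trim, case-fold, optional `hsa-` prefix strip; `-5p`/`-3p`
mature forms stay distinct).

## Individual methods

**Pearson.** r(miRNA, mRNA) across samples. Zero-variance features are
non-estimable and carry an explicit undefined marker (NaN), which always
ranks last.

**MIC.** The maximal information coefficient, implemented in-package as the
ApproxMaxMI dynamic programme: for every grid with `nx·ny ≤ B(n) = n^0.6`
cells, one axis is equipartitioned and the other optimised exactly over
clump boundaries (clump factor c = 15); the normalised mutual information
`I/log2(min(nx, ny))` is maximised over grids and both axis orientations
(which also makes the estimate symmetric). MIC carries no sign, so its
ranking is by magnitude only. Its null level is noticeably above zero at
small n (~0.2 at n = 200); comparisons should always be against that level,
not against 0.

**Lasso / Elastic-net.** Each mRNA is regressed on *all* miRNAs with an
L1 (or mixed L1/L2) penalty; the miRNA's coefficient is the association
score. Predictors and responses are standardised (population sd) so
coefficients are comparable across miRNAs. The penalty weight is chosen by
10-fold cross-validation minimising MSE with folds drawn from a caller seed,
or fixed explicitly (`lam=0.05` is used throughout the synthetic studies —
small enough to keep planted effects of size ~0.9 standardised units, large
enough to zero most decoys). The elastic-net mixing default is 0.5; mixing
share 1.0 reduces exactly to the lasso.

**Knockout Z-score.** The sample in which a miRNA is lowest (ties: first
sample index) stands in for a knockout of that miRNA; each mRNA's score is
its standardised deviation in that sample, with the n−1 sd, and exactly 0
for a zero-variance mRNA. *Direction caveat*: knocking out a repressor
should *raise* its targets, so under the global negatives-first ranking
convention (which this package follows for consistency across methods) true
targets of a strong repressor tend to rank *last*. The signed score is kept
so callers can rank by `|z|` or by descending z instead; on the synthetic
studies the default convention makes this method a deliberate weak-link
baseline.

**IDA.** The PC algorithm is run once on the joint miRNA+mRNA matrix
(standardised), giving a CPDAG; the effect of a miRNA on a gene is the
multiset of adjusted OLS coefficients — one per locally valid parent set of
the miRNA (directed parents plus every sibling subset whose orientation into
the miRNA creates no new collider), with the effect defined as 0 whenever
the gene itself lies in the adjustment set — summarised by the element of
minimum absolute value, sign preserved (the customary conservative lower
bound).

*Background knowledge.* `ida_scores` additionally enforces the hard
biological constraint that regulation runs miRNA → mRNA: undirected
miRNA–gene edges in the estimated CPDAG are oriented that way, and directed
gene→miRNA edges (artefacts of spurious v-structures) are flipped, before
Meek's rules are re-closed and effects computed. Without this, every target
attached by an unoriented edge contributes a reversed-edge zero to its
multiset and the min-abs summary degenerates to 0 for exactly the pairs the
method should find. The flag `orient_mirna_to_mrna=False` restores the
purely data-driven behaviour. The generic `pc_cpdag`/`ida_effects` API
remains data-driven and matches brute-force equivalence-class enumeration
exactly on small graphs.

*PC details.* Fisher-z partial-correlation tests at level α = 0.05;
PC-stable skeleton (neighbourhoods frozen per level) with conditioning sets
up to `max_cond_size` (default 3; the 330-variable synthetic studies use 1
— at ~54 000 candidate edges, higher orders add little for bipartite
planted structure); variable order fixed to input order for determinism.
Orientations that would close a directed cycle (possible only under
conflicting v-structures from sampling error, or inconsistent background
knowledge) are skipped deterministically, first-come-wins.

## Ensemble

`borda_rank` averages each gene's ranks across methods and sorts ascending;
ties break lexicographically by gene id, and output ranks are reassigned
1..G, so the result is again a total order. `borda_topk_rank(k)` first
replaces every rank > k by the maximal rank G, rewarding agreement within
the heads of the lists; `k = G` reproduces `borda_rank` exactly (this
identity is tested on 1000 random instances). Default is `k = G` so the
ensemble is parameter-free unless top-k truncation is requested. All input
rankings must cover the identical gene universe — no union/intersection
merging is attempted.

## Validation statistics

With an incomplete gold standard, absolute precision is meaningless, so
methods are compared relatively. For each top-N cutoff, only miRNAs for
which *every* method's top-N contains at least one confirmed target are
eligible. Per eligible miRNA, methods are scored 1..M by their confirmed
counts (most-confirmed gets M; tied counts share the average of the spanned
scores, so each miRNA's scores always sum to M(M+1)/2 — the invariant that
makes sums comparable), and scores are summed over miRNAs and datasets. The
enrichment z-score compares a method's confirmed rate x over n evaluated
pairs with the gold standard's base rate μ (confirmed / (unique miRNAs ×
unique genes in the truth table)) under a Bernoulli model:
z = (x − μ)/(√(μ(1−μ))/√n). Paired method comparisons use the two-sided
Wilcoxon signed-rank test with zero differences dropped. "Highly confident
novel" pairs are the intersection of the expression-based predictions with
an independent sequence-based prediction set, minus everything confirmed.

## Synthetic data

The generator plants the signal the methods exploit: miRNA profiles are
i.i.d. standard normal; each miRNA down-regulates `targets_per_mirna` genes
drawn uniformly; a planted gene is the sum of `effect_size ·` (its
regulators) plus N(0, noise_sd²); decoys are independent N(0, 1). Defaults —
30 miRNAs, 300 genes, 100 samples, 5 targets per miRNA, effect −1.0, noise
sd 0.5 — give planted pairs a population correlation of ≈ −0.89, i.e. strong
but noisy regulation at a desk-scale study size. A `nonlinear_fraction` of
planted pairs instead uses the monotone-decreasing bounded-slope transfer
g(x) = −|x|·x/(1+|x|), which MIC detects at full strength while Pearson
under-rates it. A `confirmed_fraction` (default 0.8) of planted pairs is
marked confirmed, emulating the incompleteness of curated interaction
databases. Every consumer draws from its own seed sub-stream
(`default_rng([seed, tag])`), so adding rankers or genes never perturbs
earlier draws, and all output is a pure function of the config.

`simulate_noisy_rankers` fabricates rankers of known quality: gene score =
`skill · 1[planted target] + Uniform(0, 1)`, ranked descending. Skill 0 is an
exactly random ranker (expected precision@k equals the planted fraction);
high skill with `noise_scale→0` recovers the truth exactly. Five skill-0.3
rankers over 200 genes with 20 targets is the regime in which the Borda
ensemble demonstrably beats the best individual ranker — the quantitative
content of the wisdom-of-crowds argument.

What the generator does *not* emulate: microarray platform noise, batch
effects, probe cross-hybridisation, correlated miRNA expression, and
combinatorial/cooperative regulation. Passing tests therefore demonstrate
correctness of the algorithms and the claimed relative behaviours under the
stated model, not field performance on real cohorts.

## Numerical choices and degenerate inputs

- Undefined scores (zero-variance features, singular regressions) are NaN
  and rank after everything, never silently 0 — except where a 0 is the
  defined value (zero-variance mRNA in the knockout z-score; zero-variance
  regression response, with a warning).
- All ranking ties break lexicographically by gene id; ties in the miRNA
  minimum break to the first sample index; PC variable order is input
  order. Equal inputs therefore always give byte-identical outputs.
- Fisher-z tests are skipped (p = 1) when the degrees of freedom
  n − |S| − 3 are non-positive; correlations are clipped away from ±1.
- BH adjustment delegates to statsmodels, the Wilcoxon test to scipy, the
  penalised regressions to scikit-learn; each is cross-checked in the test
  suite against an independent oracle (step-up rule, exact sign-flip
  enumeration, soft-threshold/ridge closed forms).
- Problem sizes in the test suite and reproduction script (330-variable PC
  graphs, 15–50 replicate studies, 100 ranker replicates) were chosen to
  exercise the full pipeline at desk scale; all are parameters, not limits.

## Known limitations

- The PC implementation targets hundreds-to-thousands of variables with
  small conditioning sets; it is not optimised for dense graphs or large
  `max_cond_size`.
- Valid-parent-set enumeration is exponential in the size of connected
  sibling cliques; on the bipartite-ish graphs this package produces that is
  harmless, but pathological dense CPDAGs could be slow.
- GenMiR++ and ProMISe (Bayesian/competition models) and sequence-based
  scoring are out of scope; sequence predictions enter only as an externally
  supplied pair list for the novel-interaction intersection.
- Cross-entropy Monte Carlo rank aggregation and moderated-statistics
  differential expression are not provided; the Welch t-test + BH prefilter
  is a deliberate lightweight stand-in for the latter.
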