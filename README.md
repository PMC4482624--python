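# mirborda

Ensemble miRNA target prediction from matched miRNA/mRNA expression data.

MicroRNAs (miRNAs) predominantly *down-regulate* their messenger-RNA targets,
so a miRNA–target pair should leave a negative statistical footprint across
samples in which both were profiled. Many expression-based predictors exploit
this — correlation, regression, causal inference, knockout emulation — but no
single one is consistently best across datasets. `mirborda` implements six
individual scoring methods and combines their per-miRNA target rankings with
**Borda count election**: each gene's aggregate score is its mean rank across
methods, and the ensemble ranking orders genes by ascending mean rank. If
every component method has better-than-random predictive power, the Borda
ensemble can outperform the best individual method — the "wisdom of crowds"
argument for network inference.

## Methods

For matched matrices `X` (miRNAs × samples) and `Y` (mRNAs × samples):

| method    | score for pair (i, j) |
|-----------|------------------------|
| `pearson` | product-moment correlation r(Xᵢ, Yⱼ) |
| `mic`     | maximal information coefficient MIC(Xᵢ, Yⱼ) ∈ [0, 1] |
| `lasso`   | coefficient of miRNA i in the L1-penalised regression of mRNA j on all miRNAs |
| `elastic` | same with a mixed L1/L2 penalty |
| `zscore`  | knockout emulation: zᵢⱼ = (Yⱼ(s*) − mean Yⱼ)/sd Yⱼ at the sample s* where miRNA i is minimal |
| `ida`     | IDA causal effect: PC algorithm → CPDAG, then the minimum-absolute adjusted regression effect over the miRNA's locally valid parent sets |

Sign-informative scores are ranked negatives-first by magnitude (down-
regulation first); MIC is ranked by magnitude alone. `borda_topk_rank`
aggregates rankings using only each method's top *k* targets — genes outside
a method's top *k* are imputed the maximal rank *G* — and reduces exactly to
the original Borda count at *k = G*.

Validation against a (necessarily incomplete) confirmed-interaction set
counts confirmed targets in each method's top-*N* list, converts counts to
per-miRNA **ranking scores** in 1..M (M methods; ties averaged), sums them
over miRNAs, and supports a Bernoulli enrichment z-score
`z = (x − μ)/(σ/√n)`, `σ = √(μ(1−μ))`, plus Wilcoxon signed-rank comparison
of two methods.

## Worked example

```python
from mirborda import (SyntheticConfig, simulate_matched_expression,
                      pearson_scores, lasso_scores, ida_scores,
                      scores_to_ranking, borda_rank, confirmed_in_topN)

cfg = SyntheticConfig(seed=1)          # 30 miRNAs, 300 genes, 100 samples,
pair, truth = simulate_matched_expression(cfg)  # 5 targets/miRNA, effect -1
tp = truth.planted_pairs()

sms = {"pearson": pearson_scores(pair),
       "lasso": lasso_scores(pair, lam=0.05),
       "ida": ida_scores(pair, max_cond_size=1)}
total = {m: 0 for m in sms} | {"ensemble": 0}
for mir in pair.mirnas.feature_ids:
    rankings = [scores_to_ranking(sm, mir) for sm in sms.values()]
    for name, r in zip(sms, rankings):
        total[name] += confirmed_in_topN(r, tp, 5)
    total["ensemble"] += confirmed_in_topN(borda_rank(rankings), tp, 5)
print(total)
```

prints

```
{'pearson': 150, 'lasso': 150, 'ida': 150, 'ensemble': 150}
```

— all 150 planted interactions (30 miRNAs × 5 targets) sit in every method's
top 5 under these conditions, and the Borda ensemble preserves that. The
ensemble's value shows when components err independently: aggregating five
noisy rankers of skill 0.3 lifts mean precision@100 above the best
individual's in ~94% of replicates (see the reproduction script below).

The same workflow is scriptable from the shell:

```sh
mirborda simulate --config cfg.json --outdir data/
mirborda predict --mirna data/mirna.tsv --mrna data/mrna.tsv \
         --methods pearson,lasso,ida --lam 0.05 --out rankings.tsv
mirborda ensemble --inputs rankings.tsv --topk 200 --out ens.tsv
mirborda validate --rankings rankings.tsv --rankings ens.tsv \
         --truth data/confirmed.tsv --topn 5,10 --out scores.tsv --report report.tsv
```

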