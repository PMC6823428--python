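# consensome

Consensus meta-analysis of differential-expression and ChIP-Seq corpora:
ranked "consensome" signatures of signaling-node target genes.

## The problem

A single perturbation experiment — knocking out a nuclear receptor,
treating cells with an agonist, immunoprecipitating a transcription
factor — yields a noisy snapshot of a signaling node's downstream
targets. Public archives hold thousands of such experiments, but their
designs are wildly heterogeneous: gain vs loss of function, different
ligands, doses, time points, tissues. The same true target can be
induced in one experiment and repressed in the next.

A consensome sidesteps this heterogeneity by ranking genes on the
*frequency* of their significant regulation across all experiments
mapped to a signaling-node family in a given biosample, rather than on
effect size or direction. Genes whose expression depends on the
integrity of a node are differentially expressed more often than chance
would allow, whatever the sign of the change.

## The statistic

Within one experiment, probeset-level evidence is collapsed to genes.
Each probeset's two-tailed p-value `P_p` and linear fold change `F_p`
become a directional z-score

    Z_p = qnorm(|1 + sign(log2 F_p) − P_p| / 2),   sign(0) = +1

(the upper tail `qnorm(1 − P_p/2)` for induction, the lower tail
`qnorm(P_p/2)` for repression). The gene-level z is the mean of its
probeset z's, `Z = (1/n) Σ Z_p`, converted back to a two-tailed p-value
`P = 2(1 − Φ(|Z|))`; the gene-level fold change `F̂ = 2^(â + b̂·Z)`
comes from an OLS regression of probeset log2 fold changes on probeset
z's, evaluated at `Z`.

Across the `N_g` experiments in which gene *g* is measured, `E_g`
counts those with `P ≤ 0.05`. The **consensome p-value (CPV)** is the
binomial upper tail

    CPV_g = P(X ≥ E_g),   X ~ Binomial(N_g, 0.05),

the probability of seeing that much recurrence by chance. The
**consensus fold change** is the geometric mean of `max(F, 1/F)` across
experiments (direction deliberately suppressed). Genes are ranked by
ascending CPV (average rank on ties) and reported with percentiles
`100·(N − rank)/N`. Cistromic (ChIP-Seq) consensomes average, across
experiments of a node family, each gene's MACS2 peak score within
±10 kb of its TSS, and rank by descending mean.

## Worked example

Build a consensome for a seeded synthetic corpus with 10 known true
targets among 1000 genes, 20 experiments:

```python
from consensome import (SimulationConfig, simulate_transcriptomic_corpus,
                        TranscriptomicConsensome)

tables, meta, truth = simulate_transcriptomic_corpus(SimulationConfig(seed=1))
est = TranscriptomicConsensome(alpha=0.05, p0=0.05).fit(tables, meta)
print(est.consensome_.head(5)[["gene_id", "n_discoveries", "n_experiments",
                               "cpv", "consensus_fc", "rank", "percentile"]])
```

```
    gene_id  n_discoveries  n_experiments           cpv  consensus_fc  rank  percentile
0  Gene0945             19             19  1.907349e-25      1.795440   1.0        99.9
1  Gene0947             18             20  6.577587e-22      1.897254   2.0        99.8
2  Gene0312             16             17  2.471924e-20      1.645339   3.0        99.7
3  Gene0469             16             18  2.120056e-19      1.847170   4.0        99.6
4  Gene0750             14             17  3.596146e-16      1.812998   5.0        99.5
```

Each row reads: the gene was significantly regulated in `n_discoveries`
of the `n_experiments` experiments measuring it; `cpv` is the binomial
probability of that recurrence under the 5% null; `consensus_fc` is the
typical magnitude of the change irrespective of direction; genes are
ranked by ascending `cpv`. All 10 true targets land in the 90th
percentile here. The same corpus can be driven from the shell:

```sh
consensome simulate --seed 1 --out corpus/
consensome consensome-tx --corpus corpus/ --family FamilyA --species mouse --out liver.tsv
consensome enrich --counts 258 99 25922 1490 --out enrich.json
```

The `enrich` example reproduces a published validation computation: a
top-1% consensome slice of 258 genes containing 99 metabolic-enzyme
genes, against a 25,922-gene universe containing 1490, gives a slice
frequency of 38% vs 5.7% — a 6.7-fold enrichment.

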