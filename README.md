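# rrho2 — rank-rank hypergeometric overlap for gene-expression signatures

Comparing two differential-expression studies by intersecting thresholded
gene lists (p < 0.05 in both, say) throws away most of the signal and says
nothing about genes moving in *opposite* directions. Rank-rank
hypergeometric overlap (RRHO) is the threshold-free alternative: rank each
study's genes by signed significance, scan **all** pairs of rank cutoffs,
and score the overlap of the selected gene sets at every cutoff pair with
a hypergeometric test. The result is a heatmap whose hotspots show where
along the significance gradient the two signatures agree — or disagree.

This package is for transcriptomics analysts (bulk or single-cell) who
want that comparison with correct handling of **discordant** overlap. It
provides four map schemes:

* **Enrichment** — the classic map; interpretable only where both studies
  change in the same direction.
* **Two-sided** — signed over-/under-enrichment variant, with fixed color
  scale and truncation of infinite scores.
* **Stratified** — quadrant-wise counting from each quadrant's outward
  corner, so all four quadrants (up/up, down/down, up/down, down/up) read
  as over-enrichment. This is the scheme that detects discordance.
* **Log odds ratio** — the stratified 2x2 table scored by its log odds
  ratio instead of a p-value; independent of sample size, hence a
  conservative companion when the gene universe is large.

## The statistic

With N common genes, s selected from study 1, M from study 2, and k in the
overlap, the over-enrichment p-value at one pixel is the inclusive
hypergeometric upper tail

    H(k; s, M, N) = sum_{j=k}^{min(s,M)}  C(M,j) C(N-M, s-j) / C(N,s),

equal to the one-sided Fisher exact p-value of [[k, s-k], [M-k, N-M-s+k]].
Maps show -log10 H (or -ln H). Genes are ranked by
DDE = -log10(p) x sign(effect). The log-odds map scores
theta = ln[ k(N+k-M-s) / ((s-k)(M-k)) ], with theta > 0 meaning
over-enrichment in every quadrant. Tails are computed in log space, so
overlaps with p ~ 1e-3000 remain finite without any p = 0 patching.

A seeded simulation module generates two-study Gaussian expression data
(correlated gene clusters via standardized inverse-Wishart draws,
truncated-normal effect sizes, concordant or discordant directions) with
full ground truth, and a built-in two-group t-test turns expression
matrices into ranked lists — so the whole claim "stratified maps recover
discordant signatures that enrichment maps miss" is reproducible end to
end with no external data.

## Worked example

Simulate a discordant pair of studies (2,000 genes, 200 of them DE with
opposite directions in the two studies) and ask where the stratified map
finds its hotspots:

```python
from rrho2 import SimulationConfig, run_simulation_study, stratified_map
from rrho2.viz import quadrant_summary

config = SimulationConfig(
    n_genes=2_000, n_clusters=40, cluster_size=20,
    n_de=200, mode="discordant", seed=11,
)
ranked, truth = run_simulation_study(config)
overlap = stratified_map(ranked)
print(quadrant_summary(overlap).to_string(index=False))
print(f"\nglobal max: {overlap.scores.max():.1f} (-log10 p)")
```

prints

```
quadrant    max_score  cutoff_x  cutoff_y  k_at_max  caveat
       A 7.693110e+01        90      1935        57   False
       B 6.338946e-05      1710      1890        5    False
       C 5.901865e-08        90       315        1    False
       D 9.715447e+01      1890        90        77   False
```

Quadrant A (up in study 1 / down in study 2) peaks at -log10 p ~ 77:
taking the 90 most up-regulated genes of study 1 and the 65 most
down-regulated of study 2 (cutoff 1935 of 2000 from the up end), 57
coincide. Quadrant D (down/up) peaks at ~97. The concordant quadrants B
and C are flat (max scores ~1e-4): the two studies share essentially no
same-direction signal — exactly the planted truth. An enrichment map on
the same data has a global max of ~0.03, i.e. it is completely blind to
this discordance.

The same pipeline is available from the shell:

```
rrho2 simulate --mode discordant --n-genes 2000 --n-clusters 40 \
               --n-de 200 --seed 11 --outdir sim/
rrho2 run sim/ranked_study1.tsv sim/ranked_study2.tsv \
          --method stratified --outdir out/
```

which writes the score matrix (`map.tsv`), the quadrant summary, a heatmap
PNG (white strips mark each study's up/down boundary), and a manifest with
input digests and the seed. `rrho2 run` also accepts your own two-column
(gene, dde) or three-column (gene, pvalue, direction) TSV/CSV lists.

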