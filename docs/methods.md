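# Methods

## The problem

Two differential-expression (DE) studies — two brain regions, two species,
two treatments — are routinely compared by intersecting thresholded gene
lists (e.g. genes with p < 0.05 in both). Thresholds discard most of the
signal and the intersection tells you nothing about *where* along the
significance gradient the agreement lives, nor whether genes move in the
same or opposite directions. Rank-rank hypergeometric overlap (RRHO)
replaces the single threshold with a scan over **all** pairs of rank
cutoffs, scoring the overlap at each pair and visualizing the result as a
heatmap.

## Ranking

Each study's genes receive a degree of differential expression,

    DDE = -log10(p_two_sided) x sign(effect),

so strongly up-regulated genes get large positive scores and strongly
down-regulated genes large negative ones. Genes are sorted by descending
DDE; ties break lexicographically by gene id so every map is
bit-reproducible. The two lists are restricted to their common universe of
N genes before mapping. The *boundary* of a list is the rank of its first
non-positive DDE; genes with DDE exactly 0 sit on the down-regulated side.
Zero p-values (possible with numerically saturated test statistics) are
floored at half the smallest positive p so the log never diverges; the
replacement count is logged.

## Overlap scoring

At a cutoff pair, s genes are selected from study 1 and M from study 2; k
of them coincide. Under the null that the selections are independent
draws from the N common genes, k is hypergeometric, and the over-enrichment
p-value is the inclusive upper tail

    H(k; s, M, N) = sum_{j=k}^{min(s,M)} C(M,j) C(N-M, s-j) / C(N,s),

identical to the one-sided Fisher exact test on the 2x2 table
[[k, s-k], [M-k, N-M-s+k]]. Tails are evaluated in log space
(`scipy.stats.hypergeom.logsf/logcdf`), which remains accurate for tails
around 1e-3000; -log10 p is therefore finite everywhere and the maps never
need post-hoc patching for p = 0. The tests cross-check the tails against
an exact rational-arithmetic enumeration (stdlib `fractions`) exhaustively
for all ~6.4e5 valid tables with N <= 60, and against `fisher_exact`.

## The four map schemes

The cutoff grid uses step = ceil(sqrt(N)) by default (cutoffs step,
2*step, ..., <= N), user-overridable. Overlap counts for the whole grid
come from one cumulative 2-D histogram of the paired rank positions, from
which all four quadrants' counts are derived in closed form.

* **Enrichment.** s and M always count from the most up-regulated end;
  score = -log H. Only the concordant quadrants (up/up = C, down/down = B)
  are interpretable: discordant overlap cannot raise k above expectation
  under this counting, which is exactly the blindness the stratified
  scheme fixes.
* **Two-sided.** Same counting; the score is signed:
  +(-log P(K >= k)) when k > E(k) = sM/N, -(-log P(K <= k)) when k < E(k),
  and 0 at equality. Where the score is positive it equals the enrichment
  score by construction. Any infinities (none arise with exact counts)
  would be bounded by the map's finite extremes.
* **Stratified.** Each pixel belongs to one quadrant, determined by its
  position relative to the two boundaries; a pixel whose cutoff equals the
  boundary rank is assigned to the down-regulated side (arbitrary but
  fixed). Within a quadrant, s and M count from the quadrant's *outward*
  ends — the up end for an up side, the down end for a down side — so the
  same upper-tail formula reads as over-enrichment of that quadrant's own
  direction pairing in all four quadrants. Discordant signatures light up
  A (up1/down2) and D (down1/up2).
* **Log odds ratio.** Same stratified selections, scored by the natural-log
  odds ratio of the pixel's 2x2 table,
  theta = log[ k (N+k-M-s) / ((s-k)(M-k)) ].
  Because the outward-corner counting already orients each quadrant's
  table, one formula serves all quadrants and theta > 0 is equivalent to
  k > E(k) everywhere (the identity k(N+k-M-s) - (s-k)(M-k) = kN - sM
  makes this exact). Writing the formula with numerator and denominator
  swapped is the equivalent device for always-from-the-top counting; doing
  both would double-invert and flip every discordant signal, so this
  package couples the uniform formula to the stratified counts. theta is
  sample-size-free, making it a conservative companion to the p-value maps
  when N is large. +/-infinite ratios (empty off-cells) are bounded by the
  map's extreme finite values; a 0/0 table (e.g. an empty selection at a
  grid edge) scores 0, i.e. "no evidence".

Scale conversion between -log10 and -ln maps is the multiplicative
constant ln(10); pixel ranks are invariant, and the base-10 maximum is
1/ln(10) ~ 0.434 of the natural-log maximum. Log-odds maps are natural-log
by definition and refuse rescaling.

Degenerate inputs: stratified and log-odds maps require a DDE sign change
in both lists (otherwise quadrants are undefined) and fail loudly;
enrichment and two-sided maps still run on one-signed lists.

## Differential expression

The built-in two-group test is a per-gene pooled-variance Student t
(Welch optional), effect = case mean - control mean, two-sided p from the
t distribution. This is deliberately plain: variance moderation
(limma-style empirical Bayes) changes little at 20 samples per group, and
the quantities the maps consume — a ranking by signed significance — are
insensitive to it. Genes constant across all samples get p = 1, effect 0,
and a flag. One-sided p-values (p/2 if the effect is in the favored
direction, 1 - p/2 otherwise) are emitted alongside; ordering by one-sided
p ascending is identical to ordering by DDE descending.

## Synthetic data

The generator reproduces a two-study Gaussian expression experiment with
known truth; defaults are the full protocol:

| parameter | default | meaning |
|---|---|---|
| n_genes | 10,000 | common gene universe |
| n_clusters x cluster_size | 200 x 20 | correlated gene clusters (4,000 genes) |
| n_per_group | 20 | cases and controls per study |
| sigma | 1.0 | noise scale (swept 1-7 in robustness checks) |
| wishart_df | 60 | inverse-Wishart df for cluster correlation |
| n_de | 1,000 | differentially expressed genes (10%) |
| mode | concordant | or discordant |

Per cluster and study, a correlation matrix is drawn from an
inverse-Wishart with scale 0.5*I + 0.5*J and standardized to unit diagonal
(A = D^-1/2 A' D^-1/2); cluster expression is multivariate normal with
covariance sigma^2 A, the remaining 6,000 genes independent N(0, sigma^2).
DE genes are drawn uniformly from all genes; each gets an effect size
theta ~ N(1,1) truncated to (0.5, inf) — sampled by inverse CDF for
determinism — and a direction d ~ Bernoulli(0.5). Cases receive the shift
(-1)^d theta in both studies; discordant mode flips the sign in study 2
only. Controls are untouched. theta is shared across studies (the mode
flag alone controls sign). All randomness flows from one seed; identical
configs give bit-identical data.

The number of DE genes is a free parameter of the design; 10% of genes
produces clear hotspots at sigma = 1 without saturating the map. What the
generator does *not* emulate: count noise (RNA-seq overdispersion),
library-size or batch effects, correlation between DE status and cluster
membership, and non-Gaussian heavy tails. Passing tests therefore
demonstrate the *algorithmic* claims (which quadrants light up, and when)
rather than performance on any particular real platform.

## Validation conditions and problem sizes

The simulation-based checks run at 2,000 genes (40 clusters of 20 + 1,200
independent, 200 DE genes — the full design scaled by 5) for the
stratified/enrichment hotspot-recovery and null-calibration checks, and at
the full 10,000-gene design for the log-odds noise sweep (sigma in
{1, 3, 7}, both modes, 5 seeds each), where the odds-ratio map is cheap
because it needs no tail summations. At 2,000 genes the sigma = 7
discordant condition is under-powered for the log-odds map, which is why
the sweep uses the full design it actually concerns. The null hotspot
threshold is the 95th percentile of the stratified map maximum over 50
pure-null (n_de = 0) runs; its batch-to-batch coefficient of variation is
~12%, so "hotspot" has a stable operational meaning.

## Numerical choices

* Tail p-values: inclusive of the observed k on both sides; computed in
  log space; -0.0 normalized to 0.0 so serialized maps are byte-stable.
* Tie-breaks: gene-id lexicographic in ranking; boundary pixels assigned
  to the down-regulated side.
* Grid: cutoffs are multiples of the step; if N is not a multiple the last
  cutoff falls short of N rather than overshooting.
* Serialization: maps are TSV matrices with cutoff headers plus a
  `# key=value` metadata block; floats use %.17g and are re-read with
  round-trip parsing, so write-then-read is lossless.
* Rendering uses a sequential palette (white-yellow-red) for pure
  over-enrichment maps and a diverging one (blue-white-red) for signed
  maps; the original figures' rainbow palette is available via the palette
  flag. Rendering never alters the matrix; the side-car TSV is
  bit-identical to the input.

## Known limitations

* The two-sided map's exact sign/tail convention follows the declared
  definition above (sign of k - E(k), inclusive tails); other
  implementations may differ at pixels very near expectation.
* The log-odds truncation ties infinite pixels to the map's observed
  finite range, so their rendered intensity depends on the rest of the
  map; on pathological inputs where *every* pixel is infinite (e.g. two
  byte-identical rankings) the map is rejected rather than guessed at.
* No multiple-testing correction is applied across pixels; the null
  calibration above is the intended way to judge map maxima.
* Gene identifier harmonization across species/platforms is the caller's
  responsibility.
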