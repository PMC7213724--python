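# Methods

## The analysis model

`mirnet` targets the common design of a small clinical transcriptomics
study: two groups of tissue samples (cases with a phenotype such as
sustained atrial fibrillation, controls without it), each profiled for
gene expression (RNA-seq counts) and mature miRNA abundance (microarray
log2 intensities) from the same RNA pool. The matched design is what makes
expression correlation between a miRNA and its predicted target a
meaningful filter: both measurements come from the same biological
replicate, so a repressive interaction should show up as monotonic
anti-correlation across samples regardless of the different measurement
scales of the two platforms. Spearman's ρ is used for exactly that reason —
it is invariant to any monotone transform of either axis.

## Differential expression

Counts are normalized with median-of-ratios size factors: the reference is
the per-gene geometric mean over genes detected in every sample, and each
sample's factor is the median ratio to that reference. This is robust to a
minority of strongly DE genes, which is the regime the planted simulations
create. Normalized values are log2(count/factor + 1); the pseudocount of 1
bounds the variance of low-count genes at the cost of compressing their
fold changes, which is acceptable because the selection threshold
(|log2FC| > 1) targets strong effects. Genes with zero counts in all
samples carry no information and are dropped before testing (reported in
the pipeline log).

Testing uses a moderated t-statistic. Per-feature pooled variances s²_g on
d = n₁+n₂−2 df are shrunk toward a prior s₀² with weight d₀, both fitted
by method of moments on e_g = log s²_g: var(e) − trigamma(d/2) estimates
trigamma(d₀/2) (inverted by Newton iteration, floored at 10⁻⁸), and
mean(e) gives log s₀² through the matching digamma identity. When the
observed log-variances are underdispersed relative to chi-square sampling
noise, d₀ is reported as unbounded and the posterior variance is s₀² for
every feature, with a normal reference distribution. Zero-variance
features are excluded from the hyperparameter fit (log 0 is undefined) but
still tested — their posterior variance is the prior's share, so no
division by zero occurs. With d₀ forced to 0 the statistic reduces exactly
to the textbook pooled t, which the tests exploit as an oracle.

The moderated test on log-normalized counts stands in for a
negative-binomial Wald fit. The substitution is deliberate: it is simpler,
its null behaviour is verifiable (the suite checks the raw p < 0.05 rate
on null negative-binomial data stays in [0.03, 0.07] across 20 seeds, and
Kolmogorov–Smirnov uniformity holds on Gaussian intensity data), and the
planted-recovery tests show it has ample power at the effect sizes the
selection thresholds target. An NB backend could be added behind the same
table contract without touching downstream stages.

Selection rules are platform-specific and strict at the boundary: genes
need BH-adjusted p < 0.05 and |log2FC| > 1; miRNAs need raw p < 0.01 with
no fold-change cut-off (microarray intensity ratios are compressed, so a
fold-change gate would be miscalibrated there). All cut-offs are exposed
as parameters.

## Network construction

Binding predictions are accepted when the binding probability is strictly
above 0.95 and the site is in the 3'-UTR; duplicate (miRNA, gene) rows
collapse to the maximum probability with validated flags OR-ed. Candidate
pairs must have both partners differentially expressed; by default only
opposite-direction pairs are kept (`opposite_only=True`), since repression
predicts opposite movement — the flag exists because correlation filtering
alone would also admit same-direction pairs. ρ is computed over the
intersection of sample IDs present in both matrices (never union or
imputation: only samples truly profiled on both platforms carry pairing
information); pairs with a constant expression vector have undefined rank
correlation and are dropped with a log entry rather than assigned 0.
Edges require ρ < −0.5 strictly. Networks keep node attributes (type,
log2FC, significance) and edge attributes (ρ, binding probability,
validated) through GraphML round trips.

## Over-representation

The enrichment statistic is the exact hypergeometric upper tail
P(X ≥ k) for an overlap of k between an n-gene query and a K-member term
in an M-gene universe — the plain version, not a mid-p or EASE-style
variant, so it is conservative under discreteness. The universe defaults
to the genes actually tested for differential expression; using the whole
genome would inflate every term's significance because unexpressed genes
can never enter a query. BH correction runs across all terms tested in a
run; per-namespace correction is a caller choice (split the collection).

## Positional clustering

"Consecutive elements overlapping or not further than 20 kbp" is resolved
as a single-linkage sweep: sort by (start, end, id) per chromosome, keep a
running maximum end E of the open cluster, and join an element when
start − E ≤ 20,000 (inclusive; overlap gives a negative gap and always
joins). The running maximum makes a long interval that contains shorter
ones unable to break a chain — standard interval-merge semantics, verified
against an O(n²) transitive-closure oracle. Clusters need ≥ 2 members;
≥ 5 members of any type makes a high-density locus; high-density clusters
composed exclusively of SNPs are flagged excluded (small SNP-only clusters
are retained but flagged). Coordinates are 0-based half-open with SNPs as
1-bp intervals; strand is ignored (no strand rule is defined for
clustering). SNP nearest-gene distance is 0 inside a gene, otherwise the
gap to the closest interval edge, with ties returning every minimal gene.
Chromosome density reports both count per Mbp and count per annotated
gene, since neither normalization alone is canonical. Host-gene
co-expression considers significant miRNAs annotated intronic/exonic with
a host present in the gene table: same-direction compares log2FC signs;
both-significant additionally applies the gene rule to the host.

## Synthetic data: what it emulates and what it does not

The generator mirrors the study shape: 6 cases vs 6 controls, counts drawn
negative-binomial (variance = μ + αμ², α = 0.05 by default — a typical
RNA-seq dispersion) around log-normal base means (median ≈ 300), planted
DE genes with |log2FC| uniform in [1.5, 3] applied to the case group, and
miRNA intensities Gaussian on the log2 scale (per-feature SD 0.25) with
planted shifts of the same magnitude range. Planted regulatory pairs link
a DE miRNA to a distinct DE gene of opposite direction; the coupling acts
on the target's log-mean — the regulator's within-group intensity residual
depresses the target, scaled so that `pair_effect` of the target's
within-group log-variance (0.9 by default) is regulator-driven, with a
within-group SD budget of 0.5 log2 units. Acting on the log-mean (not on
realized counts) preserves the marginal NB model and hence DE calibration.
Paired targets draw comfortably expressed base means (≈ 800) so counting
noise does not swamp the coupling. Decoy predictions come in three kinds —
sub-threshold probability, wrong binding region, and confident calls on
non-DE targets — so every filter has something to remove. Planted genomic
clusters pack 2 DE genes, 2 DE miRNAs and 2 SNPs with gaps far below
20 kbp; everything else is scattered ≥ 100 kbp apart so no spurious
cluster can form, except that hosted miRNAs are intentionally placed
inside their host gene. One control sample can optionally be given
inflated noise on both platforms to exercise outlier QC.

Not emulated: read-level data, probe effects, batch structure, correlated
gene-gene networks beyond the planted pairs, clinical covariates, or
realistic genome annotation. Passing the planted-recovery tests therefore
demonstrates that the pipeline's logic and thresholds behave as specified
under the stated noise model — not that the thresholds are optimal for any
particular real dataset.

## Numerical and reproducibility choices

All randomness flows from one integer seed through `numpy`'s PCG64
generator; fixed (config, seed) reproduces every file byte-for-byte, and
the pipeline manifest SHA-256-checksums every output. Sorting everywhere
uses stable mergesort with documented tie-breaks (clusters by
(start, end, id); ORA by (p_adj, p_raw, term_id)). The trigamma inversion
runs 50 Newton steps with a 10⁻¹⁰ relative tolerance. QC outlier flagging
uses strict exceedance of Q3 + 1.5·IQR of per-sample median distances.
PCA signs follow the largest-magnitude loading of each component.

Problem sizes in the test suite and acceptance script (300 genes,
60 miRNAs, 30 pairs, 10–20 seeds; 1,000 genes for null calibration) were
chosen as the smallest sizes at which the planted effects and calibration
bands are statistically stable.

## Known limitations

No covariate adjustment, paired designs, or batch correction in the DE
stage; no dispersion-trend shrinkage; enrichment does not propagate GO
graph ancestry or correct gene-length bias; clustering is descriptive
(no significance test against a positional null); mixed genome assemblies
are the caller's responsibility to avoid.
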