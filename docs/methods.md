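# Methods

## Scope and data model

The package analyses gene × cell integer count matrices from deep-coverage
single-cell RNA-seq with ERCC spike-ins. Genes are rows and cells are
columns everywhere. Spike-in rows are recognised by id prefix (`ERCC-` by
default, configurable); mitochondrial rows require a gene → chromosome
annotation sidecar because a bare matrix does not carry that information.
Normalized matrices are pandas DataFrames; curated gene lists travel as GMT
collections.

## Quality control

A cell is removed when any of the following holds (all inequalities
strict): total non-spike-in counts < `min_total_counts` (default 500,000),
detected genes (raw count > 0) < `min_genes_detected` (default 3,000),
mitochondrial fraction > `max_mito_fraction` (default 0.10), its group is
under a deletion screen and its deletion-region read count exceeds
`deletion_region_max` (default 0), or its capture flag is empty /
multiplet / anomalous. The keep decision is a pure conjunction, so filter
order is irrelevant and tightening any threshold can only shrink the kept
set. Whether "total counts" should include spike-ins is genuinely
ambiguous; we exclude them, so the filters measure cellular RNA content.

The whole-transcriptome PCA outlier step replaces what is usually a visual
judgement with a deterministic rule: a cell is flagged when its PC1 or PC2
score (PCA of log2(count+1) on non-spike-in genes) lies more than `k_mad`
(default 6) normal-consistent MADs (1.4826 × raw MAD, the R `mad()`
convention) from the per-component median. At k = 6 the false-flag
probability on homogeneous data is well below 5% per run.

## Normalization

Median-of-ratios size factors (the DESeq estimator): s_j = median over
reference genes of k_ij / g_i, where g_i is the geometric mean across
cells and the reference contains only genes with a strictly positive count
in every cell. No post-hoc rescaling is applied, which means scaling one
cell by c changes all factors through the geometric-mean reference; the
invariant that is exact is the *ratio* form (s_j/s_k scales by c for the
scaled cell). Biological genes and spike-ins get separate factor sets from
the same estimator; spike-in factors track capture/sequencing efficiency
and are the denominator of the per-cell transcriptional-activity measure.
When no gene is positive in all cells the estimator refuses rather than
silently switching to a pseudo-reference.

## Technical noise and highly variable genes

The spike-in squared coefficient of variation is modelled as
CV²(μ) = a1/μ + α0 and fitted by a gamma-family GLM with identity link on
(CV², 1/μ). The fit is restricted to spike-ins with mean at or above a
data-driven cutoff — the 80th percentile of spike-in means among
spike-ins with CV² > 0.3 — which drops the lowest-expression species where
CV² estimates are dominated by sampling error. A negative fitted α0 is
clamped to zero with a warning; fewer than 10 usable spike-ins is an
error. The shot-noise scale used for biological genes is
ψ = ξ + (a1 − ξ)·mean(s_ercc/s_cell) with ξ = mean(1/s_ercc), i.e. a1
transferred to the biological size-factor scale.

The variability test compares each gene's sample variance v (m cells,
ddof 1) with the technical expectation plus a minimal biological
dispersion margin. With minBiolDisp = (minimal biological CV)², default
CV = 0.5:

    c = α0 + minBiolDisp + α0·minBiolDisp
    d = (μψ + μ²c) / (1 + c/minBiolDisp)
    T = (m−1)·v/d,   p = P[χ²(m−1) ≥ T]

BH adjustment runs over genes with μ > 0 (zero-mean genes get p = 1 and do
not enter the multiplicity count); the highly-variable call is
padj < 0.1. The "0.5" is interpreted on the CV scale (squared internally),
matching the convention of a 50% biological-CV margin; both the margin and
the call threshold are parameters.

Setting `min_biol_cv = 0` removes the margin and its normalising factor
entirely and tests the fitted technical law itself (d = μψ + μ²α0). This
margin-free mode is the package's calibration check: on data with no
biological variability its p-values are approximately uniform. Two
approximations bound that statement. First, the χ² law for (m−1)s²/σ² is
exact only for Gaussian data; overdispersed counts carry excess kurtosis
that inflates the spread of s² by roughly (1 + κ(m−1)/2m) — about 15% at
m = 100 with α0 = 0.05 — so the null p-values are slightly heavy in both
tails. Second, the fitted (a1, α0) enter every gene's denominator, so fit
error shifts the whole p distribution coherently. Together these put the
Kolmogorov–Smirnov distance from uniformity at roughly 0.02–0.12 for a
100-cell, 92-spike-in design, varying with the draw. The default margin
test is by construction conservative at well-expressed genes (the margin
dominates) and liberal below the shot-noise crossover μ ≈ ψ/c; the
"margin-free flags ⊇ margin flags" monotonicity therefore holds in the
α0-dominated regime (means ≳ 50 at the default noise scale) and is tested
there.

## Cell-cycle reconstruction

PCA uses log2(normalized count + 1), per-gene centering, no unit-variance
scaling, and a deterministic sign convention (summed loading of the S/G2M
marker panel made non-negative per component). Clustering is k-means on
the retained components (default 2) with 25 seeded starts; clusters are
relabelled C1..Ck by decreasing size so labels are reproducible. Because
published analyses of this kind often group cells by eye, a complete-
linkage hierarchical clustering on (1 − Pearson correlation) between cells
is run as a cross-check and its adjusted Rand index with the k-means
partition is reported, not enforced.

Stage labels come from marker panels (G0/early-G1: Cdkn1c, Txnip high,
Uhrf1 low; late-G1: Ccnd2, Ccne2, Cdk2; S: Rrm2, Mcm2/5/7, Ccna2, Uhrf1;
G2/M: Ccnb2, Cdk1, Ccnf, Prc1, Plk1, Mki67 — the canonical cyclin
oscillation plus quiescence markers). A cluster's score for a stage is the
mean cluster-average z-score of the panel genes ("low" genes negated);
each cluster takes its argmax stage, ties break toward the earlier stage
in cycle order with a warning, and clusters below `min_cells_for_label`
(default 5) are labelled undetermined. Panels are overridable via GMT
input.

Perturbed cells are *projected*: centered with the reference gene means,
multiplied by the reference loadings, and assigned the stage of the
nearest cluster centroid (Euclidean). Projection keeps a clean train/test
contract — the perturbed population cannot reshape the reference cycle —
and requires ≥ 80% of the embedding's gene list (missing genes are imputed
at the center). A joint-PCA alternative can be had by simply embedding the
pooled matrix. Occupancy contrasts use the two-sided Fisher exact test on
the 2×2 (in-stage-subset × group) table. Transcriptional activity is total
non-spike-in counts divided by the spike-in size factor, compared by
two-sided Wilcoxon rank-sum between the quiescent (G0/early-G1, late-G1)
and proliferative (S, G2/M) bins within and between groups; bins with
fewer than 3 cells are skipped with a warning.

## Lineage subpopulations

Cycle signal dominates total heterogeneity, so lineage structure is
embedded on a hematopoietic gene list with cycle-annotated genes removed.
Subgroups H1..Hk (default k = 4) come from seeded k-means and are
relabelled deterministically by descending mean z-scored expression of a
quiescence/self-renewal anchor panel (Cdkn1c, Txnip, Hlf, Mecom), so H1 is
always the most quiescent, lymphoid-competent-like subgroup rather than an
arbitrary k-means label. Regulator co-expression uses Spearman correlation
over cells (invariant to monotone per-gene transforms), complete linkage
on 1 − ρ, a cut at 2 clusters by default, and reports mean within- and
between-cluster correlation; constant regulators are dropped with a
warning.

## Enrichment statistics

GSEA: genes are ranked by signal-to-noise, (mean_A − mean_B)/(sd_A +
sd_B), each sd floored at 0.2×|its class mean| (0.2 absolute at mean 0),
descending with lexicographic tie-break. The running sum gains
|metric|^p/Σ_hits|metric|^p at set members (p = 1 by default) and loses
1/(N − N_hits) elsewhere; the enrichment score is the signed maximum
deviation. Because the hit and miss increments are small rationals, the
positive peak and negative trough magnitudes can tie exactly, making the
ES sign a tie-break convention (first extremum of the cumulative sum);
oracle comparisons therefore check the magnitude. Significance uses
phenotype-label permutations (default 1,000): nominal p is the add-one
smoothed same-sign tail fraction, NES divides ES by the mean same-sign
permuted |ES|, and the FDR q is the pooled-NES tail-ratio estimate capped
at 1. Positive NES means enrichment toward the first-listed class. With
fewer than about 7 cells per class phenotype permutation loses resolution;
the class-size floor is 3 and small designs should be read with that in
mind. ORA is the exact hypergeometric upper tail of the set/selection
overlap within a stated universe, BH-adjusted across sets.

## Synthetic-data generator

The generator emulates the study layout: two genotype groups (default 119
control, 61 knockout cells), 92 spike-in species with log-spaced pool
abundances (0.5–4,000 expected copies), per-cell library size lognormal
(sd-log 0.25) and spike-in capture efficiency lognormal (sd-log 0.1).
Counts are negative binomial with variance a1·mean (quasi-Poisson shot
noise, default a1 = 2.0) around a product of baseline mean, planted fold
changes, cell scale factors, per-gene biological noise (Gamma with
CV² = 1 for the 200 planted highly variable genes, 0 otherwise) and a
global multiplicative technical Gamma with CV² = α0 = 0.05 — the minimal
generative model whose spike-ins obey CV² ≈ a1/μ + α0 after size-factor
normalization.

Structure is planted as programs: four 100-gene cell-cycle stage programs
(log2 fold 3.0) that include the named marker genes, three 40-gene lineage
programs (lymphoid, mega-erythroid, granulocyte-macrophage; log2 fold 2.5)
including Bcl11a/Hlf/Mecom, Gfi1b/Gata1/Klf1 and Gfi1/Cebpa respectively,
plus 200 null cycle-annotated and 60 null hematopoietic genes so the
curated lists are not pure signal. Stage occupancy defaults to
(72, 14, 21, 10)/117 for the control — the published cluster composition
normalized over staged cells — and (0.33, 0.08, 0.40, 0.19) for the
knockout, whose S+G2/M mass is 0.59 against the control's 0.265. Group
composition is assigned by largest-remainder quota of the occupancy vector
and then shuffled: the study conditions state composition as realized
counts (a 119-cell control yields 73/14/22/10; a 61-cell knockout yields
36/61 proliferative cells), so the emulator reproduces those counts
exactly at the stated group sizes and only the arrangement is random. The
knockout additionally has its lymphoid program prevalence set to 0 (vs
0.35 in the control), a 1.5× global mean scale-up in its proliferative
cells, and deletion-region read counts of 0 except for a 5% leak fraction
(controls draw Poisson(20)); each effect is independently switchable.
Mitochondrial rows (10 `mt-` genes) are scaled to a 4% expected fraction,
and optional planted QC failures (low depth ×0.02, mito fraction 0.25,
anomalous capture flags) support filter testing. Baseline means are
lognormal around 150 (sd-log 1.0; program genes around 80, sd-log 0.6),
and planted highly variable genes are kept at means ≥ 50 because the
variability test's power is mean-dependent.

All randomness flows from one `numpy` Generator seeded by the config;
identical configs give byte-identical output. What the generator does
*not* emulate: dropout/zero inflation beyond NB sampling, ambient RNA,
doublets, batch effects, gene–gene correlation outside the planted
programs, and realistic gene counts per cell at the default 2,000-gene
scale (thresholds for synthetic QC runs are scaled accordingly). Passing
tests therefore demonstrate correctness of the statistical machinery under
the declared generative model, not robustness to every artefact of real
libraries.

## Pipeline and problem sizes

The orchestrated run executes simulate → qc → normalize → hvg → cycle →
lineage → enrichment; each stage's seed is derived from the root seed by
hashing the stage name, so toggling one stage never perturbs another's
draws, and the manifest records per-stage checksums, sizes and wall-clock
(re-running a config reproduces the checksums bit for bit). Routine runs
and the test suite use 100–300 cells and 500–2,000 genes with 92
spike-ins; calibration checks use 2,000 genes × 100 cells, parameter
recovery 200 cells, GSEA calibration 200 random sets × 1,000 permutations
over four independent null datasets, and ORA exactness a dense grid of
universes up to size 25. These sizes give stable estimates for every
reported quantity while keeping a full run in seconds on one core.
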