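# hscycle

Spike-in calibrated analysis of deep-coverage single-cell RNA-seq from a
hematopoietic stem cell (HSC) compartment: quality control, size-factor
normalization, detection of highly variable genes against an ERCC-derived
technical-noise model, transcriptomic reconstruction of cell-cycle
progression, projection of a perturbed (knockout) population onto the
reference cycle, lineage-priming subpopulation analysis, and from-scratch
gene-set enrichment statistics (GSEA and hypergeometric
over-representation).

The package is aimed at analysts working with plate/microfluidic scRNA-seq
(hundreds of cells, millions of reads per cell, ERCC spike-ins) who want
each step of this classic workflow as a tested, scriptable library call
rather than a chain of ad-hoc scripts and web services. A synthetic-data
generator with full ground truth makes every stage testable end to end
without any sequencing data.

## The statistics at the core

**Technical noise and highly variable genes.** Across cells, the squared
coefficient of variation of a spike-in with normalized mean expression
μ follows

    CV²_tech(μ) = a1/μ + α0,

fitted by a gamma-family GLM (identity link) on the spike-ins. A gene with
sample variance v over m cells is called *highly variable* when v exceeds
the technical expectation plus a minimal biological dispersion margin
(minimal biological CV = 0.5 by default), via

    T = (m−1) · v / d,      d = (μψ + μ²c) / (1 + c/minBiolDisp),
    c = α0 + minBiolDisp + α0·minBiolDisp,      p = P[χ²(m−1) ≥ T],

with Benjamini–Hochberg adjustment and a padj < 0.1 call threshold; ψ is
the shot-noise scale combining the spike-in size factors with a1.

**Cell-cycle staging.** PCA of log2(normalized count + 1) over a curated
cycle gene list, seeded k-means into clusters C1..C5, and marker-panel
z-scoring that labels each cluster G0/early-G1 (Cdkn1c, Txnip high; Uhrf1
low), late-G1 (Ccnd2, Ccne2, Cdk2), S (Rrm2, Mcm2/5/7, Ccna2, Uhrf1) or
G2/M (Ccnb2, Cdk1, Ccnf, Prc1, Plk1, Mki67). Perturbed cells are projected
onto the reference embedding and inherit the stage of the nearest cluster
centroid; occupancy shifts are tested with Fisher's exact test, and
per-cell transcriptional activity (total counts on the ERCC size-factor
scale) with rank-sum tests.

**Enrichment.** GSEA with the weighted Kolmogorov–Smirnov running sum
(signal-to-noise ranking, weight 1), phenotype-label permutations, NES and
the pooled-NES FDR; plus an exact hypergeometric over-representation test.

## Worked example

```python
import hscycle as h

cfg = h.default_config(seed=11)            # 119 WT + 61 KO cells, 92 spike-ins
matrix, meta, truth, sets = h.simulate_experiment(cfg)

sf = h.compute_size_factors(matrix)
norm = h.normalize(matrix, sf)

wt = list(meta.groups.index[meta.groups == "WT"])
ko = list(meta.groups.index[meta.groups == "KO"])
emb = h.pca_embed(norm[wt], sets["cell_cycle"])
clusters = h.cluster_embedding(emb, k=5, seed=1)
model, wt_stage = h.assign_cluster_stages(clusters, norm[wt], groups=meta.groups)
ko_stage = h.project_and_classify(emb, model, norm[ko], groups=meta.groups)

comp = h.compare_occupancy(ko_stage, wt_stage, stages=("S", "G2/M"))
print(f"KO proliferative: {comp.fraction_a:.1%}  "
      f"WT proliferative: {comp.fraction_b:.1%}  Fisher p = {comp.p_value:.2g}")
```

prints

```
KO proliferative: 59.0%  WT proliferative: 26.9%  Fisher p = 9.9e-05
```

— the knockout population sits overwhelmingly in the proliferative (S and
G2/M) region of the reference cycle, while the control is dominated by
quiescent G0/early-G1 cells. Running GSEA of the planted lymphoid
signature between the groups (`h.gsea(..., classes=("WT", "KO"))`) yields
NES ≈ +1.7 at p < 0.01: lymphoid-program expression is significantly
depleted in the knockout.

The same pipeline is available from the shell:

```
hscycle simulate --seed 3 --outdir sim
hscycle qc sim/counts.tsv sim/cell_metadata.tsv --gene-annotation sim/gene_annotation.tsv \
        --min-total-counts 100000 --min-genes 500 --deletion-screen-group KO
hscycle hvg sim/counts.tsv
hscycle cycle sim/counts.tsv sim/gene_sets.gmt
hscycle run --seed 2 --outdir runout      # simulate → … → enrichment, with manifest
```

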