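# micronetfun

Soil microbiome association networks, function-supporting taxa, and
ecosystem multifunctionality.

## The problem

Soil microbiomes are enormously diverse, and much of that diversity is
noise with respect to any particular ecosystem function.  When a soil
community is progressively simplified — for example by inoculating sterile
microcosms with soil passed through ever finer filters — plant nutrient
uptake, litter decomposition and nutrient retention degrade.  `micronetfun`
implements the analysis chain used to dissect *why*: it asks whether the
loss of function tracks the loss of taxa per se, the loss of taxa that
support specific functions, the loss of diversity among those supporters,
or the collapse of the co-occurrence network that binds fungal and
bacterial communities together.

The package is aimed at microbial ecologists with OTU tables (16S + ITS),
per-sample ecosystem function measurements, and a treatment design; and at
methodologists who want the full pipeline runnable on synthetic data with
planted ground truth.

## What it computes

1. **Meta-network inference.** A sparse association graph over all OTUs by
   Meinshausen–Bühlmann neighborhood selection (per-node lasso, penalties
   scaled so a single-predictor solution is the soft-thresholded
   correlation `sign(r)·max(|r|−λ, 0)`), with the penalty chosen by StARS:
   over 100 random subsamples and a 50-value λ path, per-edge instability
   `2θ̂(1−θ̂)` is averaged over all possible edges and the densest graph
   whose monotonized instability stays ≤ 0.05 is kept.  Per-sample
   subnetworks are induced on the detected taxa, and *complexity* is
   linkage density (links per OTU) among bacteria, fungi, cross-kingdom, or
   all taxa.
2. **Function-supporting taxa.** Per ecosystem function, elastic-net
   selection over all taxa jointly — α from 0 to 1 in steps of 0.01, a
   100-value λ path per α, leave-one-out CV, minimum-MSE refit — classifies
   taxa with nonzero coefficients as supporting or inhibiting (loss-type
   functions such as leaching and N₂O emission are sign-inverted first).  A
   per-taxon permutation test (95% central null range) is the single-taxon
   cross-check.
3. **Diversity indices.** Functional redundancy (mean number of co-occurring
   supporters per function), functional uniqueness (Rao's quadratic entropy
   Q = Σᵢⱼ pᵢpⱼdᵢⱼ times the inverse Simpson index 1/Σpᵢ², on Jaccard
   distances between binary support profiles), function-combination
   coverage curves, and *functional complexity* (linkage density among
   co-detected taxa that support a common function).
4. **Multifunctionality and statistics.** Averaging and PCA-weighted
   multidimensional multifunctionality indices; standardized regressions
   (SES = Pearson r, with SE, P, R²), richness-detrended variants,
   sequential (Type-I) ANOVA variance partitions, and treatment ANOVA with
   Tukey HSD letters.
5. **Synthetic data.** A generator that emulates the whole study — latent
   Gaussian copula with a planted sparse partial-correlation graph, nested
   taxon-loss gradient (6 levels, n = 50), multinomial sequencing counts,
   and functions built from planted supporter taxa — returning the ground
   truth needed to score every stage.

## Worked example

```python
import micronetfun as mnf

cfg = mnf.PipelineConfig(out_dir="demo_run", seed=7)
res = mnf.run_pipeline(cfg)        # simulate -> preprocess -> network
                                   # -> support -> indices -> analyze
print(res.network.summary())
```

```
Meta-network (MB neighborhood selection + StARS)
================================================
OTUs:                  100
Edges (unordered):     270
Connectedness:         5.40% (540 / 10000 ordered links)
Selected lambda:       0.258759 (index 14 of 50)
Instability at lambda: 0.0461 (threshold 0.05)
Threshold met:         True
```

The StARS-selected meta-network over the 100 simulated OTUs has 270
associations (5.4% of the p² ordered-pair universe).  The multifunctionality
model reports how consistent the two aggregate indices are:

```python
print(res.multifunctionality.summary())
```

```
Multifunctionality indices
================================================
Samples:                    50
Averaging index grand mean: -8.88e-18
Pearson r (avg vs multidim): 0.943 (P = 1.41e-24)
```

and the regression surface ties network complexity to functioning — here
the functional-complexity → multifunctionality regression over all taxa:

```
characteristic         pairing    variant  SES    SE     P         R2
functional_complexity  Among all  plain    0.694  0.104  2.28e-08  0.482
```

i.e. microcosms whose detected, function-supporting taxa are more densely
interlinked score about 0.69 SD higher in multifunctionality per SD of
functional complexity — the planted positive coupling, recovered end to
end.  Every stage also writes TSVs (`network_edges.tsv`,
`support_map.tsv`, `sample_indices.tsv`, `table1_regressions.tsv`,
`table2_anova.tsv`) plus a `manifest.json` with versions, seeds and
parameters.

A CLI mirrors the stages:

```bash
micronetfun simulate --out demo --seed 7
micronetfun preprocess --otu demo/otu_counts.tsv --out demo
micronetfun network --otu demo/otu_standardized.tsv --out demo
micronetfun all --seed 7 --out demo_full
```

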