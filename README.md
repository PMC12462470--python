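# sskit — super-silencer analysis toolkit

`sskit` identifies **super-silencers (SSs)** — clusters of silencer elements
carrying exceptionally strong repressive H3K27me3 signal — and characterizes
their biology: cooperativity among the silencers inside one SS region,
CpG-island and TAD-geometry context, enrichment of disease variants, and the
functional conversion of normal-cell SSs into cancer **super-enhancers (SEs)**
across patient samples. It is aimed at regulatory-genomics analysts working
with silencer/enhancer calls, ChIP-seq peak sets, Hi-C contacts/TADs and
somatic/germline variant tables, and it ships a synthetic-data generator with
a ground-truth manifest so the entire pipeline is testable without any
downloads.

## The methods

**Super-region calling (rank ordering).** Elements on each chromosome are
stitched into regions when the gap between them is ≤ 12.5 kb. Region totals
(the sum of constituent H3K27me3 signal; H3K27ac for enhancers) are sorted
ascending, ranks and totals are scaled to the unit square, and the cutoff is
the rank farthest below the diagonal,

    c = argmax_i ( x_i − y_i ),   x_i = i/(n−1),   y_i = (t_i − t_min)/(t_max − t_min),

the discrete analogue of the slope-1 tangent. Regions with total strictly
above the total at rank *c* are super; their member elements are
**SS components**, everything else **typical silencers (TSs)**.

**Cooperativity.** Each element gets a ternary activity per cell type
*k* ∈ *K*: a = 1 if it overlaps an H3K27ac peak only, −1 if H3K27me3 only,
0 if both or neither. Activity cooperativity of elements *i, j* is the cosine

    coop(i,j) = Σ_k a_ik a_jk / (√Σ_k a_ik² · √Σ_k a_jk²),

and TF-binding similarity is the Jaccard index of binary occupancy vectors
over the TF panel *G*:

    sim(i,j) = Σ_g t_ig t_jg / Σ_g (t_ig + t_jg − t_ig t_jg).

Within-region pairs are compared against TS pairs sampled to match the
within-pair distance distribution and against random TS pairs
(one-sided Wilcoxon rank-sum, no adjustment).

**Annotation.** CGI status (overlap > 200 bp with a CpG island, strict), TAD
section from the element midpoint to the nearest TAD boundary (≤ 20 kb
boundary, 20–50 kb shore, beyond center), nearest gene by TSS distance,
contact-linked genes via 10-kb Hi-C anchors, tissue specificity
τ = Σ_i (1 − x_i/max x)/(N−1), and mean CpG methylation.

**Variant enrichment.** Density per kb over merged element footprints,
category fractions (e.g. B-cell-cancer SNVs among all cancer SNVs) with
two-sided binomial tests, exact density-ratio confidence intervals, GWAS LD
expansion at r² > 0.8 (strict, single pass), replicated-SNP (≥ 2 studies) and
recurrent-SNV (≥ 2 samples) fractions, and translocation-partner
classification with SS > SE > TS > TE precedence.

**Conversions.** An SS component "converts" (SS-to-SE) when it overlaps a
cancer-sample SE region in ≥ 1 sample; a conversion is *recurrent over half*
when it hits strictly more than half of the samples. Chromatin-contact
retention is the fraction of element-anchored contacts whose 10-kb bin pair
persists in a second condition, with a permutation null over matched
elements.

## Worked example

```python
import sskit

bundle = sskit.generate_bundle(seed=7)        # synthetic B-cell-like dataset
summary = sskit.run_pipeline(bundle, seed=7)  # every stage, one dict
```

On this bundle the pipeline prints (rounded):

| quantity | value | meaning |
|---|---|---|
| `n_regions` | 379 | stitched silencer regions |
| `n_super_silencer_regions` | 27 | regions above the elbow cutoff |
| `n_ss_components` | 161 | silencers inside SS regions |
| `coop_within_median` | 0.286 | median cosine cooperativity, within-SS pairs |
| `coop_matched_median` | 0.000 | same for distance-matched TS pairs |
| `bcc_snv_fold_components_vs_typicals` | 3.16 | B-cell-cancer SNV density fold, SS components vs TSs |
| `converted_fraction` | 0.130 | SS components overlapping a cancer SE in ≥ 1 sample |
| `recurrent_over_half_fraction` | 0.286 | converted components hitting > half of samples |
| `contact_retention_components` | 0.121 | SS-component contacts persisting in the cancer condition |
| `tau_ss_proximal_median` | 0.794 | tissue specificity of SS-proximal genes (all genes: 0.433) |

The bundle's manifest records what was planted (super clusters, a 3-fold
variant enrichment, a 13% conversion fraction with 0.25 recurrence, activity
correlation ρ = 0.6), so the recovery table shows the pipeline finding what
the generator hid:

```python
report = sskit.plant_report(bundle.manifest, summary, seed=7)
print(report)          # planted vs recovered, pass/fail per quantity
```

The same stages are available from the shell:

```sh
ssk simulate --seed 7 --out data/
ssk call --elements data/silencers.tsv --mark H3K27me3 --out-prefix run1
# -> "379 regions, 27 super, 161 components"
ssk convert --elements run1.components.bed --cancer-dir data/cancer_se --out-prefix run1
# -> {"n_converted": 21, "converted_fraction": 0.130..., "recurrent_over_half_fraction": 0.286...}
ssk run-all --data data/ --out report/ --seed 7
```

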