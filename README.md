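# ceqtl

Copy-number expression QTL (ceQTL) mapping for radiation-hybrid-style
panels. The package simulates RH-like panels with planted ground truth,
normalizes aCGH copy-number log-ratios, maps cis/trans dosage effects on
expression with a permutation-calibrated linear model, and runs the
downstream statistics (trans hotspots, noncoding blocks, cross-dataset
sign concordance, X-attenuation, correlation-structure comparison).

## Modules

| module | contents |
| --- | --- |
| `ceqtl.genome` | genome definition (chromosomes, markers, genes, centromeres, selectable locus) |
| `ceqtl.synthetic_panel` | panel simulator: donor fragments, binary copy state, bimodal aCGH ratios, expression with planted cis/trans effects and X attenuation |
| `ceqtl.cgh_processing` | sliding-window smoothing, bimodal mode fitting, affine normalization, retention calling, legacy-genotype concordance, centromere test, copy-number binning |
| `ceqtl.ceqtl_mapping` | OLS dosage model with F test, pooled permutation null, empirical P, cis/trans classification, per-class Benjamini–Hochberg FDR, marker variability filter, peak finding |
| `ceqtl.downstream_stats` | Poisson hotspot FDR, noncoding peak filtering/merging, one-to-one block matching, sign concordance chi-square, paired X-attenuation test, 1 Mb bin overlap, closest-gene assignment |
| `ceqtl.matrix_comparison` | gene-gene correlation matrices, Frobenius distance, gene-label permutation test |
| `ceqtl.io_cli` | TSV matrix / BED / truth-file I/O, replicate averaging, pipeline config, CLI |

## CLI

```sh
# simulate a panel (writes raw dosage, expression, truth, gene BED)
ceqtl simulate --n-clones 79 --n-genes 200 --n-markers 2000 \
    --seed 1 --out-prefix scratch/panel

# smooth + mode-normalize the raw dosage matrix
ceqtl normalize --dosage scratch/panel.dosage_raw.tsv --out scratch/panel.norm.tsv

# map ceQTLs (pooled permutation null, per-class BH FDR)
ceqtl map --expression scratch/panel.expression.tsv \
    --dosage scratch/panel.norm.tsv --n-perm 5 --trans-stride 25 \
    --seed 1 --out scratch/records.tsv

# hotspots + noncoding blocks from a record table
ceqtl downstream --records scratch/records.tsv \
    --genes-bed scratch/panel.genes.bed --out-prefix scratch/ds

# correlation-structure distance to a reference expression compendium
ceqtl compare --expression scratch/panel.expression.tsv \
    --reference ref.tsv --n-perm 10000 --seed 1 --out scratch/compare.json
```

All interchange formats are plain text: matrices are TSV with leading
annotation columns (`marker_id/chrom/position/chrom_class` for dosage,
`gene_id/chrom/start/end` for expression) and one column per clone;
intervals are BED (0-based, half-open). Every command writes a manifest
(config hash, seed, versions) next to its output.

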