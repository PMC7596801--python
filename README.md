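# sctfa

Tree-guided multi-task regression of single-cell gene expression on
transcription-factor (TF) features, with downstream interpretation of the
fitted coefficients as cell-specific TF activities.

Each cell is one regression task: given a genes × TF-features matrix `X`
(motif binding affinities, open-chromatin-restricted affinities, or ChIP-seq
counts near each gene's TSS) and a genes × cells expression matrix `Y`
(log2 TPM), the package fits `Y = X B` with a tree-structured group-lasso
penalty whose groups are the leaf sets of a task tree over the cells, so
related cells share selected TFs. The fitted `p × k` coefficient matrix `B`
is then interpreted per TF: heat-map selection, activity ranking,
differential activity between cell types (Mann–Whitney + BH), and Spearman
correlation of a TF's own expression with its inferred activity, filtered
against a permutation null.

## Layout

| module | purpose |
| --- | --- |
| `sctfa.features` | static / dynamic / ChIP-seq gene × TF feature matrices (PWM affinity scanning, distance decay, interval overlap) |
| `sctfa.preprocess` | detected-gene filter, feature-variance filter, unexpressed-TF removal, log2 transform, standardization, 60/40 gene split |
| `sctfa.trees` | task trees: hierarchical clustering (1 − Pearson, complete linkage), 2-D embedding clustering, star baseline, per-cell expression shuffling; node groups and weights |
| `sctfa.models` | single-task elastic net, joint row-sparse regression, tree-guided group lasso (monotone FISTA with an exact laminar-group proximal operator), cross-validation, prediction, per-cell Pearson evaluation |
| `sctfa.interpret` | per-TF summaries: heat-map selection, activity ranking, differential activity, TF-expression correlation, permutation-null and sign-agreement filters |
| `sctfa.simulate` | seeded synthetic fixtures: regression (planted block-sparse coefficients), TPM with dropout, genomic (genome + motifs + peaks) |
| `sctfa.io`, `sctfa.pipeline`, `sctfa.cli` | TSV/MTX/FASTA/PFM/BED/narrowPeak/Newick readers and writers, YAML run config, end-to-end runner, `sctfa` CLI |

## CLI

```sh
# generate a synthetic data set (presets: regression | tpm | genomic)
sctfa simulate --preset regression --seed 1 --out sim/

# build feature matrices from genomic inputs
sctfa features --flavour static --genome genome.fa --annotation genes.bed \
    --pwms motifs.pfm --out static.tsv

# filters, tree construction, training, interpretation
sctfa filter --expression expr.tsv --features static.tsv --out-dir filtered/
sctfa tree --expression sim/expression.tsv --variant hc --out tree.nwk
sctfa train --features sim/features.tsv --expression sim/expression.tsv \
    --tree tree.nwk --model tree --lambda-grid 0:1:0.05 --folds 5 --seed 1 \
    --out-dir fit/
sctfa interpret --fit fit/ --labels sim/labels.tsv --out report.tsv

# or the whole pipeline from a YAML config
sctfa run --config config.yaml [--subsample-cells 0.5]
```

A config file names the input paths, tree variant (`hc`, `embedding`,
`star`, `shuffled`), model (`stl`, `omtl`, `tree`), hyperparameter grid,
filter parameters, and seed; see `sctfa.pipeline.RunConfig` for all fields
and defaults.

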