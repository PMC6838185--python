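# stagecorr

Cross-species comparison of developmental transcriptomes: stage-by-stage
interspecies Pearson correlation matrices for homologous gene sets, the
average diagonal correlation **AC**, and the resampling/permutation matrix
diagonality statistic **MD**.

## The problem

When two species' embryonic time courses are profiled by RNA-seq, one can ask
whether 1:1 homologous genes are most similar in expression at
*morphologically equivalent* stages.  For an aligned set of stages, the
matrix

```
C_ij = Pearson r over n_g homolog pairs ( expression at stage i in species 1,
                                          expression at stage j in species 2 )
```

is diagonal-banded when expression conservation tracks developmental
equivalence — the signature of developmental control genes — and uniformly
high when genes are expressed everywhere regardless of stage (housekeeping
genes).  Two summaries quantify this:

- **AC** — the mean of the diagonal elements `C_ii`; 1 is perfect correlation
  at every pair of equivalent stages, 0 is none.  The diagonal profile
  `C_11 … C_nn` also locates the stage of maximal conservation (under the
  hourglass model, a mid-developmental/phylotypic stage).
- **MD** — how *significantly* diagonal C is.  For each of `n_resamp = 100`
  subsamples of `n_g = 50` genes, C is compared to the ideal diagonal matrix
  I (1 on the diagonal, 0 elsewhere) through `d = Σ_ij (C_ij − I_ij)²`, and a
  permutation test (`n_perm = 1000` random reorderings of one species' stage
  columns) asks whether the observed stage alignment is closer to I than
  chance relabelings.  MD is the count of subsamples significant at
  α = 0.05: 100 is maximal diagonality, 0 none.

The package reads per-species FPKM tables (stages × replicates), strict
1:1(:1) homolog maps and gene-set membership lists as TSV, and ships a
synthetic cohort generator that emulates stage-peaked versus
housekeeping expression at a tunable evolutionary divergence, so the whole
pipeline is testable without any downloads.

## Worked example

Generate a two-species cohort (500 developmental + 200 housekeeping genes, 7
stages × 3 replicates, divergence 0.2, log-normal replicate noise) and run
the full report:

```
$ stagecorr simulate --out-dir cohort --seed 42
$ stagecorr report --config run.yaml
```

with `run.yaml`:

```yaml
expression_a: cohort/expression_spA.tsv
expression_b: cohort/expression_spB.tsv
species_a: spA
species_b: spB
homologs: cohort/homologs.tsv
gene_sets: cohort/gene_sets.tsv
diagonality: {seed: 42}
out_dir: out
```

`out/summary.tsv` (one row per gene set, sorted by MD descending):

```
set            n_genes  AC      AC_sd   peak_stage  MD   median_p  d_median
developmental  500      0.9633  0.0025  60 hpf      100  0.0090    5.42
housekeeping   200      0.9873  0.0014  20 hpf      10   0.3072    19.46
```

Both gene classes correlate strongly between the species (AC ≈ 0.96–0.99),
but only the developmental set is *diagonal*: every one of its 100 gene
subsamples beats the permutation null (MD = 100), while the housekeeping
block — uniformly high correlations at matched *and* mismatched stages —
rarely does (MD = 10).  Per-set correlation matrices are written alongside
(`out/correlation_<set>.tsv`), each with the seed and a config hash in `#`
header comments so a rerun with the same config is byte-identical.

The `correlate` and `md` subcommands expose the two halves individually;
`stagecorr <cmd> --help` documents the options, including `--raw` (skip the
default log10(FPKM+1) transform), `--align` (explicit stage-label alignment
between species with unequal staging) and `--stage-window` (the MD test
defaults to the last 5 aligned stages).

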