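# Methods

## Pipeline

Inputs are per-species gene × sample FPKM tables (tab-separated, one header
row, sample columns named `<stage label>|<replicate id>` with the stage label
beginning `<number> hpf`), a strict 1:1(:1) homolog map, and optional
gene-set membership lists.  Processing order:

1. **Replicate averaging.** Each stage's value is the arithmetic mean of its
   replicates' FPKM, taken on the raw scale before any transform.  Stages are
   ordered by hours post fertilization.
2. **Transform.** Correlations are computed on `log10(FPKM + 1)` by default.
   Raw FPKM is heavy-tailed, and Pearson r across genes would otherwise be
   dominated by a handful of very high expressors; the unit pseudocount keeps
   zeros at zero.  A `--raw` switch disables the transform.
3. **Restriction.** Homolog records are intersected with the two tables and,
   optionally, a gene set (interpreted in the namespace of the homolog map's
   first species).  Stage columns are paired through an explicit, declared
   alignment of stage labels; the alignment must be order-preserving and
   never reuse a stage.  Inferring alignments from developmental rates is out
   of scope — they are user input.
4. **Correlation.** `C_ij` is the Pearson correlation across the homolog
   pairs between stage i of species 1 and stage j of species 2.  A
   zero-variance column yields r = 0 with a warning rather than an error:
   an all-equal expression column carries no stage-discriminating signal,
   and aborting would make resampled subsets fragile.
5. **AC.** Mean (and sample sd) of the diagonal of a square C, plus the
   diagonal profile and its argmax stage (ties broken toward the earliest
   stage — an arbitrary, documented rule).  AC uses the full displayed
   alignment; the MD test applies its own stage window.
6. **MD.** See below.

"Expressed" means FPKM strictly greater than a threshold (default 3) at one
or more stages.  The presence partition classifies every homolog record into
the 2^k Venn regions of which species express it; a gene absent from a table
counts as not expressed there, and region sizes always sum to the homolog
count.

## The MD test

For a gene subsample, the stage correlation matrix C over the configured
stage window (default: the last 5 aligned stages, the late embryonic part of
the time course) is compared to the ideal time-dependent matrix I (identity)
through the squared Frobenius distance `d = Σ(C − I)²`.  The exact
functional form of d is implementation-defined; any strictly monotone
transform of it produces the identical permutation p-value, so the choice
only affects the reported d values.

The permutation null shuffles the stage-column order of one species' matrix
only.  This relabels which stages count as "equivalent" while preserving
each species' per-stage expression distributions exactly — the null
hypothesis being "no preferential correlation at morphologically equivalent
stages".  Since column permutation changes d only through the permuted
diagonal trace (`d(π) = ‖C‖² − 2·Σ_i C[i,π(i)] + n`), the null distribution
is computed from a single C per subsample; this shortcut is unit-tested
against naive per-permutation recomputation.

The Monte-Carlo p-value uses the add-one estimator
`p = (1 + #{d_null ≤ d_obs}) / (1 + n_perm)`: it can never report 0, and is
exactly 1 when the columns are exchangeable.  With exhaustive enumeration
(available for small stage counts) the exact full-group p-value
`#{d_null ≤ d_obs}/n!` is reported instead; the identity order belongs to
the group, so the minimum is 1/n!, and the add-one Monte-Carlo estimate
converges to this value.  Significance is strict (`p < α`, default
α = 0.05).

MD is the number of significant subsamples out of `n_resamp = 100` draws of
`n_g = 50` genes without replacement (defaults; configurable).  One seeded
generator drives the gene draws and per-subsample permutation streams are
split from it, so results are exactly reproducible under a fixed seed.  If
fewer than `n_g` genes are available the test errors unless explicitly
allowed to use all genes every iteration (which suppresses resampling
variance).

**Calibration caveat.** The n_resamp p-values are exchangeable but not
independent when the gene pool is small relative to n_g: subsamples overlap,
and a chance dataset-level alignment inflates or deflates the conditional
rejection rate even under the null.  Calibration (rejection rate ≈ α under
exchangeable stage columns) therefore holds marginally over datasets, and
conditionally only when the pool is large enough that subsamples are
effectively disjoint; the test suite checks it with a 100 000-gene pool.

## Synthetic cohorts

The generator emulates the *processed product* of a comparative RNA-seq time
course — two species' non-negative FPKM tables over a shared 1:1 homolog set
— not the sequencing process itself (no read counts, library-size or batch
effects, and no three-species phylogenetic covariance; a third species is
made by running the generator twice against species 1).

- **Developmental genes** have a Gaussian bump in log10 expression,
  `baseline + amplitude·exp(−(s − s*)²/2w²)`, with peak stage s* drawn per
  gene (uniform by default; an optional weight vector concentrates peaks at
  a planted phylotypic stage) and width w = 1 stage — the simplest profile
  family that produces a diagonal C.  The second species' profile is the
  mixture `(1−δ)·(species-1 profile) + δ·(independently drawn profile)`;
  the divergence δ ∈ [0, 1] spans identical regulation to full independence.
- **Housekeeping genes** share one monotone increasing trend
  `baseline + amplitude·s/n_stages` plus a gene-specific N(0, 0.5) offset,
  identical in both species, so their interspecies correlations are
  uniformly high with no diagonal preference.  δ is not applied to them by
  default (an `hk_divergence` flag changes that), keeping the two classes'
  MD behavior cleanly separated.
- **Replicates** multiply FPKM by 10^ε with ε ~ N(0, σ): log-normal noise,
  matching the multiplicative character of FPKM replicate scatter.

Defaults — 500 developmental + 200 housekeeping genes, 7 stages × 3
replicates, δ = 0.2, σ = 0.1, baseline 1.0 log10-FPKM (10 FPKM) and
amplitude 2.0 (peaks near 1000 FPKM, all genes comfortably above the
expressed threshold) — describe a mid-sized echinoderm-style time course and
keep every pipeline stage exercised in seconds.

What passing tests on these cohorts show: the statistics behave as defined
(AC endpoints, MD bounds and calibration, class separation, monotone decay
of AC and MD with δ, recovery of a planted phylotypic stage).  What they do
not show: robustness to mapping noise in real homolog calls, batch effects,
unequal stage sampling between species, or non-Gaussian temporal shapes.

The phylotypic-stage recovery check plants half the developmental peaks at
the middle stage with δ = 0.3 and σ = 0.3: nonzero divergence/noise is what
lets the diagonal profile differentiate stages (at δ = σ = 0 every C_ii ≈ 1
and the argmax is meaningless), and concentration must be partial, since
identical peaks for all genes would remove the cross-gene variance that the
correlation is computed from.

## Numerical and design notes

- Pearson r uses population-variance z-scoring in the vectorized path; every
  cell is property-tested against an independent scipy `pearsonr` call.
  Entries are clipped to [−1, 1] against floating-point overshoot.
- Matrix TSVs round-trip bit-identically (`float_precision="round_trip"`).
- Readers never silently drop records: duplicate identifiers, negative,
  missing or non-numeric values, ragged homolog lines and unannotated sample
  columns are hard errors naming the offending cell.
- Whether the upstream study called "expressed" at FPKM > 3 or at the
  CPM-based pre-normalization filter is not recoverable; the FPKM rule is
  the default and the threshold is exposed.
- Report summaries sort by MD descending, ties by AC descending, and embed
  the seed and a configuration hash in `#` comments for provenance.
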