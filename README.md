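# s2f

A desk-scale, fully self-contained pipeline for studying individual-level
protein-expression prediction from personalized genome sequence:

- **`s2f.synthetic_data`** — generates every input the pipeline consumes:
  a reference window, cohort genotypes with a rare-heavy allele-frequency
  spectrum (optionally with block LD), a continuous NPX-like phenotype with
  a planted genetic architecture (additive effects at a target cis-h²,
  controllable rare-variant variance share, optional epistatic pairs),
  covariates, protein-altering consequence flags, chromatin-state and cCRE
  annotation tracks, and PWMs.
- **`s2f.genome_encoding`** — batch reconstruction of personalised L×4
  one-hot matrices from a variant table + reference with the 0 / 0.5 / 1
  dosage convention, TSS-centred window extraction from FASTA, and
  MAF-threshold masking ("rare-masked genomes").
- **`s2f.cohort_prep`** — per-gene exclusion of protein-altering variant
  carriers, protein selection criteria, and the shared 60/20/20 split.
- **`s2f.baseline_en`** — the elastic-net baseline on the dosage matrix
  (fixed L1 ratio 0.5, validation-selected penalty), the held-out-R²
  cis-heritability proxy, and the nonzero-support size that calibrates
  high-scoring-variant sets.
- **`s2f.s2f_model`** — a trainable sequence-to-expression surrogate:
  a configurable 1-D convolutional trunk with a position-resolved readout,
  pooled-embedding head with covariate concatenation + LayerNorm +
  MLP(512), the composite loss (alpha·MSE + (1−alpha)·pairwise-difference
  MSE, alpha = 0.5), AdamW with 10% linear warm-up and cosine decay,
  gradient accumulation, and single-gene / multi-gene (pairwise-only,
  covariate-free shared head) training schemes. Implemented in pure
  numpy with manual backpropagation (no GPU framework required).
- **`s2f.ism_hsv`** — in-silico saturation mutagenesis maps, high-scoring
  variant (HSV) selection matched to the elastic-net support size, and
  single-variant effect prediction.
- **`s2f.functional_annotation`** — chromatin-state enrichment
  (observed/expected aggregated across genes), cCRE overlap fractions,
  an internal PWM scanner (log₂-odds, exact DP p-values on a 0.01-bit
  lattice, BH correction, loss/gain/weaken/strengthen calls), and
  LD-redundancy fractions (r² > 0.8).
- **`s2f.evaluation`** — R²/PCC/Spearman metrics, rare-variant masking
  experiments, nested downsampling with matched optimizer update counts,
  multi-gene seen/unseen-gene evaluation, and effect-size agreement
  against the planted truth.
- **`s2f.cli_io`** — FASTA/VCF/TSV/BED/MEME readers and writers, YAML
  configuration, and the checksummed pipeline driver.

## Command line

```bash
s2f run-all --out demo_out --seed 1           # full pipeline on synthetic data
s2f simulate --config sim.yaml --out DIR --seed 3
s2f mask-eval --maf 0.05
s2f downsample --sizes 100,200
s2f multigene --genes 3 --individuals 150
s2f --help
```

Stage subcommands (`simulate`, `encode`, `prep`, `baseline`, `train`,
`ism`, `annotate`, `evaluate`) re-run deterministically from the config
and seed. A YAML config controls window length, cohort size, planted
architecture and training hyperparameters; `--scale desk|full` switches
between the desk-scale defaults and the full-scale settings (49,152-bp
windows, effective batch 256).

Every run writes a `manifest.json` with the package version, seed, config
hash and SHA-256 checksums of all outputs; reruns with the same config
and seed are bit-identical.

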