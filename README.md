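# tfap

Transcription-factor (TF) activity profiling toolkit: a tested, reusable
pipeline from reporter-based TF activity quantification and behavioral
phenotyping through differential expression and motif-based regulon
prediction to TF-activity / downstream-expression integration.

A TF-activity reporter construct expresses a reporter gene from a minimal
promoter with TF binding sites alongside a constitutively expressed
reference gene; the reporter:reference transcript ratio measures the TF's
transcriptional activity. Batteries of up to six constructs per animal,
normalized to within-experiment controls, are pooled into a TF-activity
profile (TFAP). Coupling the TFAP to expression changes of each TF's
predicted regulon (promoter motif hits) ranks candidate driver TFs.

Every stage is exercised end to end on a synthetic-data generator with
known ground truth (latent per-group TF activities, reporter batteries,
TF-weighted log-linear transcriptomes, social-interaction behavior coupled
to driver TFs, promoters with implanted binding sites, and qPCR standard
curves), so no external data are required.

## Modules

| module | role |
| --- | --- |
| `tfap.synthetic` | ground-truth cohort simulation (seeded, deterministic) |
| `tfap.quantify` | qPCR standard curves, absolute copies, raw reporter activity |
| `tfap.activity` | control normalization, TFAP assembly, group log2FC, Welch t, Monte-Carlo Dunnett, per-cell high/low calls |
| `tfap.behavior` | SI-rate, outlier rule (> 4 excluded), susceptible/resilient cutoff (< 1 / >= 1), day-wise normalization, Hedges' g, binomial recovery test with Holm correction |
| `tfap.transcriptome` | TPM, Welch-based DE with BH, DEG rule (p < 0.05 and FC > 2 or < 0.5), row scaling |
| `tfap.regulon` | promoter extraction (BED6 + FASTA), PWM log-odds scanning, regulon maps, JASPAR I/O |
| `tfap.integration` | activity/regulon coupling, hypergeometric enrichment, rank-sum shift, F-test variance broadening, driver ranking, activity-behavior Pearson |
| `tfap.pipeline` / `tfap.cli` | configured, seeded orchestration with a checksummed run manifest |

## CLI

```bash
# full synthetic run: simulate -> quantify -> profile -> behavior ->
# de -> regulon -> integrate, with a manifest of output checksums
tfap run --config cfg.yaml --seed 1 --out runs/demo

# single stages (prerequisites are rerun deterministically)
tfap simulate --seed 1 --out runs/demo
tfap regulon  --seed 1 --out runs/demo

# configuration linting (unknown keys, ranges, stage dependencies)
tfap validate --config cfg.yaml
```

The YAML config has one block per stage; every parameter has a default
(see `tfap.pipeline.DEFAULT_CONFIG`), so an empty config is valid. All
randomness flows from one root seed fanned out into per-component child
streams; identical config + seed reproduces byte-identical outputs.

Example config:

```yaml
seed: 1
simulate:
  n_tfs: 30
  n_genes: 1000
  n_animals_per_group: 10
  battery_size: 6       # hard-capped at 6 constructs per animal
  noise_sd_expr: 0.25
de:
  p_thresh: 0.05
  fc_up: 2.0
  fc_down: 0.5
regulon:
  threshold_kind: relative
  threshold_value: 0.8
```

## Conventions and caveats

- SI-rate defaults to occupied:empty interaction-zone time
  (`with_over_without`); the inverse direction is available via config.
- The "corrected mean" activity change is the treated group's mean
  per-animal log2 normalized activity minus the control group's mean,
  with the SEM of the treated group.
- The driver score, `|activity log2FC| x |mean regulon log2FC|` with a
  sign-concordance multiplier, is a declared convention of this package.
- Dunnett many-to-one adjustment is computed by seeded Monte-Carlo
  simulation of the joint null max-|t| distribution.
- Coordinates are BED-style 0-based half-open; minus-strand promoter
  windows are mirrored and reverse-complemented.

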