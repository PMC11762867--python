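# nanomock

De novo simulator of Nanopore-style mock metagenome samples with **exactly
controlled per-organism read abundances**, a parametric read-length model,
and transition/transversion-weighted error injection. Samples are emitted
as FASTA together with abundance, error-profile, error-distribution and
run-parameter reports plus a per-read truth table, for validating
bioinformatics pipelines and diagnostic assays against known ground truth.

Key guarantees:

* **Exact counts.** Resolved per-organism read counts always sum to the
  design total — fractional shares are rounded by largest-remainder
  (Hamilton) apportionment, so a 100,000-read sample with a pathogen at
  absolute abundance 10 contains exactly 10 pathogen reads, in every
  replicate.
* **Reproducibility.** One seed determines the whole sample byte-for-byte;
  per-organism RNG substreams are derived by stable hashing, so reordering
  design entries never changes another organism's reads. Every run's
  `*_run_parameters.json` replays the identical sample when fed back as a
  config.
* **Ground truth.** Read ids encode provenance
  (`organism|contig|start|strand|fragment_length|serial`, 0-based
  half-open) and a truth TSV records origin plus per-read substitution /
  insertion / deletion counts.

## CLI

```bash
# synthetic references + a ready-to-edit design template
nanomock mockref -n 3 --length 100000 --seed 1 -o refs/

# dry-run: resolved per-organism counts, no simulation
nanomock validate refs/design.yaml

# generate the sample(s)
nanomock simulate -d refs/design.yaml -o out/ --seed 7 --profile guppy
```

Exit codes: 0 success, 1 I/O failure, 2 design/parameter validation error.

### Design files

YAML (canonical), JSON, or a flat TSV (`organism  reference  mode  value`).
A host–pathogen example:

```yaml
sample_name: dilution
seed: 11
total_reads: 100000
scenario: host_microbiome
host: wheat            # absorbs total - sum(other organisms)
fill_remainder: true
profile: guppy         # or dorado / perfect / path to a custom YAML/JSON
length_model: {mean: 2000, sd: 200, min_len: 50}
entries:
  - organism: virus
    reference: virus.fasta
    abundance: {mode: absolute, value: 500}
  - organism: wheat
    reference: wheat.fasta
dilution:              # optional: expands to levels x replicates samples
  organism: virus
  levels: [500, 100, 50, 10, 5]
  replicates: 20
```

Abundance modes: `absolute` (read count), `relative` (percent of
`total_reads`, apportioned exactly), `random` (leftover reads shared via a
seeded symmetric Dirichlet draw). Taxa with subtaxa distribute one budget
over members (`split: equal` or `random`). Mixed modes resolve in the
order absolute → relative → random; over-allocation is a hard error.

Error profiles carry per-base substitution/insertion/deletion rates, a
transition weight `kappa` (transition chosen with probability
kappa/(kappa+2)), and a geometric insertion-extension probability.
Presets: `guppy` (5% overall error), `dorado` (1%), `perfect` (0) —
representative values, fully overridable via custom profile files.

## Outputs per sample

`<name>.fasta`, `<name>_truth.tsv`, `<name>_abundance.tsv/.json`,
`<name>_error_profile.json`, `<name>_error_distribution.tsv/.json`,
`<name>_run_parameters.json`.

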