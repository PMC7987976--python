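# guidescreen

Simulation and hit-calling toolkit for pooled in vivo CRISPRa screens whose
defining feature is a severe per-animal engraftment bottleneck: each animal
carries only a small random fraction of the guide library, so hits must be
called by recurrence across animals rather than by within-animal statistics
alone.

The package covers the full analysis path:

| Module | What it does |
| --- | --- |
| `guidescreen.library` | Guide library data model, synthetic library designs (default: 2195 genes x 5 guides + 250 non-targeting controls = 11,225 guides), CSV/TSV I/O |
| `guidescreen.simulate` | Screen simulator: Poisson transduction at low MOI, control aliquot sampling, per-cell bottleneck survival, selective lognormal clonal outgrowth, Dirichlet-multinomial sequencing; plus noise-free FASTQ generation |
| `guidescreen.quantify` | FASTQ demultiplexing by exact 8-mer barcode, exact-match protospacer counting, technical-duplicate merging with concordance report |
| `guidescreen.counts` | Count hygiene in the published order: strict `< 30`-read control-replicate filter (raw counts), total normalization to the mean column total, removal of all-zero guides |
| `guidescreen.percentile` | Percentile method: per-guide group statistics (moments over all samples, group count over present samples, SEM = sd/sqrt(k)), z-scores against the cell-control mean, per-sample nearest-rank 98th-percentile sets, cross-animal recurrence |
| `guidescreen.joint` | Joint model: `y[g,s] ~ x[g] * w[gene,condition]` with Gaussian priors, alternating conditional (MAP) updates, gene-mean-1 efficacy constraint, ranking by the late-minus-early effect contrast `d` and `z = d / sd(w_late)` |
| `guidescreen.workflow` | End-to-end pipeline, representation/clonal-enrichment QC, cross-method concordance, report bundle |

## Test

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests for the
documented invariants, and `tests/test_acceptance.py` with one test per
acceptance criterion (library composition, design bookkeeping, bottleneck
calibration against the closed form `1 - exp(-lambda * p)`, a brute-force
z-score oracle at 1e-12, normalization/filter properties, FASTQ round-trip,
joint-model parameter recovery, and full-scale planted-hit recovery).

## CLI

```bash
guidescreen make-library --out library.csv
guidescreen simulate --config config.yaml
guidescreen count --library library.csv --sample-sheet sheet.csv reads.fastq.gz
guidescreen process --counts counts_raw.tsv --sample-sheet sheet.csv
guidescreen call-percentile --counts counts_normalized.tsv --sample-sheet sheet.csv
guidescreen call-joint --counts counts_normalized.tsv --sample-sheet sheet.csv
guidescreen qc --counts counts_raw.tsv --sample-sheet sheet.csv --library library.csv
guidescreen run --config config.yaml   # everything, ending in report.json/report.md
```

A minimal simulation config:

```yaml
seed: 42
out_dir: out
simulate:
  design: {read_depth: 2000000}
  selection: {n_planted: 5, planted_beta: 0.6}
```

## File formats

- **Library**: CSV/TSV with header `guide_id,gene,protospacer,is_control`;
  controls use the gene sentinel `NTC`.
- **Count matrix**: TSV with columns `sgRNA`, `gene`, then one column per
  sample.
- **Sample sheet**: CSV/TSV with `sample_id,barcode,group,mouse_id,run`;
  groups are `cells_500x`, `lung_4h`, `lung_19d`, or cohort labels.
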