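# glycoce

Collision-energy (CE) optimization analysis for N-glycopeptide MS/MS
identification. Given CE-resolved search-engine score tables, the package
extracts each glycopeptide species' optimal collision energy as the center of
a Gaussian fitted to its score-vs-CE curve, models how that optimum depends
on structural features (m/z, hydrophobicity, mobile protons, glycan mass,
sialylation) per score channel, and quantifies the identification-score gain
of a multivariate "smart CE" choice over the classical m/z-only rule. A
first-class synthetic-data module simulates the whole CE sweep, so every
stage runs and is tested without any external data.

## Layout

| module                | role |
|-----------------------|------|
| `glycoce.glyco_chem`  | glycan composition parsing, peptide masses, structural features (hydrophobicity, mobile protons, antennae, ...) |
| `glycoce.ce_model`    | instrument CE calibration (linear in m/z, two anchors), sweep-scale grid, hardware ceiling |
| `glycoce.report_io`   | search-report dialects (normalized / byonic / pglyco / glycoquest TSV), run manifest, best-match-per-run deduplication |
| `glycoce.curve_opt`   | score-vs-CE curves, eligibility policy, Gaussian optimum fitting |
| `glycoce.modeling`    | per-channel trendlines, ANCOVA with homogeneity-of-slopes gating, lasso path + minimal-feature selection, Pearson diagnostics |
| `glycoce.smart_ce`    | m/z-only vs multivariate CE predictors, nearest-measured-score evaluation, gain report (leave-one-out or in-sample) |
| `glycoce.synth_data`  | cohort sampling, peptide/glycan catalog, engine personas (peptide- vs glycan-centric), sweep simulation with missingness and duplicates |
| `glycoce.pipeline` / `glycoce.cli` | YAML-configured, checksummed, resumable orchestration and the `glycoce` command |

## CLI

```sh
# full pipeline (simulate -> ingest -> fit-curves -> features -> model -> gain)
glycoce run-all --config config.yaml

# or stage by stage
glycoce simulate --n 300 --seed 1 --out runs/demo/reports
glycoce ingest --reports runs/demo/reports --manifest runs/demo/reports/manifest.tsv \
    --out runs/demo/score_table.tsv
glycoce fit-curves --table runs/demo/score_table.tsv --out runs/demo/optima.tsv
glycoce features --table runs/demo/score_table.tsv --out runs/demo/features.tsv
glycoce model --optima runs/demo/optima.tsv --features runs/demo/features.tsv \
    --out runs/demo/model.json
glycoce evaluate-gain --table runs/demo/score_table.tsv --optima runs/demo/optima.tsv \
    --features runs/demo/features.tsv --channel byonic --mode loo --out runs/demo/gain.json
```

Minimal config (all keys optional; unknown keys are rejected):

```yaml
seed: 1
n_species: 300
out_dir: runs/demo
ce:
  anchor_low: [600, 50]     # eV at m/z 600
  anchor_high: [2000, 135]  # eV at m/z 2000
  ceiling: 200              # maximum settable energy
  grid: {start: 6.25, stop: 175, step: 6.25}
eligibility: {min_consecutive: 4, min_points: 5}
modeling: {delta_r2: 0.01, alpha: 0.05}
smart_ce: {mode: loo, channel: byonic}
```

Exit codes: 0 ok, 2 config error, 3 stage failure.

## Notes

- All masses are monoisotopic; the proton mass is 1.00727646 Da.
- Hydrophobicity is a pluggable residue-additive index (default:
  Kyte–Doolittle sum). Only the ordering of peptides is meaningful across
  scales.
- The default sweep grid is the 28-value progression 6.25–175% in 6.25%
  steps; any strictly increasing grid (e.g. a 27-run variant) is supported.
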