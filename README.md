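# refstab

Reference-gene stability analysis for RT-qPCR experiments, built as a
reusable Python package:

- **Cq I/O** — long- and wide-format readers for raw quantification-cycle
  (Cq) tables, technical-replicate collapsing (mean/median), plausibility
  window checks, conversion to linear-scale relative quantities under a
  configurable amplification efficiency.
- **geNorm** — expression-stability M values (single-pass and classic
  stepwise-exclusion modes), normalization factors, and the pairwise
  variation series V(n/n+1) with the 0.15 rule for choosing how many
  reference genes to use.
- **NormFinder** — model-based stability from an inter/intra-group variance
  decomposition (double-centering per group, moment estimators with
  truncation at zero, shrunken inter-group deviations).
- **BestKeeper** — per-gene descriptive dispersion (mean absolute deviation
  by default, sample SD optional), the per-sample geometric-mean Cq index,
  and correlation-based ranking.
- **Consensus** — geometric-mean aggregation of per-method ranks into a
  comprehensive ranking, plus an audited reference-gene recommendation step
  with explicit exclusions/forced inclusions and a between-group delta-Cq
  diagnostic.
- **Quantification** — primer-efficiency fitting from serial dilution
  series, delta-delta-Cq relative expression under configurable reference
  sets (Student/Welch t-test on untransformed delta-Cq), and reference-set
  sensitivity comparison.
- **Synthetic data** — a seeded Cq generator with per-sample loading
  offsets, per-gene condition effects and technical-replicate noise, named
  presets, and rank-recovery metrics, so the whole pipeline is testable
  without external data.

## CLI

```sh
# one stability algorithm
refstab stability --method genorm --input cq.csv --output genorm.tsv
refstab stability --method normfinder --input cq.csv
refstab stability --method bestkeeper --input cq.csv --sd-variant mad

# full report: per-method values + ranks, comprehensive rank, V-series
refstab full-panel --input cq.csv --output panel.tsv

# how many reference genes, and which
refstab vfit --input cq.csv --threshold 0.15
refstab recommend --input cq.csv --exclude Ann:condition-responsive \
    --force-include RIBL5

# quantification
refstab efficiency --input dilution.csv
refstab quantify --input cq.csv --target ast --refs RIBL5,GAPDH,Hsp70 \
    --control isolated

# synthetic data
refstab simulate --preset piceifrons-like --seed 42 --out synth.csv \
    --truth truth.json
```

Input tables are delimited text; long format has columns
`sample,gene,replicate,group,cq` (pass `--wide` for a genes-as-columns
matrix). Exit codes: 0 success, 2 schema/contract error, 3 insufficient
data. Every file-writing run leaves a `<output>.run.json` parameter record.

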