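# collateralkit

Simulation and analysis toolkit for collateral RNA cleavage experiments:
quantify bulk RNA degradation from electropherogram traces, estimate
transcript integrity with the 5′−3′ RT-qPCR dCq/ddCq statistic, recover
hidden global mRNA depletion with spike-in-anchored normalization and
regression-outlier transcript selection, and call cleavage sites from
coverage dips in transcript-space long-read alignments — plus a
molecule-level synthetic-data generator that produces all four data
modalities with planted ground truth, so every stage is testable as a
parameter-recovery problem.

## Modules

| Module | What it does |
| --- | --- |
| `collateralkit.simkit` | Synthetic transcriptomes, per-molecule cleavage with a dinucleotide/accessibility/abundance/activation hazard model, and the downstream modalities: read alignments (PAF), NB count matrices with spike-ins, qPCR Cq tables, electropherogram traces. |
| `collateralkit.assays` | Trapezoidal total/regional AUC with mean-AUC loading normalization; initial-slope cleavage rates from fluorescence time series. |
| `collateralkit.integrity` | Replicate collapsing, 5′−3′ dCq and ddCq vs empty-transfection controls, conventional relative-expression ddCq. |
| `collateralkit.spikenorm` | Spike-in-restricted median-of-ratios size factors, moderated-ratio fold changes, log2FC ~ log10(baseMean) regression, residual-threshold selection. |
| `collateralkit.dipcall` | Per-transcript coverage, running-median dip detection, 5′-nearest-uracil cleavage-position assignment, PFM/information-content context summaries, mapped-length QC. |
| `collateralkit.io`, `config`, `pipeline`, `cli` | PAF/SAM/FASTA/TSV/CSV/BED readers and writers, validated run configuration, checksummed end-to-end pipeline. |
| `collateralkit.benchmarks` | Canonical recovery experiments used by the test suite and the acceptance report. |

Coordinates are 0-based half-open in transcript space, forward strand. A
cleavage "position" is the index of the U; the cut is modelled
immediately 3′ of it.

## Command line

```bash
# end-to-end: simulate everything, then run all analysis stages
collateral-kit run --seed 1 --outdir run1

# individual stages
collateral-kit simulate --seed 1 --outdir sim1
collateral-kit auc sim1/electropherogram_t0.tsv sim1/electropherogram_t200.tsv --region 200:1700
collateral-kit slope --series series.csv --window auto
collateral-kit integrity --cq sim1/cq.csv --samples sim1/cq_samples.csv --out integrity.tsv
collateral-kit spikenorm --counts sim1/counts.tsv --samples sim1/count_samples.csv \
    --timepoint 200 --threshold auto --out lfc.tsv
collateral-kit dipcall --paf sim1/alignments_t200.paf --fasta sim1/transcriptome.fasta --out dips/
collateral-kit logo --sites dips/sites.tsv --fasta sim1/transcriptome.fasta --flank 5
```

Every knob has a default in `collateralkit/config.py` and can be
overridden via `--config config.yaml` (unknown keys are rejected; the
merged config is echoed into the output directory). Identical config +
seed give byte-identical outputs; `manifest.json` records a sha256 per
artifact.

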