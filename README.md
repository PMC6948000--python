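# ewasrep

Cross-cohort replication analysis for epigenome-wide association studies
(EWAS). The package simulates (or ingests) whole-blood DNA-methylation
cohorts, fits per-CpG linear association models with surrogate-variable
adjustment, and quantifies how well CpG–trait associations reproduce across
cohorts: 95% confidence-interval overlap, directional consistency,
cross-cohort effect-size regression and genetic-context annotation of
discordant CpGs, plus variance decomposition (relative importance, nested
likelihood-ratio tests, incremental adjusted R²) and Bonferroni
threshold/power calculations.

## Modules

| module | what it does |
| --- | --- |
| `ewasrep.synthetic` | beta-valued methylation cohorts with probe baselines, planted trait effects, cell-mixture and slide-batch structure, a hidden confounder, and a paired reference summary table with scaled effects and configurable sign discordance |
| `ewasrep.qc` | detection-p-value QC: exclude samples/probes with > 5% of measures at p > 0.01 |
| `ewasrep.cells` | reference-based cell-fraction estimation (nonnegative least squares + sum-to-one) |
| `ewasrep.ewas` | per-CpG OLS in either orientation (methylation- or trait-as-outcome), SVD/permutation surrogate variables, genome-wide hit filtering |
| `ewasrep.concordance` | CI-overlap / direction classification, per-trait summaries, effect-size regression, mQTL/MAF/probe-flag annotation |
| `ewasrep.varpower` | exact relative-importance (all-orderings) variance shares, nested LRT, incremental adjusted R², Bonferroni threshold, two-group power |
| `ewasrep.pipeline` / `ewasrep.cli` | end-to-end orchestration with config validation, deterministic seeding and a checksummed manifest |

## CLI

```bash
# full synthetic pipeline: simulate -> qc -> cells -> ewas -> compare -> report
ewasrep run --config configs/demo.yaml --out run/

# individual stages reuse artefacts in the run directory
ewasrep simulate --config configs/demo.yaml --out run/
ewasrep ewas --config configs/demo.yaml --out run/
ewasrep compare --config configs/demo.yaml --out run/

# family-wise significance threshold
ewasrep power --alpha 0.05 --m-tests 530639
```

Outputs are plain TSV/JSON: summary tables
(`probe_id, trait, cohort, ancestry, n, effect, se, p, ci_low, ci_high,
model_id`), comparison records with overlap/direction classes and genetic
flags, a pooled replication report, and a manifest with config hash and
per-file checksums (reruns with the same config are byte-identical).

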