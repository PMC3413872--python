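# cnvsurv

Survival association analysis of **germline copy-number variants (CNVs)
measured on SNP genotyping arrays**, for statistical geneticists and
molecular epidemiologists studying whether inherited deletions and
duplications predict disease outcome in a patient cohort.

Raw two-channel allele intensities (A, B) are turned into a normalized
log2 intensity matrix *Z* whose deviations from zero track copy number,
and *Z* is related to overall survival with **left-truncated Cox
proportional-hazards models** (patients enter the risk set at enrollment,
not diagnosis — ignoring this delayed entry biases hazard ratios) through
three complementary CNV parameterizations:

1. **Single-marker scan** (small, common CNVs): each marker's *Z* is a
   Cox covariate; the per-chromosome −log₁₀ *p* profile is smoothed with
   an exact fused-lasso signal approximator
   `f = argmin ½Σ(yₜ−fₜ)² + λ₁Σ|fₜ| + λ₂Σ|fₜ₊₁−fₜ|`,
   and maximal runs with smoothed value > 2 become regions of interest,
   locally segmented per sample into loss/normal/gain states.
2. **Genome-wide segmentation** (large, rare CNVs): per-sample circular
   binary segmentation (CBS) with a permutation-tested maximal arc
   statistic and a three-marker minimum; segment means are called
   loss/gain against per-sample 3rd/97th-percentile thresholds; markers
   recurrently altered in ≥ *r* samples define common CNV regions, each
   tested with a 1-df trend model (states −1/0/+1) and a 2-df categorical
   model, Bonferroni-corrected over tested regions.
3. **CNV burden**: per-sample counts of called gains, losses, and their
   total, each entered as a continuous Cox covariate.

Normalization follows the heterozygote-based channel correction
ψⱼ = (1/K) Σ (Aᵢⱼ/Bᵢⱼ), total intensity Iᵢⱼ = log₂(Aᵢⱼ + ψⱼBᵢⱼ), quantile
normalization across subjects, per-plate median normalization per marker,
and subject centering Zᵢⱼ = Iᵢⱼ − Īᵢ.

A fully synthetic data generator (`cnvsurv.simulate`) emulates a
multi-site array study — genotype-dependent channel splitting, dye
imbalance, plate batch effects, planted CNV regions with known hazard
ratios, and exponential survival with delayed entry and administrative
censoring — so the entire pipeline is testable without patient data.

## Worked example

```python
import numpy as np
from cnvsurv import PlantedRegion, SimulationConfig
from cnvsurv.pipeline import run_segmentation_pipeline

config = SimulationConfig(
    n_samples=400, n_chrom=8, markers_per_chrom=40, seed=21,
    planted_regions=(
        PlantedRegion("3", 12, 6, -1, 0.20, np.log(2.0)),   # hazardous loss
        PlantedRegion("6", 20, 6, +1, 0.35, 0.0),           # neutral gain
    ))
run = run_segmentation_pipeline(config, recurrence=60)
for r in run.results:
    print(r.label, r.n_gain, r.n_normal, r.n_loss,
          round(r.hr, 2), round(r.p_bonferroni, 4))
```

prints

```
3:65000-90000 39 263 98 0.64 0.0011
6:105000-130000 126 210 64 1.04 1.0
6:5000-200000 38 286 76 1.25 0.2018
```

The planted chromosome-3 loss is recovered as a recurrent region whose
trend hazard ratio per +1 copy state is 0.64 — equivalently, loss
carriers (state −1) die ≈1.6× faster — Bonferroni-significant at 0.001,
while the survival-neutral gain region is recovered positionally
(126 gain carriers) but shows no association; the third region is the
whole-chromosome background run that per-sample relative calling
produces at desk scale (see `docs/methods.md`), also null.  `examples/` contains one short script per
capability (simulation, normalization, the marker scan, segmentation,
burden), each printing the numbers it computes and what they mean.

A thin CLI mirrors the stages (`cnvsurv simulate | qc | normalize |
scan | segment | burden`), reading and writing TSV matrices, SEG
segment files and association tables.

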