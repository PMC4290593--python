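# dcap

Joint and differential detection of protein–DNA occupancy across multiple
conditions, factors and replicates, from multivariate ChIP-seq / DNase-seq
signal.

Genome-wide comparisons of regulatory signal usually either call binary peaks
per sample and intersect them (threshold-sensitive, blind to quantitative
variation) or test one factor at a time (ignoring that co-binding factors
carry correlated evidence). `dcap` instead treats the `P = K·R` tracks of one
condition (K factors × R replicates) as a single multivariate observation per
genomic window and runs a three-step likelihood-ratio cascade:

1. **Occupancy** — per window `i`, is any condition's mean away from the
   local background? With `x_j(i) ~ N(u_j(i), Σ_j(i))` and the constraint
   `u_j = A u_jA` (A the P×K replicate design, so replicate means are tied),
   the statistic `T₁ = 2(L₁ − L₀)` compares the per-condition GLS means
   `û_jA = (AᵀΣ⁻¹A)⁻¹AᵀΣ⁻¹x_j` against the background mean `û_bck`
   (per-factor median over the ±5 kb neighbourhood across all conditions);
   `T₁ ~ χ²(CK)` under the null.
2. **Differential** — among occupied windows, do conditions differ? The null
   pins all conditions at the precision-weighted pooled mean
   `û₀A = (Σ_j AᵀΣ_j⁻¹A)⁻¹ Σ_j AᵀΣ_j⁻¹x_j`; `T₂ ~ χ²((C−1)K)`.
3. **Condition specificity** — among differential windows, C leave-one-out
   repeats of step 2 (`χ²((C−2)K)` each); a window is specific to condition
   `j` when dropping `j` — and only `j` — makes the rest consistent.

The covariance is heteroscedastic and structured:
`Σ_j(i) = diag(σ_j(i)) R_j diag(σ_j(i))`, with a condition-level correlation
`R_j` estimated from the genomic background by a covariance decomposition
(`Cov(X_j) = Cov(background) + Cov(binding means)`, with a plug-in bias
correction for the noise share of the sample factor means), and per-window
variances from a LOESS mean→variance curve fitted to Cholesky-whitened
replicate residuals — whitening removes the downward bias of the naive
sample variance under replicate correlation.

Before testing, tracks are normalized: log2(x + 0.1), per-factor quantile
normalization, then per-track LOESS normalization against the factor mean.

## Worked example

```python
import numpy as np
from dcap import SimulationSpec, simulate_mvn_dataset, DCaP, roc_prc

# weak-binding benchmark: 30,000 windows, 5 conditions x 3 factors x 2
# replicates, background N(0,4), binding N(4, 2.25), 1,800 bound windows
spec = SimulationSpec.regime("weak", seed=1)
values, layout, truth = simulate_mvn_dataset(spec)

est = DCaP(layout=layout).fit(values)
res = est.results_
print("bound windows:", int(res["bound"].sum()))
print("differential windows:", int(res["differential"].sum()))
print("AUPRC (occupancy task): %.3f"
      % roc_prc(est.statistics_["T1"], truth["is_binding"]).auprc)
```

prints

```
bound windows: 1711
differential windows: 317
AUPRC (occupancy task): 0.982
```

1,711 windows pass the Bonferroni-corrected occupancy test at this weak
signal strength (nearly all of them among the 1,800 planted bindings),
317 of the 600 planted
differential windows are confidently called differential (the rest are bound
in too many or too weakly separated conditions to clear the corrected
threshold), and ranking all windows by `T₁` separates bound from background
with area 0.982 under the precision–recall curve.

For file-based runs there is a CLI (`dcap run --layout layout.tsv
--chrom-sizes genome.sizes --out results/`) with subcommands `normalize`,
`fit-cov`, `test`, `run`, `bench` and `fixture`; inputs are bedGraph/bigWig
tracks, a (condition, factor, replicate, path) layout TSV, chromosome sizes
and an optional blacklist BED. Outputs are a normalized signal matrix, the
fitted covariance model (JSON), a per-window statistics TSV and BED files of
occupancy / differential / condition-specific regions. `dcap fixture`
generates a small fully-synthetic two-chromosome dataset with planted peaks
for end-to-end testing.

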