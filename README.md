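# ipacc — theoretical accuracies for indirect genomic predictions

`ipacc` is a toolkit for quantitative geneticists who release *indirect
predictions* (IP): fast, marker-based breeding-value predictions for young
genotyped animals that are not part of the official single-step GBLUP
(ssGBLUP) evaluation. IP themselves are easy — backsolve SNP effects from
GEBV and multiply by gene content — but their *individual theoretical
accuracies* are rarely reported. This package computes them, from the
prediction-error covariance (PEC) of the SNP effects, which is in turn
obtained from the PEC of GEBV in the ssGBLUP mixed-model equations.

## The model

Single-trait animal model `y = Xb + Wu + e` with a contemporary-group
fixed effect and `var(u) = H σᵤ²`, where `H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A₂₂⁻¹]`
combines the pedigree relationship matrix A with a genomic relationship
matrix built as `G = b((1−α)G₀ + αA₂₂) + 11′δ`, `G₀ = ZZ′ / 2Σpᵢ(1−pᵢ)`
(VanRaden type 1), with blending proportion α and mean-compatibility
tuning (δ, b). `G⁻¹` is computed directly or with the APY
(algorithm-for-proven-and-young) core/non-core decomposition, the core
size set by the number of leading eigenvalues explaining 98–99% of the
variance in G.

From a fitted evaluation with GEBV `û₂` for the genotyped animals and the
genotyped block `C^{u₂u₂}` of the inverted coefficient matrix:

- SNP effects: `â = (1−α) b (1/k) Z′G⁻¹û₂`, `k = 2Σpᵢ(1−pᵢ)`
- estimator variance: `var(â) = c²(Z′G⁻¹Z σᵤ² − Z′G⁻¹ C^{u₂u₂} G⁻¹Z)`,
  `c = (1−α)b/k`
- SNP PEC: `PEC = σₐ²I − var(â)` with per-SNP prior variance
  `σₐ² = (1−α)b σᵤ²/k`
- indirect prediction for a new animal j: `IP_j = z_j â`
- accuracy: `ACC_j = sqrt(1 − (z_j PEC z_j′ + (1−(1−α)b) σᵤ²) / σᵤ²)`,
  where the last term is the polygenic share of the variance that the
  markers do not carry under blending (zero when α = 0).

In the unblended, fully genotyped limit this chain is *exactly* the
SNP-BLUP mixed model: `â` equals the SNP-BLUP solutions, `PEC` equals its
`C^{gg}` block, and the IP accuracy of every training animal equals its
GEBV accuracy. Those identities are enforced to 1e-8/1e-6 in the test
suite against an independent SNP-BLUP solver.

## Worked example

```python
from ipacc import SimulationConfig, simulate, ScenarioSuite, ScenarioConfig

data = simulate(SimulationConfig(seed=11, n_founders=60,
                                 generation_sizes=(150, 150, 150, 120),
                                 m=300,
                                 genotyping_prob=(0.5, 0.85, 0.95, 0.95, 0.45)))
suite = ScenarioSuite(data, seed=11)     # alpha = 0.05 with tuning
report = suite.run(ScenarioConfig("direct"))
print(report.summary())
print(report.table.head(3).round(3))
```

prints (437 genotyped training animals, 59 genotyped validation animals
with neither phenotypes nor progeny):

```
{'scenario': 'direct', 'r_gebv_ip': 0.999, 'r': 0.991, 'b0': 0.027,
 'b1': 0.952, 'mean_abs': 0.005, 'max_abs': 0.014}
animal   gebv     ip  acc_gebv  acc_ip
   511  0.010  0.107     0.604   0.590
   513  0.018  0.044     0.674   0.678
   515 -0.118 -0.098     0.646   0.654
```

Reading this: `r_gebv_ip` is the correlation between the benchmark GEBV
(validation animals included in ssGBLUP) and the IP computed from
backsolved SNP effects of the reduced run (0.999 — the IP recover the
GEBV almost perfectly); `r`, `b0`, `b1` describe the regression of the
benchmark accuracy on the IP accuracy (a slope near 1 and intercept near
0 mean the theoretical IP accuracies are on the same scale as the GEBV
accuracies); `mean_abs`/`max_abs` are the absolute accuracy differences.
The per-animal table gives each validation animal's benchmark GEBV, its
indirect prediction, and both accuracies.

The same machinery is scriptable from the shell:

```bash
ipacc simulate --seed 3 --out data/
ipacc evaluate --pedigree data/pedigree.txt --genotypes data/genotypes.txt \
      --phenotypes data/phenotypes.txt --sigma2-u 0.4 --sigma2-e 0.6 \
      --save-pec --out run/
ipacc predict --genotypes data/genotypes.txt --snp-effects run/snp_effects.txt \
      --freqs run/allele_freqs.txt --acc run/pec.bin --out ip.csv
```

`evaluate` writes GEBV and their accuracies plus the SNP-effect file and
(with `--save-pec`) the binary PEC file; `predict` scores any genotype
file against those effects, and `--acc` appends the per-animal theoretical
accuracy (it refuses PEC files whose allele-frequency checksum does not
match).

## Scenario battery

`ScenarioSuite` reproduces a full validation design on one dataset:
`direct` (all training genotypes, direct G⁻¹), `apy` (APY G⁻¹, core from
the eigenvalue rule), `subset_n` (random genotype subsets in the PEC
computation), `core` / `hacc` (core-sized subsets chosen at random or by
highest benchmark accuracy), `core_prog` / `hacc_prog` (additionally
pruning phenotypes to the selected animals and their progeny, pedigree
kept ancestrally closed), and a blending sweep over α. SNP effects always
come from the direct reduced run; scenarios change only the evaluation
behind the PEC.

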