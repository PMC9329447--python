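# nbbtest

A negative-beta-binomial t-test for two-condition differential analysis of
RNA-seq-style count data: poly(A) isoforms, splicing exons, CRISPR screen
sgRNAs, and genes.

## The problem and the method

Sequencing experiments usually run with very few biological replicates
(often 3). At that sample size two null pathologies distort ordinary
t-statistics: the replicate ranges of the two conditions are frequently
disjoint by pure chance (a *data gap*), and the sample variance of a tiny
replicate set is erratic — usually too small (inflating t), occasionally
far too large (shrinking t).

`nbbtest` models the sequencing proportion *p* of each feature as beta
distributed, `p ~ Beta(α, β)`, estimates it per condition with
inverse-variance replicate weights (Σ w_j = 1), floors the variance with a
closed-form bound to stop small-count collapse, and forms the base
statistic

    t = (p̂_A − p̂_B) / sqrt(V̂_A + V̂_B).

The novelty is a multiplicative correction built from two data statistics:

    φ = max[(min X_A + 1)/(max X_B + 1), (min X_B + 1)/(max X_A + 1)]   (gap / fold term; φ > 1 ⇔ disjoint ranges)
    ζ = max(0, ln((X̄·σ² + 1)/(X̄_A·σ_A² + X̄_B·σ_B² + 1)))             (homogeneity term, X̄ = X̄_A + X̄_B)
    ρ = sqrt(φ·ζ)

and a null threshold ω_α estimated by repeatedly simulating no-effect
data that is moment-matched to the input, running the un-inflated test,
and recording the ρ level its false positives reach (the 85 % point of
their ρ values, averaged over simulations). The reported statistic is

    t^α = (ρ / ω_α) · t

with ρ taken feature-wise for isoforms/exons and gene-wise for sgRNAs and
genes. Clearly separated, homogeneous signals are inflated; overlapping or
noisy ones are shrunk — often to exactly 0 when ζ clamps. Two-sided
p-values come from t^α with df = m_A + m_B − 2 and are
Benjamini–Hochberg-adjusted across features with non-zero counts.

The package also ships the negative-binomial scenario simulators used to
benchmark the test (planted effects τ = U·A, technical outliers, gap- and
variance-probability experiments) and the evaluation metrics
(F1, precision/recall, type-I error, observed FDR, ROC points).

## Worked example

```python
from nbbtest import Scenario, simulate_counts, test_isoforms

scenario = Scenario(n_genes=1000, features_per_gene=2, effect_level=300.0,
                    affected_fraction=0.1, outlier_fraction=0.3,
                    reps_per_condition=3, seed=7)
ds = simulate_counts(scenario)
res = test_isoforms(ds.table, alpha=0.05, seed=11, sims=10)
```

Running `python examples/differential_isoforms.py` (this exact analysis
plus scoring against the planted truth) prints:

```
simulated 2000 isoforms in 1000 genes, 223 truly differential
omega_0.05 calibrated from 10 null simulations: 1.272
calls at FDR 0.05: 38  (tp=37, fp=1)
precision=0.974  recall=0.166  F1=0.284  observed FDR=0.026

top calls (t_alpha = rho/omega * t):
gene_id feature_id          t      rho    t_alpha     padj direction
   g972    g972.f1 -25.033066 4.550767 -89.538111 0.000102      down
   g674    g674.f0 -16.290245 6.836555 -87.533494 0.000102      down
```

`omega_0.05 = 1.272` is the ρ level a null version of this dataset reaches
among its chance positives; only features whose own ρ exceeds it get their
t inflated. The calls are almost all true (observed FDR 0.026 at nominal
0.05); recall is modest because effect sizes τ = U·300 are drawn down to
near zero. Each script in `examples/` demonstrates one capability
(gap statistics, small-sample effects, isoform test, CRISPR screen,
ω calibration) and prints a line explaining its numbers.

A thin CLI wraps the same functions for shell pipelines:

```sh
nbbtest simulate --n-genes 500 --seed 1 --out counts.tsv --design-out design.tsv --truth truth.tsv
nbbtest test --counts counts.tsv --design design.tsv --level isoform --seed 1 --out results.tsv
nbbtest metrics --results results.tsv --truth truth.tsv --out report.tsv
nbbtest omega --counts counts.tsv --design design.tsv --sims 10 --seed 1
```

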