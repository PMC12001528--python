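# mbresil — bivariate microbiome-resilience analysis

`mbresil` quantifies the **resilience** of a gut microbial community to a
perturbation — how strongly its composition is displaced and how it recovers —
from a longitudinal abundance study (subjects × conditions × timepoints). It
is aimed at microbiome researchers with genus- or species-level abundance
tables (e.g. the output of a DADA2/QIIME2 workflow collapsed to genus level)
and per-sample metadata; it does not process raw sequencing reads.

Resilience is intrinsically bivariate: a disturbance has a *magnitude* and a
*recovery time*, and indices built on a single hand-picked feature of the
response (a slope, an area under the curve) capture one aspect but not both.
`mbresil` instead lets the data define the parametrization:

1. **Compositional distance trajectories.** For each subject and condition,
   the displacement of the community at time *t* from its pre-perturbation
   baseline is measured by the Aitchison distance
   `d(u, v) = || clr(u) − clr(v) ||₂` with `clr(u)ₖ = log(uₖ / g(u))`,
   the centred log-ratio transform (`g` = geometric mean). Zeros are imputed
   first by multiplicative replacement.
2. **Log-ratio analysis (LRA).** Taxa are ranked by their share of the total
   log-ratio variance (a weighted PCA of the log-composition matrix with
   compositional part means as column weights), and the smallest set
   explaining ≥ 90 % of the variance is kept. Selection depends on
   variability, not mean abundance, so rare-but-dynamic taxa are retained.
3. **Functional PCA.** The family of trajectories `Xᵢ(t)` is decomposed via
   the Karhunen–Loève expansion `Xᵢ(t) = μ(t) + Σₖ ξᵢₖ φₖ(t)`, computed as a
   quadrature-weighted eigendecomposition on the observation grid. The first
   score typically tracks overall displacement (impact) and the second the
   timing/shape of the recovery, so each trajectory is summarized by the
   pair (ξ₁, ξ₂): resilient trajectories sit at low ξ₁ with ξ₂ near zero.
4. **Bagplot outliers.** Atypically shaped trajectories are flagged on the
   (ξ₁, ξ₂) plane with a Tukey-halfspace-depth bagplot (bag = convex hull of
   the deepest half of the points; fence = bag inflated ×3 about the depth
   median).

A synthetic-study generator with known shock magnitudes and recovery
half-lives makes every stage testable end to end.

## Worked example

```python
from mbresil import MicrobiomeResilience
from mbresil.synthetic import SynthConfig, generate_study, truth_recovery_report

table, meta, truth = generate_study(SynthConfig(seed=7))   # 15 subjects × 3 conditions
results = MicrobiomeResilience(table, meta).fit()
print(results.summary())
```

```
                Microbiome resilience analysis
==============================================================
Trajectories:   45    Conditions:  3    Grid (h): 0, 0.5, 3, 6, 24, 48
Taxa: 100 input -> 24 selected (>= 90% of log-ratio variance)
Mean distance from baseline: 2.2 +/- 0.12 (SE)
--------------------------------------------------------------
FPCA1: eigenvalue 33.12, explains 84.2% of trajectory variance
FPCA2: eigenvalue 5.806, explains 14.8% of trajectory variance
--------------------------------------------------------------
Score means +/- sd by condition:
  atv          FPCA1     -0.27 +/- 5.99 (n=15)
  atv          FPCA2     -0.06 +/- 3.40 (n=15)
  sled         FPCA1      1.98 +/- 4.52 (n=15)
  sled         FPCA2      0.40 +/- 1.59 (n=15)
  wheel        FPCA1     -1.72 +/- 6.35 (n=15)
  wheel        FPCA2     -0.35 +/- 1.96 (n=15)
Bagplot outlier trajectories: S01/atv, S08/wheel, S10/atv, S14/atv
==============================================================
```

The two leading functional components absorb 99 % of the trajectory
variance, and each trajectory collapses to its score pair. Because the
generator's ground truth is known, the interpretation of the scores can be
checked directly:

```python
print(truth_recovery_report(truth, results.scores).to_string(index=False))
```

```
truth_parameter score  spearman_rho  n
      magnitude FPCA1      0.886166 45
       halflife FPCA2      0.705534 45
```

i.e. the first score ranks trajectories by the true shock magnitude
(ρ ≈ 0.89 despite multinomial sequencing noise and 50 % zeros) and the
second tracks recovery timing. `results.simulate(xi1_grid, xi2_grid)`
synthesizes curves on a grid of score pairs to visualize what each score
does to a trajectory's shape, and `results.group_mean_curves()` gives the
per-condition mean ± SE distance profile.

The same pipeline is available from the shell:

```bash
mbresil synth --seed 7 --out-table T.tsv --out-meta M.tsv --out-truth truth.csv
mbresil run --table T.tsv --meta M.tsv --outdir out/
mbresil simulate --model out/fpca_model.json --xi1 "-25,30,4" --xi2 "-16,11,4" --out curves.csv
```

`mbresil run` writes the selected taxa, trajectories, FPCA model, scores
with outlier flags, score–distance correlations and a manifest; reruns with
the same inputs and configuration are byte-identical.

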