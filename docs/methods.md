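# Methods

This note documents the statistical machinery implemented in `mbresil`, the
choices made where several constructions were defensible, and what the
synthetic-data experiments do and do not demonstrate.

## Compositional geometry

Relative-abundance vectors are compositions: only ratios carry information.
All distances are Aitchison distances, the Euclidean distance between
centred log-ratio (CLR) images; natural logarithms are used throughout (the
log base only rescales all distances by a constant, so one convention must
be fixed). The distance is scale-invariant — input rows need not be closed —
permutation-equivariant, and subcomposition-consistent, which is why it is
preferred here over divergences such as Jensen–Shannon.

**Zero replacement.** CLR is undefined at zero. The default is multiplicative
replacement on the proportion scale: each zero becomes `δ` and the nonzero
parts of a row with `z` zeros shrink by `(1 − zδ)`, keeping the row closed;
`δ` defaults to 0.65 × the smallest nonzero proportion in the table, a
widely used convention that keeps the imputed value strictly below anything
actually observed. The alternative `bayes_multiplicative` method imputes the
Bayes–Laplace (uniform-prior) posterior mean `1/(nᵢ + D)` for a zero count
in a row with total `nᵢ` over `D` taxa, then adjusts the nonzero parts
multiplicatively; it requires count input because the posterior depends on
the sequencing total. The multiplicative default was chosen because it is
deterministic, parameter-transparent and hand-checkable; no claim is made of
parity with any particular zero-replacement software.

## Log-ratio analysis and taxon selection

Microbiome tables are wide and sparse; most taxa are absent from most
samples. Dimensionality is reduced by log-ratio analysis: with closed
proportions `p_ij`, uniform row weights `r_i = 1/n` and column weights
`c_j` equal to the mean closed abundance of taxon `j`, the log matrix is
double-centred (row-centre with `c`, then column-centre with `r`) into
`y_ij`, and

    total variance  = Σ_ij r_i c_j y_ij²,
    contribution_j  = Σ_i r_i c_j y_ij² / total.

The double-centring order is fixed as above; its correctness is pinned by
the classical identity `total = ½ Σ_jk c_j c_k Var(log p_j/p_k)`, which the
tests verify against a brute-force pairwise computation. Contributions are
column shares of the total weighted variance (not per-dimension PCA
loadings): this matches the "minimum set of taxa explaining ≥ X% of the
variance" semantics used for selection. Ranking ties are broken
lexicographically by taxon id so selection is deterministic. Selection
rewards variability, not abundance — a rare taxon with volatile ratios can
outrank a dominant stable one. After selection, tables are restricted to the
chosen taxa and rows re-closed (a subcomposition), and all downstream
distances are computed on that subcomposition.

## Trajectories

For each (subject, condition) the Aitchison distance of every sample to the
group's baseline sample defines a time-indexed curve. By default the
baseline also contributes an anchor point (t₀, 0) — the distance of the
baseline to itself — which stabilizes the FPCA mean at the origin of the
response; the anchor can be disabled, and pooled summary statistics always
exclude it. Besides the per-condition baseline, a per-subject mode (one
reference shared by all of a subject's conditions, optionally pinned to a
named condition) supports drift analyses of the baseline state itself, and a
fixed-sample mode references every trajectory to one chosen sample.

Missing single timepoints are either left missing (default; such ragged
families cannot be stacked for FPCA) or linearly interpolated onto the
common grid, with endpoint values held constant outside a trajectory's
observed span. A wholly absent (subject, condition) series is simply not a
trajectory. Standard errors use the n−1 standard deviation and are reported
as missing — never zero — when only one observation contributes.

## Functional PCA

With at most a handful of observation times per trajectory, basis smoothing
is underdetermined; FPCA is therefore computed directly on the grid as a
quadrature-weighted eigenproblem, with no pre-smoothing. Given curves
`X (n × m)`, mean `μ`, sample covariance `C` (denominator n−1) and
quadrature weights `w` (trapezoid rule by default, so irregular spacing —
e.g. 0, 0.5, 3, 6, 24, 48 h — is integrated correctly; unit weights
optionally, falling back to unit weights for grids shorter than 3), the
eigenvectors `v_k` of `W^{1/2} C W^{1/2}` give eigenfunctions
`φ_k = W^{−1/2} v_k`, orthonormal under `⟨f, g⟩_w = Σ_t w_t f g`, and scores
`ξ_ik = Σ_t w_t (X_i − μ) φ_k`. Eigenvalues are clipped at zero and sorted
non-increasing; explained fractions are taken relative to the full weighted
total variance `Σ_t w_t C(t,t)` (trace preservation), not to the retained
components only.

Numerical conventions worth stating:

* **Sign.** Eigenfunctions satisfy `Σ_t w_t φ_k(t) ≥ 0`, with the first
  nonzero element made positive if the weighted mass is zero. Statements
  like "resilient trajectories have low first scores" are sign-convention
  dependent; fixing the convention makes score signs reproducible.
* **Uniform weights reduce to matrix PCA** exactly (eigenvalues equal those
  of the sample covariance), which the tests exploit as an oracle.
* **Truncation is an orthogonal projection in the `w`-metric.** The
  reconstruction error `Σ_t w_t (X̂ − X)²` is non-increasing in the number
  of components; the *sup-norm* error is not guaranteed monotone when early
  grid points carry small trapezoid weights, and the tests assert the
  weighted quantity.
* `K` defaults to 2, mirroring the empirical finding that two modes —
  overall displacement and recovery timing — dominate perturbation-response
  families.

Score-grid simulation (`μ + a φ₁ + b φ₂` over a Cartesian grid of `(a, b)`)
visualizes the joint repertoire of shapes; projecting the simulated curves
back returns the generating grid exactly, by orthonormality.

## Bagplot outliers

Atypical trajectories are flagged on the (ξ₁, ξ₂) plane using Tukey
halfspace depth, computed exactly by an angular sweep: the count of points
in a closed halfplane through the query point is piecewise constant in the
boundary direction, changing only at directions perpendicular to some
cloud point, so evaluating one direction per angular interval suffices. The
bag is the convex hull of the ⌈n/2⌉ deepest points (depth ties at the
cutoff broken by distance to the depth median, exact ties included); the
depth median is the centroid of the maximal-depth points; the fence is the
bag inflated ×3 about the median (the conventional bagplot constant);
points strictly outside the fence are outliers. This point-based bag is
simpler and fully deterministic compared with interpolated depth contours,
and adequate at the few-dozen-trajectory scale typical of these studies; at
small n it slightly underestimates the half-mass contour, so a few percent
of a well-behaved Gaussian cloud may be flagged — the flags should be read
as candidates for inspection, not as a calibrated test.

## Synthetic studies and what they show

The generator emulates a perturbation–recovery design: subject baselines are
drawn in CLR space around heavy-tailed population log-levels (σ = 2 across
taxa, subject effect σ = 0.7), reproducing the unbalanced
few-dominant/many-rare abundance profile of real gut data. Each (subject,
condition) trajectory displaces the baseline along a fixed zero-sum unit
CLR direction spanning 10 taxa by `m · s(t)`, where the magnitude
`m ~ N(8, 3²)` (truncated at 0) and `s(t)` rises linearly to 1 at the peak
time (4.5 h, the midpoint of the 3–6 h window where such responses are
typically strongest) and decays exponentially with half-life
`h ~ N(12, 4²)` hours (truncated at 0.5). Because the direction has unit
CLR norm, the noise-free distance from baseline is exactly `m · s(t)`.
Observation noise is multinomial resampling at a sequencing depth (default
50 000 reads), and the smallest cells are zeroed to reach a target zero
fraction (default 50 %), never emptying a sample. Defaults (15 subjects ×
3 conditions × 6 timepoints, 100 taxa) mirror a realistic cohort design.

Passing the end-to-end tests shows that the pipeline recovers a known
impact/recovery structure through zero replacement, taxon selection and
FPCA, and that the first score ranks trajectories by true impact. It does
not show that real data follow a rank-2 shock-and-decay model: real
perturbations need not share a direction across subjects, baselines drift,
and sample-type artifacts (e.g. swab vs stool) are not emulated.

The FPCA parameter-recovery experiment (`generate_fpca_family`) is a
*linear-algebra oracle*, deliberately noise-free: drawn scores are
standardized to exactly zero mean, the nominal sample variances (4, 1) and
zero sample correlation, so the fitted explained fractions (0.8, 0.2) and
score correlations are exact up to floating point. With raw Gaussian scores
at n = 200 the sampling noise of those quantities (sd ≈ 0.02 on the
fraction; eigenvector mixing of order the empirical cross-covariance)
would dominate what is being tested, which is the decomposition itself.

## Determinism and output conventions

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical configurations are bit-reproducible.
Written artifacts use nine significant digits, long formats for trajectory
data (tolerant of missingness), JSON for fitted FPCA models, and a manifest
carrying the package version, configuration and its SHA-256 hash; stage
timings go to the log, not the manifest, so pipeline outputs are
byte-identical across reruns.

## Known limitations

* No sparse/irregular FPCA with covariance-surface smoothing (PACE-style);
  trajectories must share the grid after the missing-data policy.
* Depth computation is exact but O(n²) per query point; fine for hundreds
  of trajectories, not tens of thousands.
* Zero replacement parity with external implementations is not claimed, and
  heavy zero-inflation makes any imputation-based CLR analysis sensitive to
  the replacement scale.
* LRA selection can be run pooled (default) or per condition by slicing the
  input; the package does not decide which is scientifically appropriate.
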