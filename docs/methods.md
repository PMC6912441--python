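# Methods

## Model

Surprisal analysis treats the transcriptome of a biological sample as a
maximal-entropy "balanced state" perturbed by a small number of
constraints. For gene *i* in sample *s* the natural log of its abundance
X_i(s) (FPKM-like units) is written

    Y_i(s) = ln X_i(s) = ln X_i0 + Σ_{α=1..Nα} G_iα λ_α(s),
    ln X_i0 = G_i0 λ_0

The balanced-state term G_i0 λ_0 is common to all samples; each
constraint α contributes a gene-weight pattern G_·α (the "phenotype")
scaled per sample by a Lagrange multiplier λ_α(s). The central empirical
claim the pipeline operationalises is that the *sign* of λ_α(s) groups
samples: in a batch-culture dose × time design, the first constraint
separates exponential-phase from stationary-phase samples and the second
separates low-dose from high-dose samples.

## Estimation

The model is estimated by SVD of the genes × samples log matrix,
Y = U S Vᵀ: G_·α is column α of U and λ_α(s) = S_αα V_sα. Component 0
(largest singular value) is the balanced state. The full spectrum is
always computed and stored; by default the two leading constraints are
interpreted downstream (`n_constraints=2` in the drivers), since
truncations are optimal in the Frobenius sense at any depth.

Sign conventions (SVD determines each component only up to sign):

- λ_0 is made positive for every sample. If the leading right-singular
  vector changes sign across samples, the data have no common dominant
  component and the fit aborts rather than report a meaningless
  "balanced state".
- For α ≥ 1 the component is flipped so that the lexicographically
  smallest sample label in a user-declared reference group (all samples
  when none is declared) has λ_α > 0. Declaring the exponential-phase
  conditions the reference for α = 1 and the high-dose conditions for
  α = 2 yields the conventional orientation (positive λ_1 =
  exponential, positive λ_2 = high dose). The rule is deterministic:
  decomposing the same matrix twice gives identical output.

### Input handling

- **Gene filter.** ln 0 is undefined, so the default filter keeps a gene
  only if its abundance is strictly positive in every sample
  (`all_positive`, threshold 0). A `min_fraction_positive` policy is
  available; the removed count is logged.
- **Floor.** Before the log transform, abundances are floored at 0.01
  (configurable, recorded in the model). The floor bounds the dynamic
  range so that a single near-zero measurement cannot dominate the
  decomposition; for noiseless method-validation runs the tests use a
  much smaller floor (1e-9) since clipping is the only thing separating
  the fit from exact algebraic recovery.
- **Replicate collapsing.** Default is the arithmetic mean of abundances
  per condition cell (`mean_linear`), then log; geometric-mean
  collapsing (`mean_log`) is the alternative. For log-normal replicate
  noise of sd σ, `mean_linear` biases the collapsed log value upward by
  ≈ σ²/2 (second order; tested at σ = 0.2), while `mean_log` is
  unbiased; both are offered because abundance-scale averaging is the
  common field default. The per-gene, per-condition sd across replicates
  (log space, ddof = 1, zero for singleton cells) is the dispersion
  input to the error bars.

## Error bars on the multipliers

A perturbation δY of the log matrix propagates to the multipliers as
δλ_α(s) = G_·α · δY(·,s) at first order. Two summaries are implemented:

- **`norm_bound` (default).** Because the weight columns have unit norm,
  Cauchy–Schwarz gives |δλ_α(s)| ≤ ‖δY(·,s)‖, estimated as
  sqrt(Σ_i σ_i(s)²). This is a genuine upper bound, the same for every
  component, and deliberately conservative: with thousands of genes the
  realised |δλ_α(s)| concentrates far below it (the projection of a
  high-dimensional noise vector onto one direction is much shorter than
  the vector). This is the bar the pipeline draws, honouring the
  contract that the actual error is below the bar; the Monte-Carlo
  coverage test requires it to hold in ≥ 99% of replicate
  perturbations.
- **`propagated_sd`.** The first-order standard deviation
  sqrt(Σ_i G_iα² σ_i(s)²) under independent per-gene errors — a
  typical-error scale (≈ σ for constant dispersion), useful for judging
  how conservative the bound is, but *not* an upper bound: a Gaussian
  perturbation exceeds its own sd about a third of the time.
- **Bootstrap.** Resampling replicates within each condition,
  recollapsing and redecomposing gives an empirical per-λ sd as an
  assumption-free cross-check.

Both analytic forms are zero wherever the dispersion is zero and
monotone non-decreasing in every σ_i(s).

## Gene ranking and stability

Within a constraint, genes are ordered by G_iα descending; the 100
largest and 100 smallest weights are the differential lists (n
configurable). Ties break by gene ID so rankings are reproducible; any
gene-ID subset can be passed as a mask (e.g. a regulator list). Since
λ_0 > 0 by convention, the balanced-state call reduces to the sign of
G_i0: positive → stable (baseline abundance above 1 in the log's
units), negative → unstable; an exactly-zero weight is labelled
unstable and flagged. The per-sample direction of a constraint's effect
on a gene is the sign of G_iα λ_α(s).

## Set-ratio enrichment

For gene set J and constraint α, P = Σ G_iα² over member genes with
G_iα > 0 and N = Σ G_iα² over members with G_iα < 0; the set ratio is
SR = P/N. SR > 2 calls the set for the positive pole of the phenotype,
SR < 0.5 for the negative pole (thresholds configurable). Semantics at
the limits: an all-positive set has SR = +∞ (serialised as the token
`Inf`, never a sentinel number); an all-negative set has SR = 0; a set
whose members all have exactly zero weight has no defined ratio and is
flagged and excluded from ranking. Genes with exactly zero weight
contribute to neither sum (strict inequalities). Sets with fewer than
10 members *present in the fitted model* are omitted — the filter
exists for statistical support, so nominal set size is irrelevant.
Ranking places all-positive sets (by P descending) above finite ratios
in the positive direction and all-negative sets (by N descending) above
them in the negative direction. No significance test is attached to SR;
it is a descriptive enrichment weight.

## Synthetic data generator

The generator emulates the targeted study design: C dose levels × T
time points × R biological replicates (default 4 × 4 × 3), 2000 genes.
Noiseless log expression is b_i + G_i1 λ_1(cond) + G_i2 λ_2(cond) with:

- baseline b_i ~ N(2, 2) in log space, so stable and unstable genes
  both exist (≈ 84% above zero);
- each constraint loaded on a disjoint random 20% of genes (sparse, so
  top-100 lists are meaningful), unit-norm, orthogonalised to the
  baseline within its support;
- λ_1 = ±0.20·‖b‖ with positive sign on the exponential time points
  (t1, t2), λ_2 = ±0.10·‖b‖ with positive sign on the high-dose levels
  (ac3, ac4). The 10–20% energy ratio keeps λ_0 dominant (its relative
  range across samples stays well under the constraint/baseline ratio)
  and separates the two constraint singular values so the components do
  not mix;
- replicate noise: i.i.d. N(0, 0.1) in log space (multiplicative
  log-normal on abundances);
- planted gene sets of 30 genes drawn from the same-sign loaded genes
  of each constraint (two positive, two negative), plus uniform-random
  decoy sets and one deliberately undersized (5-gene) set to exercise
  the size filter.

One seeded RNG stream drives every draw in a fixed order, so a seed
reproduces the dataset bit for bit.

What the generator does **not** emulate: read-count sampling noise and
its mean–variance relation, library-size/length normalisation (FPKM
computation), missing replicates, correlated gene modules beyond the
two planted constraints, or condition-dependent dispersion. Passing the
recovery tests therefore shows the estimator and its contracts are
correct under the stated noise model — not that real RNA-seq data meet
that model.

## Auxiliary metrics

K-means (k = 3 by default, Euclidean distance on per-gene z-scored log
profiles, 10 seeded restarts keeping the best inertia) is provided as a
model-free view; rows are processed in gene-ID order and labels
renumbered by first appearance, making assignments reproducible and
permutation-consistent. Doublings per day between two sampled times is
log2(N_end/N_start)/((t_end − t_start)/24).

## Problem sizes in the test suite

The simulation studies run at the default conditions above: 100 seeds
for the sign-separation and planted-set criteria, 1000 Monte-Carlo
replicate perturbations for the error-bound coverage, 20 seeds × 4
noise levels (at 300 genes) for the noise-degradation sweep, and
brute-force eigensolver cross-checks on matrices up to 8 × 6. The whole
suite completes in well under a minute on one core.

## Known limitations

- The SVD route is the only estimator; no iterative maximal-entropy
  refinement is attempted.
- Samples are categorical conditions; time is not modelled as
  continuous.
- The balanced-state sign check requires a dominant common component;
  centred or signed input matrices are rejected by design.
- SR has no attached null distribution; with small sets, random weights
  can produce extreme ratios (visible on the decoy sets in the example
  analysis), which is why SR is reported together with P, N and the
  member count.
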