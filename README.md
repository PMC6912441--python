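# surprisalx

Surprisal analysis of bulk expression matrices: a tested pipeline that
decomposes log expression into a maximal-entropy **balanced state**
plus **constraints** via SVD, groups samples by the sign of the
per-sample Lagrange multipliers, ranks genes by constraint weight, and
scores gene sets with the **set ratio** statistic.

## Who this is for

Transcriptomics analyses of designed experiments — here, the motivating
case of a *Chlamydomonas reinhardtii* batch culture grown at four
acetate concentrations and sampled at four time points in biological
triplicate — where the question is not "which genes changed between two
groups" but "how few collective constraints explain the whole
expression matrix, and which experimental axes do they track".

## The model

For gene *i* in sample *s* with abundance X_i(s) (FPKM-like):

    ln X_i(s) = ln X_i0 + Σ_α G_iα λ_α(s),      ln X_i0 = G_i0 λ_0

estimated by SVD of the genes × samples log matrix. Component 0 is the
balanced state common to all samples; each constraint α ≥ 1 pairs a
gene-weight phenotype G_·α with per-sample multipliers λ_α(s) whose
*sign* groups the samples (exponential vs stationary growth for α = 1,
low vs high acetate for α = 2 in the motivating design). Gene sets are
scored per constraint by

    P = Σ_{G_iα>0} G_iα²,   N = Σ_{G_iα<0} G_iα²,   SR = P / N

with SR > 2 / SR < 0.5 calling a set for the positive / negative pole
of the phenotype, and sets with fewer than 10 genes in the model
omitted. Error bars on λ_α(s) are Cauchy–Schwarz upper bounds
propagated from replicate dispersion. See `docs/methods.md` for the
full account.

## Worked example

The package ships a generator that emulates the 4 × 4 × 3 study design
with two planted constraints and planted enriched gene sets, so the
whole pipeline runs without downloads. The numbered drivers under
`analysis/` run it end to end and write their tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_fit_surprisal.py
python analysis/03_rank_genes.py
python analysis/04_set_enrichment.py
python analysis/05_cluster_and_growth.py
```

Output of the first two steps:

```
wrote 2000 genes x 48 replicate samples
planted sets: planted_c1_pos, planted_c1_neg, planted_c2_pos, planted_c2_neg
genes with positive baseline log-abundance (planted stable): 1656

lambda_0 mean 124.74, range 0.30 (0.24% of its level; error bars ~4.46)
lambda_1 separates exponential vs stationary: True (agreement 1.00)
lambda_2 separates high vs low acetate: True (agreement 1.00)
```

Read: the balanced-state multiplier is constant across the 16
conditions to within a fraction of its upper-bound error bars — the
hallmark of a shared balanced state — while the first constraint's
multiplier changes sign exactly between growth phases and the second
between dose classes. Step 3 then reports 1659 of 2000 genes stable
(vs 1656 planted), and step 4 recovers the planted sets at the extremes
of the set-ratio ranking (`planted_c1_pos` SR = Inf,
`planted_c1_neg` SR = 0, and likewise for the dose constraint).

The same steps are available as a CLI (`surprisalx simulate`, `fit`,
`rank`, `enrich`, `cluster`, `growth`, `io validate`, `io collapse`) for
use on real matrices: a genes × samples TSV, a sample-design CSV
(sample_id, concentration_index, time_index, replicate_index) and gene
sets in GMT or two-column TSV.

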