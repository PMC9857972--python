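# Methods

## Model

Hi-C experiments report, for every pair of genomic bins (*beads*) `i, j`, a
contact count `c_ij`. `hicnb` infers a single consensus 3D configuration
`X = (x_1, …, x_n) ∈ R^{3×n}` by modeling the counts as independent
negative-binomial (NB) random variables whose mean decays as a power law of
the Euclidean distance `d_ij = ‖x_i − x_j‖`:

    C_ij ~ NB(mean μ_ij, dispersion r_ij)
    μ_ij = β · b_i · b_j · d_ij^α         (α < 0, β > 0)
    r_ij = b_i · b_j · r                  (r > 0)

with variance `σ²_ij = μ_ij + μ²_ij / r_ij`. The `b_i` are per-locus
multiplicative biases estimated by ICE balancing; `α` controls how fast
contacts decay with distance; `r` is a single genome-wide dispersion that
lets the variance exceed the Poisson value `σ² = μ`, which real Hi-C data
demand. As `r → ∞` the model reduces to a Poisson model with intensity
`μ_ij`, which is also provided as an alternative objective.

Two degeneracies are structural, not numerical: the likelihood depends on
`X` only through distances, so solutions are defined up to rotation,
translation and mirror image; and `β` trades off exactly against the overall
scale of `X` (`β d^α` is unchanged by `β → βs^{-α}, d → sd`), so `β` is
fixed to 1 during inference and absolute size is restored afterwards by
rescaling into a nucleus of chosen diameter.

## Dispersion estimation

`r` is estimated from the data before structure inference, exploiting the
fact that many bead pairs share the same genomic distance `l = |i − j|`
(bins, intra-chromosomal only). For each `l` we compute over all unfiltered
pairs the empirical mean `μ̃_l` and sample variance `ω̃_l` (ddof = 1) of the
normalized counts `c_ij/(b_i b_j)`, and correct the variance for the bias
spread, `σ̃²_l = ω̃_l / mean(1/(b_i b_j))`: under the model the variance of a
normalized count is `(d^α + d^{2α}/r)/(b_i b_j)`, so dividing by the mean
inverse bias product recovers the unit-bias variance. (The two readings of
the correction — multiply or divide — coincide for unit biases; division is
the direction that removes bias-induced inflation.) Inverting the NB moment
relation gives a per-distance dispersion `r̃_l = μ̃²_l/(σ̃²_l − μ̃_l)`, and the
global estimate is the pair-count-weighted average clamped at zero:

    r̂ = max(0, Σ_l w_l r̃_l / Σ_l w_l),   w_l = N_l .

Distances are dropped when: `l ≥ (2/3)·l_max` (strict; long-range moments
are unreliable, and the cutoff choice moves `r̂` by little), fewer than two
pairs exist, the mean or corrected variance is zero, or `σ̃²_l = μ̃_l` (the
inversion has a pole there). The pole test uses a relative tolerance of
1e−9 rather than exact equality: a count vector of all zeros plus a single
one has sample variance *exactly* equal to its mean in exact arithmetic,
and float roundoff otherwise turns that into `r̃_l` of order ±1e12.

A clamped estimate `r̂ ≈ 0` means the data show no overdispersion; the NB
PMF is undefined at `r = 0`, so the package warns and recommends the
Poisson objective in that case.

Caveats. The estimator assumes beads at equal genomic distance sit at
roughly equal spatial distance — exactly true for the helix test geometry,
approximately true for chromatin. The inversion `μ̃²/(σ̃² − μ̃)` is fat-tailed
when `μ̃_l` is small and `N_l` is modest: at `N_l ≈ 70` and `μ̃ = 0.5` only
about two-thirds of draws land within a factor of 2 of the truth even for a
single distance. Real Hi-C matrices have thousands of pairs per distance;
at the desk-scale simulations used in the tests (50–100 beads) the estimate
is correct in the median but individual seeds can miss a factor-of-2 band,
and it tends to underestimate `r` because spatial-distance spread at a
given genomic distance inflates the variance. Structure inference is
fortunately insensitive to `r` misspecification within an order of
magnitude (verified in the test suite by refitting with `r` and `10r`).

## Inference

Coordinates and `α` are fitted jointly by maximizing the summed NB log-PMF
over all pairs `i < j` of unfiltered beads (intra- and inter-chromosomal),
computed via log-Gamma:

    log P(c) = logΓ(c + r_ij) − logΓ(c + 1) − logΓ(r_ij)
             + c·(log μ_ij − log(r_ij + μ_ij)) + r_ij·(log r_ij − log(r_ij + μ_ij)).

Zero counts are kept in the objective by default: a pair never observed in
contact is evidence for a large separation, and dropping that information
measurably degrades recovery (tested, and reported by the acceptance
script). The analytic gradient flows through the mean only (`r` is held
fixed, so no digamma terms): `∂logP/∂μ = c/μ − (c + r_ij)/(r_ij + μ)`,
`∂μ/∂x_i = μ α (x_i − x_j)/d²`, `∂μ/∂α = μ log d`.

Numerical choices:

- `log μ` is formed analytically as `log(βb_ib_j) + α log d` so pairs whose
  mean underflows still contribute finite `c·log μ` terms; `log(r + μ)`
  uses `log1p`, which keeps the Poisson limit accurate at `r = 1e8`; the
  gradient uses the product `μ·∂logP/∂μ = c − (c + r_ij)μ/(r_ij + μ)`
  directly, which is finite for any `μ ≥ 0`.
- Distances are floored at `ε = 1e−8` inside `μ` so transiently coincident
  beads during optimization cannot overflow; with zero counts included the
  objective itself repels coincident beads.
- `α` is optimized as `α = −exp(a)`, enforcing negativity without box
  constraints on the interesting range; `a` is additionally bounded so that
  `α ∈ [−30, −0.05]`, wide enough for any realistic contact decay while
  preventing `d^α` overflow during line searches. Initial `α = −3`.
- The likelihood is non-convex, so L-BFGS-B (gradient tolerance 1e−5, at
  most 10 000 function evaluations) is restarted `n_init = 5` times from
  i.i.d. standard-normal coordinates; restart `k` uses a generator seeded
  with `seed + k`, making runs bit-reproducible. The restart with the
  highest final log-likelihood wins; exact ties break to the lowest index.
- Beads that are bias-filtered or have zero marginal count are excluded
  from the fit and returned as invalid (`NA`) coordinates.

## ICE balancing

Iterative correction repeats `b_i ← b_i · S_i / mean(S)`, where `S_i` is
the current normalized row sum over unfiltered loci, until
`max_i |S_i/mean(S) − 1| < tol` (defaults `tol = 1e−5`, 300 iterations).
Zero-marginal loci are always filtered; a `filter_fraction` of the
sparsest remaining loci can additionally be dropped, as is conventional for
real Hi-C (default 0 for synthetic data). Biases are normalized to
arithmetic mean 1 over unfiltered loci, pinning the scale degeneracy
between `b` and `β`.

## Synthetic data

The generator draws counts from exactly the model above — for each pair,
`C_ij ~ NB(β b_i b_j d_ij^α, γ b_i b_j)` via the gamma–Poisson mixture —
so coverage (`β`), overdispersion (`γ`, smaller = noisier, directly
comparable to the estimated `r`) and decay (`α`) can be swept
independently. Defaults define the study conditions: a 50-bead regular
helix (unit radius, unit rise per turn, 12 beads per turn — all adjacent
distances equal, and all pairs at one genomic distance share one spatial
distance), `α = −3`, `γ = 1`, unit biases, and a reference coverage
calibrated so the mean nearest-neighbour expected count is 100; coverage
sweeps scale that reference by `β_rel ∈ (0, 1]`. A unit-step random walk
and i.i.d. log-normal biases (rescaled to mean 1) are available as
alternatives.

What this emulates — and does not. The generator reproduces the power-law
mean decay, NB overdispersion and multiplicative biases of real Hi-C, so
passing tests demonstrate the statistical machinery end to end. It does
not emulate polymer physics (excluded volume, chain connectivity beyond
the helix geometry), domain structure, translocations, mappability gaps,
or single-cell sparsity; accuracy numbers on it are not forecasts for real
genomes. Because the model is self-consistent (simulator and likelihood
share one family), recovery here is an upper bound on what misspecified
real data allow.

## Evaluation metrics

Structure comparisons superpose one structure onto another by least-squares
(Kabsch, SVD). Reflection is allowed by default since chirality is
unidentifiable from distances; optional similarity alignment adds the
Procrustes scale, in which case the two directed RMSDs differ and their
average is reported. Recovery numbers in the tests and the acceptance
script follow one protocol: both structures are rescaled so all beads fit a
nucleus of diameter 100, then the averaged two-way similarity RMSD is
expressed as a percentage of the rescaled true structure's diameter,
alongside the Spearman correlation of the two upper-triangle distance
matrices. Supporting protocol operations: quantile-based nucleus rescaling
(quantile 1.0 = all beads inside; 0.99 leaves outliers out), resolution
coarsening by averaging runs of beads anchored at each chromosome start,
binomial thinning of counts, and joint invalidation of beads with zero
counts in either of two replicate matrices.

## Problem sizes and known limitations

Tests and the acceptance script use 50–100 beads, 10 simulation seeds and
5 restarts per fit — sizes chosen so the whole pipeline stays interactive
while leaving every statistical assertion well-posed; the method itself has
no such limit (cost is O(n²) per gradient evaluation). Known limitations:
consensus structures average over cell populations and can place
population-variable features (e.g. clustered telomeres) misleadingly;
the dispersion estimator's desk-scale variance discussed above; joint
whole-genome fits let inter-chromosomal pairs dominate `α` (observed in the
field, not mitigated here); and no nuclear-envelope or chain-connectivity
constraints are imposed.
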