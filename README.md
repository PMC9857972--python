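# hicnb

Consensus 3D genome structure inference from Hi-C contact maps, using a
negative-binomial likelihood that models the overdispersion real Hi-C data
show.

## The problem

A Hi-C experiment counts, for every pair of genomic bins *i, j*, how often
the two loci were captured in contact, yielding a symmetric matrix of
contact counts `c_ij`. Treating each bin as a bead in space, one can ask
for a single *consensus* 3D configuration `X = (x_1, …, x_n)` that best
explains the counts. Poisson models of `c_ij` force the variance to equal
the mean, but across organisms the per-genomic-distance variance of
normalized Hi-C counts sits far above the mean. `hicnb` models the counts
as negative binomial,

```
C_ij ~ NB(μ_ij, r_ij),   μ_ij = β b_i b_j d_ij^α,   r_ij = b_i b_j r,
```

with `d_ij = ‖x_i − x_j‖`, ICE biases `b_i`, decay exponent `α < 0` and a
global dispersion `r` estimated from the data (variance
`σ²_ij = μ_ij + μ²_ij/r_ij`; `r → ∞` recovers Poisson). Coordinates and
`α` are inferred jointly by multi-restart L-BFGS maximum likelihood, with
zero counts kept in the objective — a never-seen contact is evidence of
distance. The package is aimed at anyone reconstructing chromosome or
genome architecture from contact data, and at method developers who need a
self-consistent simulator and stability metrics.

Included, beside the estimator: ICE matrix balancing, the
per-genomic-distance dispersion estimator, a synthetic Hi-C generator with
tunable coverage/dispersion/decay, and evaluation tools (Kabsch/Procrustes
RMSD, distance-matrix Spearman, nucleus rescaling, resolution coarsening,
binomial downsampling, replicate bead filtering). See `docs/methods.md`
for the model details and design choices.

## Worked example

Simulate a 40-bead helix map, infer the structure with biases and
dispersion estimated automatically, and compare against the truth:

```
$ hicnb simulate --n-beads 40 --gamma 1.0 --seed 7 --out-dir demo
$ hicnb infer --counts demo/counts.tsv --bias auto --dispersion auto \
      --seed 0 --out-structure demo/inferred.tsv --out-log demo/run.json
Consensus 3D structure inference
================================================
objective:        nb
beads:            40 (40 active)
pairs in fit:     780
dispersion r:     1.3102739316926435
zero counts:      included
alpha-hat:        -3.05925
log-likelihood:   -1712.210644
restarts:         5 (best: #2)
...
$ hicnb evaluate --structure-a demo/inferred.tsv \
      --structure-b demo/true_structure.tsv --allow-scaling --quantile 1.0
RMSD    8.65178
Spearman        0.895261
```

Reading the output: the data were generated with dispersion `γ = 1` and
decay `α = −3`; the pipeline recovers `r ≈ 1.31` and `α̂ ≈ −3.06`. Five
random restarts agree on the optimum to six decimals except one trapped in
a poor local optimum (`α ≈ −0.25`), which the multi-start discards. The
evaluation rescales both structures into a nucleus of diameter 100 before
aligning, so the RMSD of 8.65 is in nucleus units (~5% of the structure
diameter) and the distance matrices correlate at ρ = 0.90.

The same operations are available as a library:

```python
from hicnb import (read_counts, ice_normalize, per_distance_stats,
                   estimate_dispersion, HiCStructureModel)

m = read_counts("demo/counts.tsv", "coo")
bias = ice_normalize(m).bias
r = estimate_dispersion(per_distance_stats(m, bias)).r
results = HiCStructureModel(m, bias, dispersion=r).fit(n_init=5, seed=0)
print(results.summary())          # per-restart table, alpha-hat, loglik
results.structure                 # Structure3D with invalid-bead mask
```

## File formats

Plain text throughout: dense whitespace matrices or `i j count` triplets
(`#` comments) for counts; `chrom bin x y z` per bead for structures, with
`NA` marking beads that could not be placed; `index bias-or-NA` per locus
for biases. See `hicnb --help` for the six subcommands
(`simulate`, `normalize`, `dispersion`, `infer`, `evaluate`, `downsample`).
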