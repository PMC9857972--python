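"""Synthetic Hi-C generator: ground-truth structures plus NB-distributed counts.

Counts are drawn from the same generative model the inference assumes:

    C_ij ~ NB(mean mu_ij = beta * b_i * b_j * d_ij^alpha,
              dispersion r_ij = gamma * b_i * b_j)

so that the coverage scale ``beta``, the dispersion tuning ``gamma``
(smaller = more overdispersed; the simulator's gamma is directly comparable
to the estimated global dispersion r) and the power-law exponent ``alpha``
can each be swept independently.  Sampling uses the gamma–Poisson mixture
construction of the negative binomial, which is reproducible and exact for
any positive (mean, dispersion) pair.

Ground-truth geometries are stand-ins with the right statistical character
(a smooth curve in space with equal adjacent spacing, or a random walk);
they carry no polymer-physics realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ContactMatrix, InputError, Structure3D
from .normalization import BiasVector

__all__ = [
    "SimulationConfig",
    "generate_structure",
    "generate_biases",
    "simulate_counts",
    "reference_beta",
]


@dataclass
class SimulationConfig:
    """Knobs of one synthetic experiment; identical config => identical data.

    ``beta`` is the absolute coverage scale.  Leave it ``None`` to use the
    reference coverage — calibrated so the mean nearest-neighbour count is
    ``target_nn_count`` (default 100) — times ``beta_rel``; coverage sweeps
    are fractions ``beta_rel in (0, 1]`` of that reference.
    """

    n_beads: int = 50
    structure_kind: str = "helix"
    alpha: float = -3.0
    beta: float | None = None
    beta_rel: float = 1.0
    gamma: float = 1.0
    bias_sd: float = 0.0  # sd of log-biases; 0 => unit biases
    target_nn_count: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beads < 2:
            raise InputError("n_beads must be >= 2")
        if not self.alpha < 0:
            raise InputError("alpha must be negative")
        if self.beta is not None and not self.beta > 0:
            raise InputError("beta must be positive")
        if not self.beta_rel > 0:
            raise InputError("beta_rel must be positive")
        if not self.gamma > 0:
            raise InputError("gamma must be positive")
        if self.bias_sd < 0:
            raise InputError("bias_sd must be non-negative")


def generate_structure(n: int, kind: str = "helix", seed: int = 0) -> Structure3D:
    """Deterministic ground-truth geometry: ``helix`` or ``random_walk``.

    The helix has unit radius and unit rise per turn, so all adjacent bead
    distances are equal by construction.  The random walk takes unit-length
    isotropic steps.
    """
    if n < 2:
        raise InputError("need at least 2 beads")
    if kind == "helix":
        theta = np.arange(n) * (np.pi / 6)
        coords = np.column_stack(
            [np.cos(theta), np.sin(theta), theta / (2 * np.pi)]
        )
    elif kind == "random_walk":
        rng = np.random.default_rng(seed)
        steps = rng.standard_normal((n - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    else:
        raise InputError(f"unknown structure kind {kind!r}")
    return Structure3D(coords)


def generate_biases(n: int, sd: float = 0.0, seed: int = 0) -> BiasVector:
    """I.i.d. log-normal per-locus biases rescaled to arithmetic mean 1.

    ``sd`` is the standard deviation of the log-biases; ``sd=0`` gives unit
    biases.  No locus is filtered.
    """
    if n < 1:
        raise InputError("need at least 1 locus")
    if sd < 0:
        raise InputError("sd must be non-negative")
    if sd == 0:
        return BiasVector.unit(n)
    rng = np.random.default_rng(seed)
    b = np.exp(rng.normal(0.0, sd, size=n))
    b /= b.mean()
    return BiasVector(b, np.zeros(n, dtype=bool))


def reference_beta(
    s: Structure3D, alpha: float, target_nn_count: float = 100.0
) -> float:
    """Coverage scale making the mean adjacent-bead expected count equal
    ``target_nn_count`` (the 100%-coverage reference of a sweep)."""
    d = np.linalg.norm(np.diff(s.coords[s.valid_mask], axis=0), axis=1)
    return float(target_nn_count / np.mean(d**alpha))


def simulate_counts(
    s: Structure3D, bias: BiasVector, cfg: SimulationConfig
) -> ContactMatrix:
    """Draw one NB contact map from a ground-truth structure.

    Every ``i < j`` pair gets an independent draw with mean
    ``beta b_i b_j d_ij^alpha`` and dispersion ``gamma b_i b_j``, sampled as
    Poisson(Gamma(shape=r_ij, scale=mu_ij/r_ij)) and mirrored below the
    diagonal.
    """
    if not np.all(s.valid_mask):
        raise InputError("ground-truth structure must have all beads valid")
    if bias.n != s.n:
        raise InputError("bias length does not match structure")
    if np.any(bias.filtered_mask):
        raise InputError("simulation requires unfiltered biases")
    n = s.n
    d = s.pairwise_distances()
    iu, ju = np.triu_indices(n, k=1)
    dv = d[iu, ju]
    if np.any(dv == 0):
        raise InputError("coincident beads in the ground-truth structure")

    beta = cfg.beta
    if beta is None:
        beta = cfg.beta_rel * reference_beta(s, cfg.alpha, cfg.target_nn_count)
    bb = bias.b[iu] * bias.b[ju]
    mu = beta * bb * dv**cfg.alpha
    r_ij = cfg.gamma * bb

    rng = np.random.default_rng(cfg.seed)
    lam = rng.gamma(shape=r_ij, scale=mu / r_ij)
    c = rng.poisson(lam)
    counts = np.zeros((n, n), dtype=np.int64)
    counts[iu, ju] = c
    counts[ju, iu] = c
    return ContactMatrix(counts, s.chrom, s.bin_index)
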