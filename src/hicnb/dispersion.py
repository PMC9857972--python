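"""Data-driven estimation of the negative-binomial dispersion parameter.

Hi-C counts are overdispersed: the variance of normalized counts at a given
genomic distance exceeds their mean, which a Poisson model (variance = mean)
cannot express.  The NB dispersion ``r`` controls the excess through
``sigma^2 = mu + mu^2 / r``; inverting this moment relation gives
``r = mu^2 / (sigma^2 - mu)``.

Estimation proceeds in two steps.  First, for every genomic distance ``l``
(separation ``|i - j|`` in bins along one chromosome), compute the empirical
mean and variance of the normalized counts over all intra-chromosomal pairs
at that distance — this rests on the working assumption that beads at equal
genomic distance sit at roughly equal spatial distance, used only here.
Second, invert the moment relation per distance and average the per-distance
dispersions, weighting by the number of pairs so that the well-populated
short distances dominate.  Long distances (beyond a cutoff fraction of the
largest distance) are dropped as unreliable, as are distances with zero
empirical mean or variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ContactMatrix, InputError
from .normalization import BiasVector

logger = logging.getLogger(__name__)

__all__ = ["DistanceStats", "DispersionEstimate", "per_distance_stats", "estimate_dispersion"]

#: dispersion below this is treated as the Poisson-degenerate clamp
R_POISSON_FLOOR = 1e-6


@dataclass
class DistanceStats:
    """Per-genomic-distance empirical moments of normalized contact counts.

    Arrays are aligned on ``l``; ``discarded`` marks distances excluded by
    the zero-mean / zero-variance rule or with fewer than two pairs.  The
    corrected variance divides the naive sample variance by the mean inverse
    bias product at that distance, undoing bias-induced variance inflation
    (with unit biases the correction factor is 1).
    """

    l: np.ndarray  # genomic distances present (bins)
    n_pairs: np.ndarray  # N_l
    mean: np.ndarray  # empirical mean of normalized counts
    var_biased: np.ndarray  # naive sample variance (ddof=1)
    var: np.ndarray  # corrected variance
    discarded: np.ndarray  # bool, excluded from dispersion estimation
    l_max: int  # largest distance with >= 2 pairs

    @property
    def weight(self) -> np.ndarray:
        """Estimation weight per distance: the number of pairs used."""
        return self.n_pairs


@dataclass
class DispersionEstimate:
    """Global NB dispersion ``r`` with the per-distance estimates behind it."""

    r: float
    stats: DistanceStats
    cutoff_fraction: float
    r_per_distance: np.ndarray  # r~_l on retained distances (may be negative)
    retained_l: np.ndarray


def per_distance_stats(m: ContactMatrix, bias: BiasVector | None = None) -> DistanceStats:
    """Empirical mean/variance of normalized counts at each genomic distance.

    Only intra-chromosomal, unfiltered pairs with ``i < j`` contribute;
    inter-chromosomal pairs have no genomic distance.  A distance needs at
    least two pairs for a sample variance; distances with zero mean or zero
    corrected variance are marked discarded.
    """
    if bias is None:
        bias = BiasVector.unit(m.n)
    if bias.n != m.n:
        raise InputError("bias length does not match matrix size")

    keep = ~bias.filtered_mask
    per_l: dict[int, list[tuple[float, float]]] = {}
    for ch in np.unique(m.chrom.astype(str)):
        idx = np.flatnonzero((m.chrom.astype(str) == ch) & keep)
        if idx.size < 2:
            continue
        # order beads along the chromosome so |i-j| in bins is the row offset
        idx = idx[np.argsort(m.bin_index[idx])]
        pos = m.bin_index[idx].astype(int)
        for a in range(len(idx)):
            for b_ in range(a + 1, len(idx)):
                l = int(pos[b_] - pos[a])
                i, j = idx[a], idx[b_]
                bb = bias.b[i] * bias.b[j]
                per_l.setdefault(l, []).append((m.counts[i, j] / bb, 1.0 / bb))

    if not per_l:
        raise InputError("no valid intra-chromosomal pair at any distance")

    ls = np.array(sorted(per_l))
    n_pairs = np.array([len(per_l[l]) for l in ls])
    mean = np.empty(len(ls))
    var_biased = np.full(len(ls), np.nan)
    var = np.full(len(ls), np.nan)
    discarded = np.zeros(len(ls), dtype=bool)
    for k, l in enumerate(ls):
        vals = np.array([v for v, _ in per_l[l]])
        inv_bb = np.array([w for _, w in per_l[l]])
        mean[k] = vals.mean()
        if len(vals) < 2:
            discarded[k] = True
            continue
        var_biased[k] = vals.var(ddof=1)
        var[k] = var_biased[k] / inv_bb.mean()
        if mean[k] == 0 or var[k] == 0:
            discarded[k] = True

    with_var = ls[n_pairs >= 2]
    if with_var.size == 0:
        raise InputError("no genomic distance has two or more pairs")
    return DistanceStats(ls, n_pairs, mean, var_biased, var, discarded, int(with_var.max()))


def estimate_dispersion(stats: DistanceStats, cutoff_fraction: float = 2 / 3) -> DispersionEstimate:
    """Weighted-average dispersion over short genomic distances.

    Retains distances with ``l < cutoff_fraction * l_max`` (strict), inverts
    the NB moment relation per distance, and returns the pair-count-weighted
    mean clamped at zero.  Underdispersed distances yield negative
    per-distance values and pull the average down; a clamped (near-zero)
    result means the data show no overdispersion and a Poisson objective is
    the better fit, which is reported as a warning.
    """
    if not 0 < cutoff_fraction <= 1:
        raise InputError("cutoff_fraction must lie in (0, 1]")
    cut = cutoff_fraction * stats.l_max
    sel = (stats.l < cut) & ~stats.discarded
    # degenerate var == mean gives an infinite dispersion estimate; skip it.
    # Equality must be tested to rounding tolerance: a count vector of zeros
    # plus a single one has sample variance exactly equal to its mean, and
    # float roundoff turns the exact-arithmetic singularity into r~_l of
    # order 1e12 with either sign.
    with np.errstate(invalid="ignore"):
        degen = sel & np.isclose(stats.var, stats.mean, rtol=1e-9, atol=0.0)
    if np.any(degen):
        logger.debug("skipping %d distance(s) with variance exactly equal to mean", degen.sum())
        sel &= ~degen
    if not np.any(sel):
        raise InputError("every genomic distance was discarded; cannot estimate dispersion")

    mu = stats.mean[sel]
    s2 = stats.var[sel]
    w = stats.weight[sel].astype(float)
    r_l = mu**2 / (s2 - mu)
    r = max(0.0, float(np.sum(w * r_l) / np.sum(w)))
    if r < R_POISSON_FLOOR:
        warnings.warn(
            "estimated dispersion is ~0 (no overdispersion); "
            "the NB likelihood degenerates — use the Poisson objective",
            stacklevel=2,
        )
    return DispersionEstimate(r, stats, cutoff_fraction, r_l, stats.l[sel])
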