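"""Structure comparison metrics and stability protocols.

Inferred structures are identified only up to rotation, translation, mirror
image (distance data cannot fix chirality) and — because the coverage scale
is dropped during inference — overall size.  Comparisons therefore go
through optimal superposition: Kabsch least-squares alignment with optional
reflection and scaling, followed by the root-mean-square deviation over
beads valid in both structures.  Rank correlation of the two pairwise
distance matrices gives a superposition-free alternative.

The stability protocols mirror common robustness checks: rescaling
structures into a nucleus of fixed diameter, coarsening a high-resolution
structure by coordinate averaging, binomial downsampling of counts, and
dropping beads with zero counts in either of two replicate maps before
comparing their structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .io import ContactMatrix, InputError, Structure3D

__all__ = [
    "AlignmentOptions",
    "rmsd",
    "distance_spearman",
    "rescale_structure",
    "coarsen_structure",
    "downsample_counts",
    "filter_common_beads",
]


@dataclass
class AlignmentOptions:
    """Superposition transform group: rigid motion always; reflection by
    default (chirality is unidentifiable from distances); scaling off by
    default (turn on to reproduce the two-way average-RMSD protocol)."""

    allow_reflection: bool = True
    allow_scaling: bool = False


def _common_valid(a: Structure3D, b: Structure3D) -> np.ndarray:
    if a.n != b.n:
        raise InputError(f"structures differ in size: {a.n} vs {b.n}")
    return a.valid_mask & b.valid_mask


def _superpose(src: np.ndarray, dst: np.ndarray, opts: AlignmentOptions) -> np.ndarray:
    """Least-squares map of ``src`` onto ``dst`` (Kabsch, optional scale)."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    p = src - mu_s
    q = dst - mu_d
    h = p.T @ q
    u, sing, vt = np.linalg.svd(h)
    sign = np.ones(3)
    if not opts.allow_reflection and np.linalg.det(u @ vt) < 0:
        sign[-1] = -1.0
    rot = u @ np.diag(sign) @ vt
    scale = 1.0
    if opts.allow_scaling:
        denom = (p**2).sum()
        if denom == 0:
            raise InputError("degenerate structure: all beads coincident")
        scale = float((sing * sign).sum() / denom)
    return scale * (p @ rot) + mu_d


def rmsd(a: Structure3D, b: Structure3D, opts: AlignmentOptions | None = None) -> float:
    """RMSD after optimal superposition over beads valid in both structures.

    Without scaling the value is symmetric in its arguments.  With scaling
    the superposition is direction-dependent, so the two directed RMSDs are
    computed and averaged.
    """
    opts = opts or AlignmentOptions()
    common = _common_valid(a, b)
    if common.sum() < 3:
        raise InputError("need at least 3 common valid beads")
    xa = a.coords[common]
    xb = b.coords[common]

    def directed(src, dst):
        fit = _superpose(src, dst, opts)
        return float(np.sqrt(((fit - dst) ** 2).sum(axis=1).mean()))

    if opts.allow_scaling:
        return 0.5 * (directed(xa, xb) + directed(xb, xa))
    return directed(xa, xb)


def distance_spearman(a: Structure3D, b: Structure3D) -> float:
    """Spearman rank correlation of upper-triangle pairwise distances."""
    common = _common_valid(a, b)
    if common.sum() < 3:
        raise InputError("need at least 3 common valid beads")
    iu, ju = np.triu_indices(int(common.sum()), k=1)
    da = a.pairwise_distances()[np.ix_(common, common)][iu, ju]
    db = b.pairwise_distances()[np.ix_(common, common)][iu, ju]
    if np.all(da == da[0]) or np.all(db == db[0]):
        raise InputError("constant distance vector; correlation undefined")
    rho = spearmanr(da, db).statistic
    return float(rho)


def rescale_structure(
    s: Structure3D, diameter: float = 100.0, quantile: float = 1.0
) -> Structure3D:
    """Center at the centroid and scale so the ``quantile`` radius of valid
    beads equals ``diameter / 2`` (quantile 1.0: all beads fit the nucleus;
    0.99: the sphere holds 99% of beads, outliers may protrude)."""
    if not diameter > 0:
        raise InputError("diameter must be positive")
    if not 0 < quantile <= 1:
        raise InputError("quantile must lie in (0, 1]")
    valid = s.valid_mask
    if valid.sum() < 1:
        raise InputError("no valid bead to rescale")
    out = s.copy()
    centroid = s.coords[valid].mean(axis=0)
    centered = s.coords - centroid
    radii = np.linalg.norm(centered[valid], axis=1)
    ref = float(np.quantile(radii, quantile))
    if ref == 0:
        raise InputError("all beads coincident; cannot rescale")
    out.coords = centered * (diameter / 2.0 / ref)
    out.coords[~valid] = np.nan
    return out


def coarsen_structure(s: Structure3D, factor: int = 1) -> Structure3D:
    """Average consecutive runs of ``factor`` beads within each chromosome.

    Emulates viewing a high-resolution structure at a coarser bin size.
    A group's coordinate is the mean of its valid beads; a group with no
    valid bead is invalid.  A trailing partial group averages what it has.
    """
    if factor < 1:
        raise InputError("factor must be >= 1")
    if factor == 1:
        return s.copy()
    coords, valid, chroms, bins = [], [], [], []
    for ch in dict.fromkeys(s.chrom.astype(str)):  # preserve chromosome order
        idx = np.flatnonzero(s.chrom.astype(str) == ch)
        idx = idx[np.argsort(s.bin_index[idx])]
        for g, start in enumerate(range(0, idx.size, factor)):
            grp = idx[start : start + factor]
            ok = grp[s.valid_mask[grp]]
            if ok.size:
                coords.append(s.coords[ok].mean(axis=0))
                valid.append(True)
            else:
                coords.append(np.full(3, np.nan))
                valid.append(False)
            chroms.append(ch)
            bins.append(g)
    return Structure3D(
        np.array(coords),
        np.array(valid),
        np.array(chroms, dtype=object),
        np.array(bins),
    )


def downsample_counts(m: ContactMatrix, fraction: float, seed: int = 0) -> ContactMatrix:
    """Binomial thinning: keep each contact independently with probability
    ``fraction``, preserving the count distribution's shape at lower
    coverage.  Deterministic given ``seed``."""
    if not 0 <= fraction <= 1:
        raise InputError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(m.n, k=1)
    thinned = rng.binomial(m.counts[iu, ju], fraction)
    counts = np.zeros_like(m.counts)
    counts[iu, ju] = thinned
    counts[ju, iu] = thinned
    return ContactMatrix(counts, m.chrom, m.bin_index, m.resolution)


def filter_common_beads(
    a: Structure3D,
    b: Structure3D,
    ma: ContactMatrix,
    mb: ContactMatrix,
) -> tuple[Structure3D, Structure3D]:
    """Invalidate, in both structures, beads with zero marginal count in
    either matrix (such beads were never constrained by data)."""
    if not (a.n == b.n == ma.n == mb.n):
        raise InputError("structures and matrices must have matching sizes")
    keep = (ma.marginal() > 0) & (mb.marginal() > 0)
    if not np.any(keep & a.valid_mask & b.valid_mask):
        raise InputError("no surviving bead after zero-count filtering")
    out_a, out_b = a.copy(), b.copy()
    for s in (out_a, out_b):
        s.valid_mask = s.valid_mask & keep
        s.coords[~s.valid_mask] = np.nan
    return out_a, out_b
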