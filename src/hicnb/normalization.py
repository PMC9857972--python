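"""ICE matrix balancing.

Raw Hi-C counts are biased by locus-specific multiplicative factors
(mappability, GC content, restriction-site density).  Iterative correction
(ICE) estimates a per-locus bias ``b_i`` such that the normalized matrix
``c_ij / (b_i b_j)`` has equal row sums over unfiltered loci, i.e. every
locus has the same total visibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .io import ContactMatrix, InputError

logger = logging.getLogger(__name__)

__all__ = ["BiasVector", "NormalizedMatrix", "ICEResult", "ice_normalize", "normalize_counts"]


@dataclass
class BiasVector:
    """Per-locus multiplicative bias with a filtered-locus mask.

    ``b[i]`` is defined (positive, mean 1 over unfiltered loci) only where
    ``filtered_mask[i]`` is False; filtered loci carry NaN.
    """

    b: np.ndarray
    filtered_mask: np.ndarray

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.filtered_mask = np.asarray(self.filtered_mask, dtype=bool)
        if self.b.shape != self.filtered_mask.shape:
            raise InputError("bias and mask length mismatch")
        ok = ~self.filtered_mask
        if np.any(~np.isfinite(self.b[ok])) or np.any(self.b[ok] <= 0):
            raise InputError("bias must be positive and finite on unfiltered loci")

    @classmethod
    def unit(cls, n: int) -> "BiasVector":
        return cls(np.ones(n), np.zeros(n, dtype=bool))

    @property
    def n(self) -> int:
        return self.b.shape[0]

    def outer(self) -> np.ndarray:
        """``b_i * b_j`` matrix, NaN where either locus is filtered."""
        return self.b[:, None] * self.b[None, :]


@dataclass
class NormalizedMatrix:
    """Bias-corrected counts ``c_ij / (b_i b_j)``; NaN where undefined."""

    values: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]


class ICEResult(NamedTuple):
    bias: BiasVector
    normalized: NormalizedMatrix
    converged: bool
    n_iter: int


def normalize_counts(m: ContactMatrix, bias: BiasVector) -> NormalizedMatrix:
    """Divide counts by the outer bias product; filtered pairs become NaN."""
    if bias.n != m.n:
        raise InputError(f"bias length {bias.n} != matrix size {m.n}")
    values = m.counts / bias.outer()
    values[bias.filtered_mask, :] = np.nan
    values[:, bias.filtered_mask] = np.nan
    return NormalizedMatrix(values)


def ice_normalize(
    m: ContactMatrix,
    max_iter: int = 300,
    tol: float = 1e-5,
    filter_fraction: float = 0.0,
) -> ICEResult:
    """Estimate ICE biases by iterative row-sum correction.

    Loci with zero marginal count are always filtered; additionally the
    ``filter_fraction`` fraction of lowest-marginal nonzero loci is removed
    before iteration (real Hi-C maps conventionally drop the sparsest bins).
    The update is ``b_i <- b_i * S_i / mean(S)`` where ``S_i`` is the current
    normalized row sum; iteration stops when
    ``max_i |S_i / mean(S) - 1| < tol``.  Biases are rescaled to arithmetic
    mean 1 over unfiltered loci, which pins the scale degeneracy between the
    biases and the coverage factor.
    """
    if not 0 <= filter_fraction < 1:
        raise InputError("filter_fraction must lie in [0, 1)")
    marg = m.marginal()
    filtered = marg == 0
    if np.all(filtered):
        raise InputError("no informative loci: contact matrix is entirely zero")
    if filter_fraction > 0:
        nonzero = np.flatnonzero(~filtered)
        k = int(np.floor(filter_fraction * nonzero.size))
        if k > 0:
            order = nonzero[np.argsort(marg[nonzero], kind="stable")]
            filtered[order[:k]] = True
    active = ~filtered
    if active.sum() < 2:
        raise InputError("fewer than two unfiltered loci after filtering")

    c = m.counts[np.ix_(active, active)].astype(float)
    b = np.ones(c.shape[0])
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        s = (c / np.outer(b, b)).sum(axis=1)
        mean_s = s.mean()
        if mean_s == 0:
            raise InputError("no informative loci: zero total count on active set")
        rel = s / mean_s
        if np.max(np.abs(rel - 1)) < tol:
            converged = True
            break
        b *= rel
    if not converged:
        logger.warning("ICE did not converge in %d iterations (tol=%g)", max_iter, tol)

    b /= b.mean()
    full_b = np.full(m.n, np.nan)
    full_b[active] = b
    bias = BiasVector(full_b, filtered)
    return ICEResult(bias, normalize_counts(m, bias), converged, n_iter)
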