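"""Maximum-likelihood inference of a consensus 3D structure from contact counts.

The model: contact counts are independent negative-binomial variables

    C_ij ~ NB(mean mu_ij, dispersion r_ij),
    mu_ij = beta * b_i * b_j * d_ij^alpha,    r_ij = b_i * b_j * r,

where ``d_ij`` is the Euclidean distance between beads ``i`` and ``j``,
``alpha < 0`` is the power-law count-to-distance exponent, ``b_i`` are the
ICE biases and ``r > 0`` the global dispersion.  The coverage factor
``beta`` is unidentifiable jointly with the overall scale of the structure
and is fixed to 1 during inference; absolute scale is restored afterwards
by rescaling to a nucleus size.  The variance is
``sigma_ij^2 = mu_ij + mu_ij^2 / r_ij``; as ``r -> inf`` the model reduces
to the Poisson objective with intensity ``mu_ij``.

The coordinates and ``alpha`` are fitted jointly by L-BFGS from several
random initializations (the likelihood is non-convex); the restart with the
highest final log-likelihood wins.  Zero counts are informative — a pair
observed zero times is evidence of a large distance — and are kept in the
objective by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .io import ContactMatrix, InputError, Structure3D
from .normalization import BiasVector

logger = logging.getLogger(__name__)

__all__ = [
    "NBParams",
    "HiCStructureModel",
    "StructureResults",
    "RestartInfo",
    "nb_log_likelihood",
    "poisson_log_likelihood",
    "nb_gradient",
    "infer_structure",
]

#: distance floor inside mu_ij, guarding against transiently coincident beads
DISTANCE_FLOOR = 1e-8


@dataclass
class NBParams:
    """Parameters of the count model: exponent ``alpha`` (< 0), coverage
    ``beta`` (> 0, fixed to 1 during inference) and dispersion ``r`` (> 0)."""

    alpha: float
    r: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not self.alpha < 0:
            raise InputError(f"alpha must be negative, got {self.alpha}")
        if not self.r > 0:
            raise InputError(f"dispersion r must be positive, got {self.r}")
        if not self.beta > 0:
            raise InputError(f"beta must be positive, got {self.beta}")


# ---------------------------------------------------------------------------
# pair bookkeeping


class _Pairs:
    """Flattened upper-triangle pairs entering the likelihood."""

    def __init__(
        self,
        m: ContactMatrix,
        bias: BiasVector,
        active: np.ndarray,
        include_zeros: bool,
    ) -> None:
        idx = np.flatnonzero(active)
        ii, jj = np.triu_indices(idx.size, k=1)
        self.i = idx[ii]  # global bead index, first of pair
        self.j = idx[jj]
        self.c = m.counts[self.i, self.j].astype(float)
        if not include_zeros:
            nz = self.c > 0
            self.i, self.j, self.c = self.i[nz], self.j[nz], self.c[nz]
        self.bb = bias.b[self.i] * bias.b[self.j]
        self.active = active
        # local positions within the active-bead coordinate block
        pos = np.full(len(active), -1)
        pos[idx] = np.arange(idx.size)
        self.li = pos[self.i]
        self.lj = pos[self.j]
        self.n_active = idx.size

    def distances(self, coords_active: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        diff = coords_active[self.li] - coords_active[self.lj]
        d = np.sqrt((diff**2).sum(axis=1))
        return np.maximum(d, DISTANCE_FLOOR), diff


def _check_structure(X: Structure3D, m: ContactMatrix) -> None:
    if X.n != m.n:
        raise InputError(f"structure has {X.n} beads, matrix has {m.n}")
    if np.any(~np.isfinite(X.coords[X.valid_mask])):
        raise InputError("non-finite coordinates on a valid bead")


def _pairs_from_structure(
    X: Structure3D, m: ContactMatrix, bias: BiasVector, include_zeros: bool
) -> tuple[_Pairs, np.ndarray]:
    _check_structure(X, m)
    active = X.valid_mask & ~bias.filtered_mask
    pairs = _Pairs(m, bias, active, include_zeros)
    return pairs, X.coords[active]


# ---------------------------------------------------------------------------
# likelihoods and gradients (functional surface)


def _nb_terms(c, log_mu, mu, r_ij):
    """Per-pair NB log-PMF via log-Gamma.

    ``log_mu`` is supplied analytically (log beta + log b_i b_j + alpha log d)
    so that pairs whose mean underflows to zero still contribute a finite
    ``c * log_mu`` term.
    """
    ratio = mu / r_ij
    log_rm = np.log(r_ij) + np.log1p(ratio)  # log(r_ij + mu), stable for mu << r_ij
    return (
        gammaln(c + r_ij)
        - gammaln(c + 1.0)
        - gammaln(r_ij)
        + c * (log_mu - log_rm)
        - r_ij * np.log1p(ratio)
    )


def nb_log_likelihood(
    X: Structure3D,
    params: NBParams,
    m: ContactMatrix,
    bias: BiasVector | None = None,
    include_zeros: bool = True,
) -> float:
    """Negative-binomial log-likelihood of a structure given counts.

    Sums the NB log-PMF over all pairs ``i < j`` of valid, unfiltered beads
    (intra- and inter-chromosomal); pairs with zero count are included
    unless ``include_zeros`` is False.
    """
    if bias is None:
        bias = BiasVector.unit(m.n)
    pairs, coords = _pairs_from_structure(X, m, bias, include_zeros)
    d, _ = pairs.distances(coords)
    log_mu = np.log(params.beta * pairs.bb) + params.alpha * np.log(d)
    r_ij = pairs.bb * params.r
    return float(_nb_terms(pairs.c, log_mu, np.exp(log_mu), r_ij).sum())


def poisson_log_likelihood(
    X: Structure3D,
    alpha: float,
    m: ContactMatrix,
    bias: BiasVector | None = None,
    include_zeros: bool = True,
    beta: float = 1.0,
) -> float:
    """Poisson log-likelihood with intensity ``beta b_i b_j d_ij^alpha``
    — the infinite-dispersion limit of the NB objective."""
    if not alpha < 0:
        raise InputError(f"alpha must be negative, got {alpha}")
    if bias is None:
        bias = BiasVector.unit(m.n)
    pairs, coords = _pairs_from_structure(X, m, bias, include_zeros)
    d, _ = pairs.distances(coords)
    log_mu = np.log(beta * pairs.bb) + alpha * np.log(d)
    return float(np.sum(pairs.c * log_mu - np.exp(log_mu) - gammaln(pairs.c + 1.0)))


def _loglik_and_grad(
    coords_active: np.ndarray,
    alpha: float,
    pairs: _Pairs,
    r: float | None,
    model: str,
    beta: float = 1.0,
) -> tuple[float, np.ndarray, float]:
    """Log-likelihood, coordinate gradient (active beads) and d/dalpha.

    The gradient flows through the mean only: with the dispersion held
    fixed, d logP / d mu = c/mu - (c + r_ij)/(r_ij + mu), and the chain
    rule through mu_ij = beta b_i b_j d_ij^alpha gives
    d mu / d x_i = mu * alpha * (x_i - x_j) / d^2 and
    d mu / d alpha = mu * log d.  No digamma terms arise.  The product
    mu * d logP / d mu is formed directly (c - (c + r_ij) mu / (r_ij + mu)),
    which stays finite even when mu underflows.
    """
    d, diff = pairs.distances(coords_active)
    log_d = np.log(d)
    log_mu = np.log(beta * pairs.bb) + alpha * log_d
    mu = np.exp(log_mu)
    if model == "nb":
        r_ij = pairs.bb * r
        ll = float(_nb_terms(pairs.c, log_mu, mu, r_ij).sum())
        gmu = pairs.c - (pairs.c + r_ij) * mu / (r_ij + mu)  # mu * dlogP/dmu
    else:
        ll = float(np.sum(pairs.c * log_mu - mu - gammaln(pairs.c + 1.0)))
        gmu = pairs.c - mu
    # coordinate gradient: accumulate +/- pair contributions on each bead
    coef = (gmu * alpha / d**2)[:, None] * diff
    grad = np.zeros_like(coords_active)
    np.add.at(grad, pairs.li, coef)
    np.add.at(grad, pairs.lj, -coef)
    grad_alpha = float(np.sum(gmu * log_d))
    return ll, grad, grad_alpha


def nb_gradient(
    X: Structure3D,
    params: NBParams,
    m: ContactMatrix,
    bias: BiasVector | None = None,
    include_zeros: bool = True,
) -> tuple[np.ndarray, float]:
    """Analytic gradient of the NB log-likelihood.

    Returns an ``(n, 3)`` array (rows of invalid/filtered beads are zero)
    and the scalar derivative with respect to ``alpha``.
    """
    if bias is None:
        bias = BiasVector.unit(m.n)
    pairs, coords = _pairs_from_structure(X, m, bias, include_zeros)
    _, grad_active, grad_alpha = _loglik_and_grad(
        coords, params.alpha, pairs, params.r, "nb", params.beta
    )
    grad = np.zeros((m.n, 3))
    grad[pairs.active] = grad_active
    return grad, grad_alpha


# ---------------------------------------------------------------------------
# model / results


@dataclass
class RestartInfo:
    seed: int
    loglik: float
    converged: bool
    n_iter: int
    alpha: float
    message: str = ""


class StructureResults:
    """Fit results: best structure, fitted exponent, log-likelihood and the
    per-restart optimization trace."""

    def __init__(
        self,
        model: "HiCStructureModel",
        structure: Structure3D,
        alpha: float,
        loglik: float,
        restarts: list[RestartInfo],
        best_index: int,
    ) -> None:
        self.model = model
        self.structure = structure
        self.alpha = alpha
        self.loglik = loglik
        self.restarts = restarts
        self.best_index = best_index

    @property
    def alpha_hat(self) -> float:
        return self.alpha

    def summary(self) -> str:
        m = self.model
        lines = [
            "Consensus 3D structure inference",
            "=" * 48,
            f"objective:        {m.objective}",
            f"beads:            {m.counts.n} ({int(m.active.sum())} active)",
            f"pairs in fit:     {m._pairs.c.size}",
            f"dispersion r:     {m.dispersion if m.dispersion is not None else '-'}",
            f"zero counts:      {'included' if m.include_zeros else 'excluded'}",
            f"alpha-hat:        {self.alpha:.6g}" + ("  (fixed)" if m._fixed_alpha else ""),
            f"log-likelihood:   {self.loglik:.6f}",
            f"restarts:         {len(self.restarts)} (best: #{self.best_index})",
            "-" * 48,
            "restart   loglik           alpha      converged  iters",
        ]
        for k, rs in enumerate(self.restarts):
            mark = "*" if k == self.best_index else " "
            lines.append(
                f"{mark}{k:<8d} {rs.loglik:<16.6f} {rs.alpha:<10.4f} "
                f"{str(rs.converged):<10s} {rs.n_iter}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<StructureResults loglik={self.loglik:.4f} alpha={self.alpha:.4f} "
            f"n={self.structure.n}>"
        )


class HiCStructureModel:
    """Joint maximum-likelihood model for bead coordinates and the
    count-to-distance exponent.

    Parameters
    ----------
    counts
        Symmetric contact matrix.
    bias
        ICE bias vector; unit biases if omitted.
    dispersion
        Global NB dispersion ``r`` (> 0).  Required for the ``"nb"``
        objective, ignored by ``"poisson"``.
    objective
        ``"nb"`` (default) or ``"poisson"``.
    include_zeros
        Keep zero-count pairs in the objective (default True); excluding
        them discards the long-range repulsive information they carry.

    Beads that are bias-filtered or have zero marginal count cannot be
    placed and come back invalid (NA) in the fitted structure.
    """

    def __init__(
        self,
        counts: ContactMatrix,
        bias: BiasVector | None = None,
        dispersion: float | None = None,
        objective: str = "nb",
        include_zeros: bool = True,
    ) -> None:
        if objective not in ("nb", "poisson"):
            raise InputError(f"unknown objective {objective!r}")
        if objective == "nb":
            if dispersion is None or not dispersion > 0:
                raise InputError("the NB objective requires a positive dispersion r")
        self.counts = counts
        self.bias = bias if bias is not None else BiasVector.unit(counts.n)
        if self.bias.n != counts.n:
            raise InputError("bias length does not match matrix size")
        self.dispersion = dispersion
        self.objective = objective
        self.include_zeros = include_zeros
        self.active = (counts.marginal() > 0) & ~self.bias.filtered_mask
        if self.active.sum() < 2:
            raise InputError("fewer than two active beads; nothing to infer")
        self._pairs = _Pairs(counts, self.bias, self.active, include_zeros)
        self._fixed_alpha: float | None = None

    @classmethod
    def from_files(
        cls,
        counts_path,
        format: str = "dense",
        bias_path=None,
        dispersion: float | None = None,
        **kwargs,
    ) -> "HiCStructureModel":
        """Build a model from a counts file and an optional bias file."""
        from .io import read_counts
        from .cli import read_bias_file

        m = read_counts(counts_path, format)
        bias = read_bias_file(bias_path, m.n) if bias_path is not None else None
        return cls(m, bias, dispersion, **kwargs)

    # -- objective ---------------------------------------------------------

    def _negloglik(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        n_act = self._pairs.n_active
        coords = theta[: 3 * n_act].reshape(n_act, 3)
        if self._fixed_alpha is not None:
            alpha = self._fixed_alpha
        else:
            alpha = -np.exp(theta[-1])
        ll, grad_x, grad_a = _loglik_and_grad(
            coords, alpha, self._pairs, self.dispersion, self.objective
        )
        if self._fixed_alpha is not None:
            g = -grad_x.ravel()
        else:
            # chain rule through alpha = -exp(a): d/da = alpha * d/dalpha
            g = -np.concatenate([grad_x.ravel(), [alpha * grad_a]])
        return -ll, g

    def loglike(self, structure: Structure3D, alpha: float) -> float:
        """Log-likelihood of an explicit structure under this model."""
        if self.objective == "nb":
            return nb_log_likelihood(
                structure,
                NBParams(alpha, self.dispersion),
                self.counts,
                self.bias,
                self.include_zeros,
            )
        return poisson_log_likelihood(
            structure, alpha, self.counts, self.bias, self.include_zeros
        )

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        n_init: int = 5,
        seed: int = 0,
        fix_alpha: float | None = None,
        alpha0: float = -3.0,
        gtol: float = 1e-5,
        maxfun: int = 10_000,
    ) -> StructureResults:
        """Run ``n_init`` L-BFGS restarts and keep the best local optimum.

        Restart ``k`` draws its initial coordinates i.i.d. standard normal
        from a generator seeded with ``seed + k`` (bit-reproducible).
        ``alpha`` is optimized through the substitution
        ``alpha = -exp(a)``, which enforces negativity without bounds;
        ``fix_alpha`` holds it at a given value instead.  Ties in final
        log-likelihood break toward the lowest restart index.
        """
        if n_init < 1:
            raise InputError("n_init must be >= 1")
        if fix_alpha is not None and not fix_alpha < 0:
            raise InputError("fix_alpha must be negative")
        self._fixed_alpha = fix_alpha
        n_act = self._pairs.n_active

        restarts: list[RestartInfo] = []
        best: tuple[float, np.ndarray] | None = None
        best_idx = -1
        for k in range(n_init):
            rng = np.random.default_rng(seed + k)
            x0 = rng.standard_normal(n_act * 3)
            if fix_alpha is None:
                theta0 = np.concatenate([x0, [np.log(-alpha0)]])
                # keep alpha in [-30, -0.05]: wide enough for any realistic
                # contact decay, tight enough to avoid overflow in d^alpha
                bounds = [(None, None)] * (3 * n_act) + [(np.log(0.05), np.log(30.0))]
            else:
                theta0 = x0
                bounds = None
            res = minimize(
                self._negloglik,
                theta0,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"gtol": gtol, "maxfun": maxfun},
            )
            alpha_k = fix_alpha if fix_alpha is not None else -np.exp(res.x[-1])
            restarts.append(
                RestartInfo(
                    seed=seed + k,
                    loglik=-float(res.fun),
                    converged=bool(res.success),
                    n_iter=int(res.nit),
                    alpha=float(alpha_k),
                    message=str(res.message),
                )
            )
            logger.debug(
                "restart %d: loglik=%.6f alpha=%.4f converged=%s",
                k, -res.fun, alpha_k, res.success,
            )
            if np.isfinite(res.fun) and (best is None or -res.fun > best[0]):
                best = (-float(res.fun), res.x.copy())
                best_idx = k
        if best is None:
            raise RuntimeError(
                "optimizer failed on all restarts: "
                + "; ".join(r.message for r in restarts)
            )

        loglik, theta = best
        coords = np.full((self.counts.n, 3), np.nan)
        coords[self.active] = theta[: 3 * n_act].reshape(n_act, 3)
        structure = Structure3D(
            coords, self.active.copy(), self.counts.chrom, self.counts.bin_index
        )
        alpha_hat = restarts[best_idx].alpha
        logger.info(
            "best restart #%d: loglik=%.6f alpha=%.4f", best_idx, loglik, alpha_hat
        )
        return StructureResults(self, structure, alpha_hat, loglik, restarts, best_idx)


def infer_structure(
    m: ContactMatrix,
    bias: BiasVector | None = None,
    r: float = 1.0,
    n_init: int = 5,
    seed: int = 0,
    include_zeros: bool = True,
    fix_alpha: float | None = None,
    objective: str = "nb",
) -> StructureResults:
    """Functional one-call wrapper around :class:`HiCStructureModel`."""
    model = HiCStructureModel(
        m,
        bias,
        dispersion=r if objective == "nb" else None,
        objective=objective,
        include_zeros=include_zeros,
    )
    return model.fit(n_init=n_init, seed=seed, fix_alpha=fix_alpha)
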