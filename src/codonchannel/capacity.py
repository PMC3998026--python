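"""Channel capacity of a discrete memoryless channel by Arimoto–Blahut.

The algorithm alternates two steps from a strictly positive input
distribution p (uniform by default):

1.  c(x_j) = exp( sum_k P(y_k|x_j) ln[ P(y_k|x_j) / q(y_k) ] )
    with q = p @ P the induced output distribution;
2.  p(x_j) <- p(x_j) c(x_j) / sum_j p(x_j) c(x_j).

At every iteration the capacity C is sandwiched,

    ln sum_j p(x_j) c(x_j)  <=  C  <=  ln max_j c(x_j),

the lower bound is non-decreasing, and the iteration stops when the gap
falls below the requested tolerance.  Internally everything is kept in
natural-log domain for numerical stability; reported values are in bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import logsumexp, xlogy

from .distributions import LN2
from .matrix_io import ChannelMatrix, Distribution, MatrixValidationError

#: Probability floor keeping iterates strictly positive (an AB requirement).
PROB_FLOOR = 1e-300


@dataclass(frozen=True)
class CapacityResult:
    """Capacity in bits with the optimizing input and convergence record."""

    capacity: float
    optimal_input: Distribution
    iterations: int
    final_gap: float
    converged: bool
    lower_bounds: np.ndarray = field(repr=False, default=None)
    upper_bounds: np.ndarray = field(repr=False, default=None)


def arimoto_blahut(
    P: ChannelMatrix,
    init: Optional[Distribution] = None,
    tol: float = 1e-9,
    max_iter: int = 100_000,
    seed: Optional[int] = None,
) -> CapacityResult:
    """Compute channel capacity and the capacity-achieving input distribution.

    Parameters
    ----------
    P:
        Row-stochastic channel matrix; no all-zero rows (guaranteed by
        :class:`~codonchannel.matrix_io.ChannelMatrix` validation).
    init:
        Starting input distribution; must be strictly positive.  Default is
        uniform.  Ignored when *seed* is given, in which case a random
        strictly-positive start is drawn (the capacity value is independent
        of the start; only the iterate path differs).
    tol:
        Termination threshold on the upper−lower capacity-bound gap, bits.
    max_iter:
        Iteration cap; if reached the best lower bound is returned with
        ``converged=False``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    M = P.probs
    n = M.shape[0]
    if seed is not None:
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(n))
        p = np.maximum(p, 1e-12)
        p /= p.sum()
    elif init is not None:
        if init.labels != P.labels:
            init = init.reorder(P.labels)
        p = init.probs.copy()
        if np.any(p <= 0):
            raise MatrixValidationError(
                "Arimoto-Blahut initialization must be strictly positive"
            )
    else:
        p = np.full(n, 1.0 / n)

    # Precompute per-row entropy term sum_k P_jk ln P_jk (0 ln 0 = 0).
    row_plogp = xlogy(M, M).sum(axis=1)

    log_tol_nats = tol * LN2
    lowers, uppers = [], []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        q = p @ M
        # ln c_j = sum_k P_jk ln(P_jk / q_k); columns with q_k = 0 have
        # P_jk = 0 for all j (p is strictly positive), so they drop out.
        with np.errstate(divide="ignore"):
            log_q = np.where(q > 0, np.log(np.maximum(q, PROB_FLOOR)), 0.0)
        log_c = row_plogp - M @ np.where(q > 0, log_q, 0.0)
        log_p = np.log(np.maximum(p, PROB_FLOOR))
        lower = logsumexp(log_p + log_c)
        upper = log_c.max()
        lowers.append(lower / LN2)
        uppers.append(upper / LN2)
        p = np.exp(log_p + log_c - lower)
        p = np.maximum(p, PROB_FLOOR)
        p /= p.sum()
        if upper - lower <= log_tol_nats:
            converged = True
            break

    capacity_bits = max(lowers[-1], 0.0)
    return CapacityResult(
        capacity=capacity_bits,
        optimal_input=Distribution.from_values(P.labels, p),
        iterations=it,
        final_gap=uppers[-1] - lowers[-1],
        converged=converged,
        lower_bounds=np.asarray(lowers),
        upper_bounds=np.asarray(uppers),
    )
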