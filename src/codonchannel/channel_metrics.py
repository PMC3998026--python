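"""Mutual information, conditional entropy and KL divergence for a fixed channel.

All quantities are in bits.  For an input distribution p_x and channel
P(y|x):

* output distribution  p_y(j) = sum_i p_x(i) P(y_j|x_i)
* conditional entropy  H(Y|X) = -sum_i p_x(i) sum_j P(y_j|x_i) log2 P(y_j|x_i)
* mutual information   I(X;Y) = H(Y) - H(Y|X)

H(Y|X) is the "prevarication" (irrelevance) of the channel: the part of the
output entropy produced by channel noise rather than by the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr, xlogy

from .distributions import LN2, entropy
from .matrix_io import ChannelMatrix, Distribution, MatrixFormatError


def _align(p_x: Distribution, P: ChannelMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Return (input vector, matrix) aligned on the channel's label order."""
    if p_x.labels != P.labels:
        if set(p_x.labels) != set(P.labels):
            unmatched = sorted(set(p_x.labels) ^ set(P.labels))
            raise MatrixFormatError(f"input/channel labels differ: {unmatched}")
        p_x = p_x.reorder(P.labels)
    return p_x.probs, P.probs


def output_distribution(p_x: Distribution, P: ChannelMatrix) -> Distribution:
    """Propagate the input distribution through the channel: p_y = p_x @ P."""
    p, M = _align(p_x, P)
    return Distribution.from_values(P.labels, p @ M)


def conditional_entropy(p_x: Distribution, P: ChannelMatrix) -> float:
    """H(Y|X) in bits, 0*log(0) terms contributing zero."""
    p, M = _align(p_x, P)
    row_ent = -xlogy(M, M).sum(axis=1) / LN2
    return float(p @ row_ent)


@dataclass(frozen=True)
class ChannelEvaluation:
    """I(X;Y) together with its H(Y) − H(Y|X) decomposition."""

    mutual_information: float
    output_entropy: float
    conditional_entropy: float
    output_distribution: Distribution


def mutual_information(p_x: Distribution, P: ChannelMatrix) -> ChannelEvaluation:
    """Evaluate I(X;Y) = H(Y) − H(Y|X) for a fixed input distribution."""
    p_y = output_distribution(p_x, P)
    h_y = entropy(p_y)
    h_y_given_x = conditional_entropy(p_x, P)
    mi = max(h_y - h_y_given_x, 0.0)
    return ChannelEvaluation(
        mutual_information=mi,
        output_entropy=h_y,
        conditional_entropy=h_y_given_x,
        output_distribution=p_y,
    )


def kl_divergence(p: Distribution, q: Distribution) -> float:
    """D_KL(p || q) in bits.

    Nonnegative, zero iff the distributions coincide.  Where q has zero
    mass but p does not, the divergence is +inf (reported with a warning
    rather than raised): no code built on q can represent those outcomes.
    """
    if p.labels != q.labels:
        if set(p.labels) != set(q.labels):
            unmatched = sorted(set(p.labels) ^ set(q.labels))
            raise MatrixFormatError(f"distribution labels differ: {unmatched}")
        q = q.reorder(p.labels)
    val = float(rel_entr(p.probs, q.probs).sum() / LN2)
    if np.isinf(val):
        warnings.warn(
            "KL divergence is infinite: q assigns zero mass where p does not",
            stacklevel=2,
        )
    return val
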