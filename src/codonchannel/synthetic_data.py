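"""Synthetic channels, count matrices, and packaged codon-frequency fixtures.

Channels with closed-form capacity (symmetric, weakly symmetric, binary
symmetric, Z) serve as independent oracles for the Arimoto–Blahut
implementation; the reversible codon channel is an ECM-like surrogate — a
61x61 reversible mutation matrix with a prescribed stationary profile —
for end-to-end pipeline tests.  It is NOT the published empirical codon
mutation matrix, only a stand-in with the same structural character
(reversibility, codon-frequency-shaped equilibrium).

Two codon relative-frequency tables observed/derived for five vertebrate
genomes are packaged as 4-decimal TSV fixtures: the biological codon usage
(64 codons, tiny stop-codon mass) and the capacity-achieving usage
(61 sense codons).
"""

from __future__ import annotations

from importlib import resources
from typing import Optional, Tuple

import numpy as np

from .distributions import LN2, entropy
from .genetic_code import standard_code
from .matrix_io import (
    ChannelMatrix,
    CountMatrix,
    Distribution,
    MatrixValidationError,
    read_distribution,
)


def _generic_labels(K: int) -> Tuple[str, ...]:
    """Labels for non-codon channels; codon labels when K matches 61."""
    if K == 61:
        return standard_code().sense_order
    width = len(str(K - 1))
    return tuple(f"s{i:0{width}d}" for i in range(K))


def make_symmetric_channel(
    K: int, noise: float, seed: Optional[int] = None
) -> Tuple[ChannelMatrix, float]:
    """Symmetric channel: diagonal 1−noise, off-diagonal noise/(K−1).

    Returns the channel together with its closed-form capacity
    log2(K) − H(row) in bits; the optimal input is uniform.
    """
    if not 0.0 <= noise <= (K - 1) / K:
        raise ValueError(f"noise must lie in [0, {(K - 1) / K}], got {noise}")
    off = noise / (K - 1)
    M = np.full((K, K), off)
    np.fill_diagonal(M, 1.0 - noise)
    labels = _generic_labels(K)
    channel = ChannelMatrix(labels, M)
    row = Distribution.from_values(labels, M[0])
    return channel, float(np.log2(K) - entropy(row))


def make_binary_symmetric_channel(flip: float) -> Tuple[ChannelMatrix, float]:
    """BSC with crossover *flip*; capacity 1 − h(flip) bits."""
    return make_symmetric_channel(2, flip)


def make_weakly_symmetric_channel(
    K: int, seed: int
) -> Tuple[ChannelMatrix, float]:
    """Circulant channel from a random simplex row.

    Rows are cyclic shifts of one another and column sums are equal, so
    the capacity has the closed form log2(K) − H(row) with uniform
    optimal input.
    """
    rng = np.random.default_rng(seed)
    row = rng.dirichlet(np.ones(K))
    M = np.empty((K, K))
    for i in range(K):
        M[i] = np.roll(row, i)
    labels = _generic_labels(K)
    channel = ChannelMatrix(labels, M)
    return channel, float(np.log2(K) - entropy(Distribution.from_values(labels, row)))


def make_z_channel(flip: float) -> ChannelMatrix:
    """Z-channel: symbol 0 is transmitted faithfully, symbol 1 flips with *flip*."""
    if not 0.0 <= flip < 1.0:
        raise ValueError(f"flip must lie in [0, 1), got {flip}")
    M = np.array([[1.0, 0.0], [flip, 1.0 - flip]])
    return ChannelMatrix(("s0", "s1"), M)


def make_reversible_codon_channel(
    stationary: Distribution,
    roughness: float = 0.5,
    seed: int = 0,
    self_weight: float = 0.85,
) -> ChannelMatrix:
    """Reversible 61x61 surrogate mutation channel shaped by *stationary*.

    Construction: a seeded symmetric exchangeability matrix
    S = (A + A^T)/2 with A_ij ~ 1 + roughness·U(−1, 1); the exchange
    kernel p(y|x) ∝ S_xy · π_y is row-normalized and then mixed with the
    identity, P = self_weight·I + (1−self_weight)·M.  The unnormalized
    exchange kernel π_x S_xy π_y is symmetric, so the chain satisfies
    detailed balance with respect to a distribution recoverable from the
    construction (proportional to π_x Z_x with Z_x the row normalizer);
    mixing in the identity preserves reversibility.

    The default ``self_weight`` of 0.85 mimics the strong diagonal
    dominance of empirical codon substitution matrices, where most codons
    are conserved over the estimation period.  Higher *roughness* gives
    more irregular (but still strictly positive) off-diagonal structure;
    roughness 0 with a uniform stationary yields a doubly stochastic
    matrix for any self-weight.
    """
    pi = stationary.probs
    if np.any(pi <= 0):
        raise MatrixValidationError("stationary distribution must be strictly positive")
    if not 0.0 <= roughness < 1.0:
        raise ValueError(f"roughness must lie in [0, 1), got {roughness}")
    if not 0.0 <= self_weight < 1.0:
        raise ValueError(f"self_weight must lie in [0, 1), got {self_weight}")
    n = len(stationary)
    rng = np.random.default_rng(seed)
    A = 1.0 + roughness * rng.uniform(-1.0, 1.0, size=(n, n))
    S = 0.5 * (A + A.T)
    kernel = S * pi[None, :]
    M = kernel / kernel.sum(axis=1)[:, None]
    P = self_weight * np.eye(n) + (1.0 - self_weight) * M
    return ChannelMatrix(stationary.labels, P)


def sample_count_matrix(
    p_x: Distribution, P: ChannelMatrix, n: int, seed: int
) -> CountMatrix:
    """Multinomial sample of *n* (input, output) substitution events.

    Cell (i, j) counts draws from the joint p_x(i)·p(y_j|x_i); this is the
    ground-truth sampling model for estimating the input distribution from
    a substitution count matrix.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if p_x.labels != P.labels:
        p_x = p_x.reorder(P.labels)
    joint = p_x.probs[:, None] * P.probs
    rng = np.random.default_rng(seed)
    flat = rng.multinomial(n, joint.ravel() / joint.sum())
    return CountMatrix(P.labels, flat.reshape(joint.shape))


def load_biological_codon_frequencies(renormalize: bool = True) -> Distribution:
    """Packaged 64-codon relative frequencies observed in five vertebrates.

    Verbatim 4-decimal values; renormalized to an exact simplex by default.
    """
    ref = resources.files("codonchannel.data") / "biological_codon_frequency.tsv"
    with resources.as_file(ref) as path:
        return read_distribution(path, renormalize=renormalize)


def load_capacity_achieving_codon_frequencies(renormalize: bool = True) -> Distribution:
    """Packaged 61-sense-codon capacity-achieving relative frequencies."""
    ref = resources.files("codonchannel.data") / "capacity_achieving_codon_frequency.tsv"
    with resources.as_file(ref) as path:
        return read_distribution(path, renormalize=renormalize)


def fixtures(renormalize: bool = True) -> Tuple[Distribution, Distribution]:
    """(biological 64-codon, capacity-achieving 61-codon) fixture pair."""
    return (
        load_biological_codon_frequencies(renormalize),
        load_capacity_achieving_codon_frequencies(renormalize),
    )
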