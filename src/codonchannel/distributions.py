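"""Codon and amino-acid distributions, entropies, and the required rate.

The biological codon distribution is the row-marginal of a substitution
count matrix: p_x(i) = sum_j C_ij / sum_ij C_ij.  Aggregating synonymous
codons gives the 20-amino-acid distribution whose Shannon entropy, R20, is
the information rate (bits per codon) that a mutation channel must support
for the encoded protein sequence to be transmissible without error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .genetic_code import GeneticCode, standard_code
from .matrix_io import CountMatrix, Distribution

LN2 = np.log(2.0)


def entropy(dist: Distribution) -> float:
    """Shannon entropy in bits, with the 0*log(0) = 0 convention."""
    p = dist.probs
    return float(-xlogy(p, p).sum() / LN2)


def distribution_from_counts(counts: CountMatrix) -> Distribution:
    """Input-codon distribution from substitution counts (row sums / total)."""
    row_sums = counts.counts.sum(axis=1).astype(float)
    return Distribution.from_values(counts.labels, row_sums)


def aggregate_to_amino_acids(
    codon_dist: Distribution, code: GeneticCode | None = None
) -> Distribution:
    """Sum synonymous-codon masses into a 20-amino-acid distribution.

    Stop-codon entries, if present, are dropped and the vector is
    renormalized before aggregation; the amino-acid labels come out in
    alphabetical order.
    """
    code = code or standard_code()
    sense = [l for l in codon_dist.labels if l not in code.stop_set]
    if len(sense) < len(codon_dist.labels):
        codon_dist = codon_dist.restrict(sense)
    groups = code.synonymous_groups()
    series = codon_dist.to_series()
    labels = sorted(groups)
    masses = [sum(series.get(c, 0.0) for c in groups[aa]) for aa in labels]
    return Distribution.from_values(labels, masses)


@dataclass(frozen=True)
class RequiredRate:
    """The rate requirement R20 and the amino-acid distribution behind it."""

    R20: float
    amino_acid_distribution: Distribution


def required_rate(
    codon_dist: Distribution, code: GeneticCode | None = None
) -> RequiredRate:
    """Entropy (bits) of the amino-acid distribution implied by *codon_dist*.

    This is the information content per codon position that must survive
    the mutation channel; it is bounded above by log2(20) ~= 4.3219 bits.
    """
    aa = aggregate_to_amino_acids(codon_dist, code)
    return RequiredRate(R20=entropy(aa), amino_acid_distribution=aa)
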