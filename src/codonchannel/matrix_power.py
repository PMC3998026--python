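"""Fractional powers of a channel matrix via its singular value decomposition.

A mutation matrix estimated over a long divergence time can be "shortened"
by writing P = U Σ V* and forming P^(F) := U Σ^F V* for an exponent
0 ≤ F ≤ 1.  Unlike an eigendecomposition power, this SVD construction is
defined for every real matrix; for symmetric positive-definite stochastic
matrices the two coincide.

The SVD power of a stochastic matrix is generally *not* stochastic: small
negative entries appear and row sums drift from 1.  Since capacity
computation needs a valid conditional-probability matrix, the raw result is
repaired — negatives clipped to zero, rows renormalized — and the size of
the repair is recorded per row so callers can judge how much the exponent
distorted stochasticity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix_io import ChannelMatrix

#: Negative entries smaller than this magnitude are clipped silently;
#: anything more negative is still clipped but counted as genuine repair.
CLIP_TOL = 1e-12

#: Singular-value gap below which paired sign choices in U/V become
#: basis-dependent across linear-algebra backends.
DEGENERACY_GAP = 1e-12


@dataclass(frozen=True)
class SVDFactors:
    """The factors of P = U diag(S) V* together with the exponent applied."""

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray  # right factor, columns are right-singular vectors
    F: float

    def reconstruct(self, exponent: float | None = None) -> np.ndarray:
        f = self.F if exponent is None else exponent
        return (self.U * self.S**f) @ self.V.T

    @property
    def degenerate(self) -> bool:
        """True when some singular values are closer than ``DEGENERACY_GAP``."""
        return bool(np.any(np.diff(self.S) > -DEGENERACY_GAP))


@dataclass(frozen=True)
class RepairReport:
    """Per-row account of how far the raw SVD power was from stochastic."""

    clipped_mass: np.ndarray  # total negative mass removed per row
    renorm_factors: np.ndarray  # factor each row was multiplied by
    degenerate_singular_values: bool = False

    @property
    def max_clipped(self) -> float:
        return float(self.clipped_mass.max(initial=0.0))

    @property
    def max_renorm_deviation(self) -> float:
        return float(np.abs(self.renorm_factors - 1.0).max(initial=0.0))


@dataclass(frozen=True)
class PoweredChannel:
    matrix: ChannelMatrix
    F: float
    repair_report: RepairReport
    factors: SVDFactors = field(repr=False, default=None)


def svd_factors(P: ChannelMatrix, F: float = 1.0) -> SVDFactors:
    """Singular value decomposition of the channel matrix."""
    if not np.all(np.isfinite(P.probs)):
        raise np.linalg.LinAlgError("channel matrix has non-finite entries")
    U, S, Vt = np.linalg.svd(P.probs)
    return SVDFactors(U=U, S=S, V=Vt.T, F=float(F))


def fractional_power(P: ChannelMatrix, F: float) -> PoweredChannel:
    """Form U Σ^F V* and repair it to a row-stochastic matrix.

    Parameters
    ----------
    P:
        A validated channel matrix.
    F:
        Exponent in [0, 1].  F = 1 reproduces P to numerical precision.
        F = 0 is permitted but gives the orthogonal polar factor U V*,
        which is not a meaningful channel; exponent scans should start
        strictly above 0.

    Returns
    -------
    PoweredChannel
        The repaired matrix, the exponent, and a :class:`RepairReport`
        quantifying the clipped negative mass and row renormalization.
    """
    if not 0.0 <= F <= 1.0:
        raise ValueError(f"exponent must lie in [0, 1], got {F}")
    factors = svd_factors(P, F)
    raw = factors.reconstruct()
    negative = np.where(raw < 0.0, raw, 0.0)
    clipped_mass = -negative.sum(axis=1)
    clipped = np.clip(raw, 0.0, None)
    sums = clipped.sum(axis=1)
    if np.any(sums <= 0):
        raise np.linalg.LinAlgError(
            f"row collapsed to zero after clipping at exponent {F}"
        )
    repaired = clipped / sums[:, None]
    report = RepairReport(
        clipped_mass=clipped_mass,
        renorm_factors=1.0 / sums,
        degenerate_singular_values=factors.degenerate,
    )
    return PoweredChannel(
        matrix=ChannelMatrix(P.labels, repaired),
        F=float(F),
        repair_report=report,
        factors=factors,
    )
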