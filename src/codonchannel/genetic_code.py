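"""The standard genetic code: codon ordering, translation, synonymous groups.

Everything downstream (matrix I/O, channel restriction, amino-acid
aggregation) refers to the single :class:`GeneticCode` instance returned by
:func:`standard_code`.  Two canonical codon orderings are provided:

* ``table`` order — first base T,C,A,G outermost, then second, then third
  base, i.e. TTT, TTC, TTA, TTG, TCT, ...  This is the layout used by
  printed codon-usage tables and is the default matrix ordering.
* ``alphabetical`` order — strict A<C<G<T string order, selectable at I/O
  time for files written that way.

The mapping itself is taken from Biopython's standard DNA codon table; this
module owns the ordering, the sense/stop partition and the synonymous-group
structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Mapping, Tuple

from Bio.Data.CodonTable import standard_dna_table

#: Marker returned by :meth:`GeneticCode.translate` for a stop codon.
STOP = "*"

#: Codon order of printed codon tables: bases cycle T, C, A, G.
TABLE_ORDER: Tuple[str, ...] = tuple(
    "".join(b) for b in itertools.product("TCAG", repeat=3)
)

#: Strict alphabetical codon order (A < C < G < T).
ALPHABETICAL_ORDER: Tuple[str, ...] = tuple(sorted(TABLE_ORDER))


class CodonError(ValueError):
    """Raised for a malformed or unknown codon token."""


def normalize_codon(codon: str) -> str:
    """Uppercase a codon and map RNA (U) onto the DNA alphabet (T).

    Raises
    ------
    CodonError
        If *codon* is not three characters over {T, C, A, G, U}.
    """
    if not isinstance(codon, str):
        raise CodonError(f"codon must be a string, got {type(codon).__name__}")
    token = codon.strip().upper().replace("U", "T")
    if len(token) != 3 or any(b not in "TCAG" for b in token):
        raise CodonError(f"malformed codon {codon!r}: expected 3 bases over T/C/A/G (or U)")
    return token


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino-acid mapping with a fixed sense-codon ordering.

    Attributes
    ----------
    codon_to_aa:
        Maps each of the 64 codons to a one-letter amino-acid symbol, or to
        ``"*"`` for the three stop codons.
    sense_order:
        The 61 sense codons in canonical (table) order; defines default
        row/column order of 61x61 matrices.
    stop_set:
        The stop codons TAA, TAG, TGA.
    """

    codon_to_aa: Mapping[str, str]
    sense_order: Tuple[str, ...]
    stop_set: frozenset = field(default_factory=frozenset)

    def translate(self, codon: str) -> str:
        """Return the amino-acid symbol for *codon*, or ``"*"`` for a stop.

        Accepts lowercase and RNA spellings (``"aug"`` -> ``"M"``).
        """
        return self.codon_to_aa[normalize_codon(codon)]

    def is_stop(self, codon: str) -> bool:
        return normalize_codon(codon) in self.stop_set

    def synonymous_groups(self) -> Dict[str, List[str]]:
        """Map each amino-acid symbol to its codons in alphabetical order.

        The 20 groups partition the 61 sense codons.
        """
        groups: Dict[str, List[str]] = {}
        for codon in sorted(self.sense_order):
            groups.setdefault(self.codon_to_aa[codon], []).append(codon)
        return groups

    @property
    def amino_acids(self) -> Tuple[str, ...]:
        """The 20 amino-acid symbols, alphabetical."""
        return tuple(sorted({self.codon_to_aa[c] for c in self.sense_order}))


@lru_cache(maxsize=1)
def standard_code() -> GeneticCode:
    """The standard nuclear genetic code (61 sense codons, 3 stops)."""
    stops = frozenset(standard_dna_table.stop_codons)
    mapping = dict(standard_dna_table.forward_table)
    mapping.update({c: STOP for c in stops})
    sense = tuple(c for c in TABLE_ORDER if c not in stops)
    return GeneticCode(codon_to_aa=mapping, sense_order=sense, stop_set=stops)
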