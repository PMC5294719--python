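"""Genetic-code tables and codon-pair classification.

The codon state space of every model in this package is the set of *sense*
codons of a genetic code (61 for the universal nuclear code): stop codons are
trimmed from coding sequences before analysis and are not part of the state
space.  Codons are ordered lexicographically over the nucleotide order
``T < C < A < G`` (the convention of most codon-model software), and that
ordering is frozen: row/column ``i`` of every rate or probability matrix
refers to ``code.sense_codons[i]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Mapping

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
#: index into NUCLEOTIDES for each of T, C, A, G
NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

#: purine/purine and pyrimidine/pyrimidine exchanges
_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}

STOP = "*"


def is_transition(n1: str, n2: str) -> bool:
    """True if ``n1 -> n2`` is a transition (A<->G or C<->T)."""
    return frozenset((n1, n2)) in _TRANSITION_PAIRS


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code restricted to its sense codons.

    Parameters
    ----------
    name : str
        Human-readable table name.
    codon_to_aa : Mapping[str, str]
        All 64 triplets mapped to one-letter amino acids, stops to ``"*"``.
    """

    name: str
    codon_to_aa: Mapping[str, str]

    def __post_init__(self):
        if len(self.codon_to_aa) != 64:
            raise ValueError(
                f"genetic code must map all 64 triplets, got {len(self.codon_to_aa)}"
            )

    @cached_property
    def sense_codons(self) -> tuple[str, ...]:
        """Sense codons in fixed T<C<A<G lexicographic order."""
        return tuple(
            a + b + c
            for a in NUCLEOTIDES
            for b in NUCLEOTIDES
            for c in NUCLEOTIDES
            if self.codon_to_aa[a + b + c] != STOP
        )

    @cached_property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == STOP)

    @cached_property
    def n_states(self) -> int:
        return len(self.sense_codons)

    @cached_property
    def codon_index(self) -> dict[str, int]:
        """Sense codon -> state index; stop codons are absent."""
        return {c: i for i, c in enumerate(self.sense_codons)}

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon.upper().replace("U", "T")]

    # ---- pairwise classification arrays (cached, n x n) -------------------

    @cached_property
    def _pair_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = self.n_states
        single = np.zeros((n, n), dtype=bool)
        transition = np.zeros((n, n), dtype=bool)
        synonymous = np.zeros((n, n), dtype=bool)
        codons = self.sense_codons
        for i in range(n):
            ci = codons[i]
            for j in range(i + 1, n):
                cj = codons[j]
                diffs = [k for k in range(3) if ci[k] != cj[k]]
                if len(diffs) != 1:
                    continue
                k = diffs[0]
                single[i, j] = single[j, i] = True
                ts = is_transition(ci[k], cj[k])
                transition[i, j] = transition[j, i] = ts
                syn = self.codon_to_aa[ci] == self.codon_to_aa[cj]
                synonymous[i, j] = synonymous[j, i] = syn
        return single, transition, synonymous

    @property
    def single_step(self) -> np.ndarray:
        """Boolean (n, n): codon pairs differing at exactly one position."""
        return self._pair_arrays[0]

    @property
    def transition_step(self) -> np.ndarray:
        """Boolean (n, n): single-step pairs whose change is a transition."""
        return self._pair_arrays[1]

    @property
    def synonymous_step(self) -> np.ndarray:
        """Boolean (n, n): single-step pairs coding the same amino acid."""
        return self._pair_arrays[2]

    @cached_property
    def codon_position_nucleotides(self) -> np.ndarray:
        """Integer (n, 3): NUC_INDEX of each codon position per sense codon."""
        return np.array(
            [[NUC_INDEX[c[k]] for k in range(3)] for c in self.sense_codons],
            dtype=np.int64,
        )


def _from_biopython(table_id: int, name: str) -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = STOP
    return GeneticCode(name=name, codon_to_aa=mapping)


#: The universal nuclear genetic code (61 sense codons), the default everywhere.
UNIVERSAL: GeneticCode = _from_biopython(1, "universal")
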