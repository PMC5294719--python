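"""Codon alignments and equilibrium codon-frequency estimation.

A :class:`CodonAlignment` stores one integer state per taxon per codon column:
the index of a sense codon in the fixed ordering of a :class:`~wgdomega.genetics.GeneticCode`,
or ``MISSING`` (-1) for gaps, ambiguous nucleotides, and untranslatable
triplets, which all enter the likelihood as missing data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .genetics import UNIVERSAL, GeneticCode

MISSING = -1

FREQUENCY_MODES = ("equal", "F1x4", "F3x4")

#: floor applied to a per-position nucleotide frequency before renormalisation,
#: so that no sense codon gets probability exactly zero under F1x4/F3x4
NUCLEOTIDE_FREQ_FLOOR = 1e-6


@dataclass(frozen=True)
class CodonFrequencies:
    """Equilibrium frequencies over sense codons.

    ``pi`` sums to one over ``code.sense_codons``; ``mode`` records how it was
    obtained (``equal``, ``F1x4`` pooled nucleotide frequencies, or ``F3x4``
    position-specific nucleotide frequencies).
    """

    pi: np.ndarray
    mode: str
    code: GeneticCode = UNIVERSAL

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if pi.shape != (self.code.n_states,):
            raise ValueError(f"pi must have length {self.code.n_states}")
        if np.any(pi < 0):
            raise ValueError("codon frequencies must be non-negative")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("codon frequencies must sum to 1")

    @classmethod
    def equal(cls, code: GeneticCode = UNIVERSAL) -> "CodonFrequencies":
        n = code.n_states
        return cls(pi=np.full(n, 1.0 / n), mode="equal", code=code)


class CodonAlignment:
    """A taxa x codon-column matrix of sense-codon states.

    Parameters
    ----------
    taxa : sequence of str
        Ordered sequence names.
    codons : array-like of int, shape (n_taxa, n_codons)
        Sense-codon indices, ``MISSING`` (-1) for gap/ambiguous states.
    """

    def __init__(self, taxa: Sequence[str], codons, code: GeneticCode = UNIVERSAL):
        self.taxa = list(taxa)
        self.codons = np.asarray(codons, dtype=np.int64)
        self.code = code
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise ValueError("codons must be (n_taxa, n_codons)")
        if self.codons.shape[1] < 1:
            raise ValueError("alignment must have at least one codon column")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        if self.codons.size and (
            self.codons.max() >= code.n_states or self.codons.min() < MISSING
        ):
            raise ValueError("codon states out of range")

    # ---- construction -----------------------------------------------------

    @classmethod
    def from_strings(
        cls, sequences: Mapping[str, str], code: GeneticCode = UNIVERSAL
    ) -> "CodonAlignment":
        """Build from aligned nucleotide strings (equal lengths, length % 3 == 0).

        Gaps (``-``), ambiguity codes, and any triplet that is not a sense
        codon of ``code`` become missing states.
        """
        if not sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal lengths")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError("aligned length must be a multiple of 3")
        taxa = list(sequences)
        n_codons = length // 3
        mat = np.full((len(taxa), n_codons), MISSING, dtype=np.int64)
        index = code.codon_index
        for i, name in enumerate(taxa):
            seq = sequences[name].upper().replace("U", "T")
            for j in range(n_codons):
                mat[i, j] = index.get(seq[3 * j : 3 * j + 3], MISSING)
        return cls(taxa, mat, code)

    # ---- basic properties -------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    def row(self, name: str) -> np.ndarray:
        return self.codons[self.taxa.index(name)]

    def subset(self, names: Iterable[str]) -> "CodonAlignment":
        names = list(names)
        idx = [self.taxa.index(n) for n in names]
        return CodonAlignment(names, self.codons[idx], self.code)

    def to_strings(self, gap: str = "---") -> dict[str, str]:
        codons = self.code.sense_codons
        out = {}
        for i, name in enumerate(self.taxa):
            out[name] = "".join(
                gap if s == MISSING else codons[s] for s in self.codons[i]
            )
        return out

    def __repr__(self) -> str:
        return f"<CodonAlignment {self.n_taxa} taxa x {self.n_codons} codons>"


# ---- frequency estimation --------------------------------------------------


def _nucleotide_counts(aln: CodonAlignment) -> np.ndarray:
    """Counts (3, 4) of nucleotides per codon position over non-missing codons."""
    pos_nucs = aln.code.codon_position_nucleotides  # (n_states, 3)
    states = aln.codons[aln.codons != MISSING]
    counts = np.zeros((3, 4), dtype=float)
    if states.size:
        for k in range(3):
            counts[k] = np.bincount(pos_nucs[states, k], minlength=4)
    return counts


def estimate_codon_frequencies(
    alignment: CodonAlignment, mode: str = "F3x4"
) -> CodonFrequencies:
    """Estimate equilibrium codon frequencies from observed composition.

    ``F3x4`` multiplies position-specific nucleotide frequencies over the
    three codon positions; ``F1x4`` pools positions; both are restricted to
    sense codons and renormalised.  Missing states are ignored in the counts,
    and any unobserved nucleotide receives a small frequency floor so no
    sense codon has probability zero.
    """
    if mode not in FREQUENCY_MODES:
        raise ValueError(f"mode must be one of {FREQUENCY_MODES}")
    code = alignment.code
    if mode == "equal":
        return CodonFrequencies.equal(code)

    counts = _nucleotide_counts(alignment)
    if counts.sum() == 0:
        raise ValueError("alignment has no resolved codons")
    if mode == "F1x4":
        pooled = counts.sum(axis=0)
        freqs = np.tile(pooled / pooled.sum(), (3, 1))
    else:  # F3x4
        freqs = counts / counts.sum(axis=1, keepdims=True)
    freqs = np.maximum(freqs, NUCLEOTIDE_FREQ_FLOOR)
    freqs /= freqs.sum(axis=1, keepdims=True)

    pos_nucs = code.codon_position_nucleotides
    pi = freqs[0, pos_nucs[:, 0]] * freqs[1, pos_nucs[:, 1]] * freqs[2, pos_nucs[:, 2]]
    pi /= pi.sum()
    return CodonFrequencies(pi=pi, mode=mode, code=code)


# ---- flat-file output -------------------------------------------------------


def write_phylip(alignment: CodonAlignment, handle) -> None:
    """Write a sequential PHYLIP nucleotide alignment (the PAML layout)."""
    close = False
    if isinstance(handle, (str,)):
        handle = open(handle, "w")
        close = True
    try:
        strings = alignment.to_strings()
        handle.write(f" {alignment.n_taxa}  {alignment.n_codons * 3}\n")
        for name in alignment.taxa:
            handle.write(f"{name}  {strings[name]}\n")
    finally:
        if close:
            handle.close()


def write_fasta(sequences: Mapping[str, str], handle) -> None:
    close = False
    if isinstance(handle, str):
        handle = open(handle, "w")
        close = True
    try:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                handle.write(seq[i : i + 60] + "\n")
    finally:
        if close:
            handle.close()


def read_fasta(handle) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence mapping."""
    if isinstance(handle, str):
        records = SeqIO.parse(handle, "fasta")
        return {r.id: str(r.seq) for r in records}
    return {r.id: str(r.seq) for r in SeqIO.parse(handle, "fasta")}
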