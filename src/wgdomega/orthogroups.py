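"""Orthogroup ingestion: filtering, stop trimming, back-translation, batch prep.

An :class:`Orthogroup` bundles the per-gene coding sequences, the aligned
proteins used as a back-translation template, and the assignment of each
sequence to a species and a paralog copy (A/B for post-WGD species, ``none``
for outgroups).  Sequence names follow ``species|copyTag|geneID`` unless an
explicit assignment table is supplied.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .alignment import CodonAlignment, read_fasta, write_fasta, write_phylip
from .genetics import UNIVERSAL, GeneticCode

#: default filter thresholds: orthogroups need at least this many sequences,
#: and at least this many from non-WGD species
MIN_TOTAL_SEQUENCES = 13
MIN_NONWGD_SEQUENCES = 3

#: alternative-dataset rules: minimum sequences and the per-sequence cap on
#: the fraction of undetermined (non-ACGT) nucleotides
MIN_SEQUENCES_ALT = 6
MAX_UNDETERMINED_FRAC = 0.05


class OrthogroupError(ValueError):
    pass


@dataclass
class Orthogroup:
    """One group of orthologous genes spanning the WGD."""

    id: str
    cds: dict[str, str]
    protein_alignment: dict[str, str]
    assignment: dict[str, tuple[str, str]]
    provenance: str = ""
    #: species whose both copies must be present to keep the group
    focal_species: str | None = None

    @property
    def n_sequences(self) -> int:
        return len(self.assignment)

    def n_nonwgd(self) -> int:
        return sum(1 for _sp, tag in self.assignment.values() if tag in (None, "none"))

    def copies_of(self, species: str) -> set[str]:
        return {
            tag
            for _seq, (sp, tag) in self.assignment.items()
            if sp == species and tag in ("A", "B")
        }


def parse_sequence_name(name: str) -> tuple[str, str]:
    """``species|copyTag|geneID`` -> (species, copy tag)."""
    parts = name.split("|")
    if len(parts) != 3:
        raise OrthogroupError(
            f"sequence name {name!r} does not follow species|copyTag|geneID"
        )
    species, tag, _gene = parts
    if tag not in ("A", "B", "none"):
        raise OrthogroupError(f"copy tag in {name!r} must be A, B or none")
    return species, tag


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_orthogroups(
    groups: Sequence[Orthogroup],
    min_total: int = MIN_TOTAL_SEQUENCES,
    min_nonwgd: int = MIN_NONWGD_SEQUENCES,
    require_both_copies: bool = True,
) -> tuple[list[Orthogroup], list[tuple[Orthogroup, str]]]:
    """Primary-dataset filter: size, outgroup representation, focal copies.

    Keeps groups with at least ``min_total`` sequences, at least
    ``min_nonwgd`` non-WGD sequences, and — when a focal species is set —
    both A and B copies present in it.  Returns (kept, discarded with
    reasons); filtering is total, order-independent, and idempotent.
    """
    kept, discarded = [], []
    for g in groups:
        if g.n_sequences < min_total:
            discarded.append((g, f"too few sequences ({g.n_sequences} < {min_total})"))
        elif g.n_nonwgd() < min_nonwgd:
            discarded.append(
                (g, f"too few non-WGD sequences ({g.n_nonwgd()} < {min_nonwgd})")
            )
        elif (
            require_both_copies
            and g.focal_species is not None
            and g.copies_of(g.focal_species) != {"A", "B"}
        ):
            discarded.append(
                (g, f"missing ohnolog copy in focal species {g.focal_species!r}")
            )
        else:
            kept.append(g)
    return kept, discarded


def undetermined_fraction(seq: str) -> float:
    """Fraction of characters that are not A, C, G or T (gaps excluded)."""
    bases = [c for c in seq.upper() if c != "-"]
    if not bases:
        return 1.0
    return sum(1 for c in bases if c not in "ACGT") / len(bases)


def filter_orthogroups_alt(
    groups: Sequence[Orthogroup],
    min_seqs: int = MIN_SEQUENCES_ALT,
    max_undetermined_frac: float = MAX_UNDETERMINED_FRAC,
) -> tuple[list[Orthogroup], list[tuple[Orthogroup, str]]]:
    """Alternative-dataset filter: sequence quantity and quality.

    Discards groups with fewer than ``min_seqs`` sequences or any sequence
    whose undetermined-nucleotide fraction exceeds the threshold.
    """
    kept, discarded = [], []
    for g in groups:
        if g.n_sequences < min_seqs:
            discarded.append((g, f"too few sequences ({g.n_sequences} < {min_seqs})"))
            continue
        bad = [
            name
            for name, seq in g.cds.items()
            if undetermined_fraction(seq) > max_undetermined_frac
        ]
        if bad:
            discarded.append(
                (g, f"undetermined-nucleotide fraction above {max_undetermined_frac} "
                    f"in {sorted(bad)}")
            )
        else:
            kept.append(g)
    return kept, discarded


# ---------------------------------------------------------------------------
# Stop trimming and back-translation
# ---------------------------------------------------------------------------


def trim_stop_codons(cds: str, code: GeneticCode = UNIVERSAL) -> str:
    """Remove one terminal stop codon if present; reject internal stops."""
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise OrthogroupError(f"CDS length {len(cds)} is not divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in code.stop_codons:
        codons = codons[:-1]
    for pos, codon in enumerate(codons):
        if codon in code.stop_codons:
            raise OrthogroupError(f"premature stop codon {codon} at codon {pos + 1}")
    return "".join(codons)


def back_translate_alignment(
    protein_alignment: Mapping[str, str],
    cds_map: Mapping[str, str],
    code: GeneticCode = UNIVERSAL,
) -> CodonAlignment:
    """Expand an aligned protein template to a codon alignment.

    Each amino-acid column becomes the source codon of that residue; protein
    gaps become codon gaps (missing states).  Every CDS must translate,
    after stop trimming, residue-for-residue to its ungapped protein row.
    """
    if not protein_alignment:
        raise OrthogroupError("empty protein alignment")
    lengths = {len(s) for s in protein_alignment.values()}
    if len(lengths) != 1:
        raise OrthogroupError("protein rows must have equal aligned lengths")
    rows = {}
    for name, prot in protein_alignment.items():
        if name not in cds_map:
            raise OrthogroupError(f"no CDS for aligned protein {name!r}")
        cds = trim_stop_codons(cds_map[name], code)
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        residues = [r for r in prot if r != "-"]
        if len(codons) != len(residues):
            raise OrthogroupError(
                f"{name}: CDS has {len(codons)} codons but protein row has "
                f"{len(residues)} residues"
            )
        k = 0
        out = []
        for col, r in enumerate(prot):
            if r == "-":
                out.append("---")
                continue
            codon = codons[k]
            aa = code.translate(codon) if codon in code.codon_to_aa else "X"
            if r.upper() != aa:
                raise OrthogroupError(
                    f"{name}: codon {codon} translates to {aa!r}, protein has "
                    f"{r.upper()!r} at position {col + 1}"
                )
            out.append(codon)
            k += 1
        rows[name] = "".join(out)
    return CodonAlignment.from_strings(rows, code)


# ---------------------------------------------------------------------------
# Directory-based readers/writers
# ---------------------------------------------------------------------------


def read_orthogroup_dir(
    path: str,
    og_id: str | None = None,
    code: GeneticCode = UNIVERSAL,
    focal_species: str | None = None,
) -> Orthogroup:
    """Read one orthogroup bundle: ``cds.fasta``, ``proteins.fasta``, and an
    optional ``assignment.tsv`` (columns: sequence, species, copy)."""
    cds = read_fasta(os.path.join(path, "cds.fasta"))
    prot = read_fasta(os.path.join(path, "proteins.fasta"))
    table = os.path.join(path, "assignment.tsv")
    if os.path.exists(table):
        df = pd.read_csv(table, sep="\t")
        assignment = {
            str(r.sequence): (str(r.species), str(r.copy)) for r in df.itertuples()
        }
    else:
        assignment = {name: parse_sequence_name(name) for name in cds}
    return Orthogroup(
        id=og_id or os.path.basename(os.path.normpath(path)),
        cds=cds,
        protein_alignment=prot,
        assignment=assignment,
        provenance=path,
        focal_species=focal_species,
    )


def write_orthogroup_dir(og: Orthogroup, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    write_fasta(og.cds, os.path.join(path, "cds.fasta"))
    write_fasta(og.protein_alignment, os.path.join(path, "proteins.fasta"))
    rows = [
        {"sequence": seq, "species": sp, "copy": tag}
        for seq, (sp, tag) in og.assignment.items()
    ]
    pd.DataFrame(rows).to_csv(os.path.join(path, "assignment.tsv"), sep="\t", index=False)


def prepare_orthogroup(og: Orthogroup, topology) -> tuple[CodonAlignment, object]:
    """Trim, back-translate, and build the labeled gene tree for one group."""
    from .trees import build_orthogroup_tree

    aln = back_translate_alignment(og.protein_alignment, og.cds)
    tree = build_orthogroup_tree(topology, og.assignment)
    return aln, tree


def write_prepared_bundle(og_id, alignment, tree, out_dir: str) -> None:
    from .trees import write_newick

    os.makedirs(out_dir, exist_ok=True)
    write_phylip(alignment, os.path.join(out_dir, f"{og_id}.phy"))
    with open(os.path.join(out_dir, f"{og_id}.nwk"), "w") as fh:
        fh.write(write_newick(tree) + "\n")
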