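"""FASTA handling and in-silico trypsin + Lys-C digestion.

The combined-protease rule models a joint trypsin/Lys-C digest: cleave
after every K (Lys-C is proline-insensitive, so K-P bonds are cut) and
after R unless the next residue is P (the trypsin rule). Peptides with up
to ``max_missed`` missed cleavages are enumerated with their 1-based
protein coordinates and flanking residues, so a digest peptide can be
rendered in the usual [K].PEPTIDEK.[V] notation.

Initiator methionine is not removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO

from .chem import STANDARD_RESIDUES

__all__ = [
    "ProteinRecord",
    "DigestPeptide",
    "PeptideMapping",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "cleavage_sites",
    "digest",
    "write_digest_tsv",
    "map_peptides_to_proteins",
]

TERMINUS = "-"


class FastaFormatError(ValueError):
    """Raised for empty or malformed FASTA input."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its accession and description."""

    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.accession!r}: empty sequence")
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.accession!r}: non-standard residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class DigestPeptide:
    """One digest peptide with protein context.

    ``start``/``end`` are 1-based inclusive protein coordinates;
    ``preceding_residue``/``following_residue`` are the flanking residues
    or ``"-"`` at a protein terminus.
    """

    sequence: str
    protein_accession: str
    start: int
    end: int
    preceding_residue: str
    following_residue: str
    missed_cleavages: int

    def notation(self) -> str:
        """Render as e.g. ``[K].YAGQDIVSNASCTTNCLAPLAK.[V]``."""
        return f"[{self.preceding_residue}].{self.sequence}.[{self.following_residue}]"


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Order-preserving; accession is the first whitespace-delimited header
    token; sequences are uppercased. Records containing non-standard
    residues (U, X, ...) are skipped with a warning. Empty files or files
    whose first non-blank line is not a header raise
    :class:`FastaFormatError` with the offending line number.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{path}: line {lineno}: expected FASTA header, got {line.strip()[:30]!r}"
                    )
                break
        else:
            raise FastaFormatError(f"{path}: empty FASTA file")

    records = []
    for seq_record in SeqIO.parse(str(path), "fasta"):
        sequence = str(seq_record.seq).upper()
        bad = set(sequence) - STANDARD_RESIDUES
        if bad:
            warnings.warn(
                f"skipping {seq_record.id}: non-standard residues {sorted(bad)}",
                stacklevel=2,
            )
            continue
        records.append(
            ProteinRecord(
                accession=seq_record.id,
                description=seq_record.description,
                sequence=sequence,
            )
        )
    if not records:
        raise FastaFormatError(f"{path}: no usable FASTA records")
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.accession
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that the bond after ``sequence[i]`` is cut.

    Cut after K always (Lys-C cleaves K-P); after R unless followed by P.
    The C-terminal residue is never a cleavage site.
    """
    sites = []
    for i in range(len(sequence) - 1):
        aa = sequence[i]
        if aa == "K" or (aa == "R" and sequence[i + 1] != "P"):
            sites.append(i)
    return sites


def digest(
    protein: ProteinRecord,
    max_missed: int = 2,
    min_length: int = 1,
    max_length: int | None = None,
) -> list[DigestPeptide]:
    """Enumerate digest peptides with 0..``max_missed`` missed cleavages.

    Fully cleaved (0-missed) peptides concatenate, in order, to the
    protein sequence. ``min_length``/``max_length`` filter the reported
    peptides only (coordinates are unaffected).
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.sequence
    bounds = [0] + [i + 1 for i in cleavage_sites(seq)] + [len(seq)]
    peptides = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for m in range(max_missed + 1):
            j = i + m + 1
            if j > n_frag:
                break
            start, end = bounds[i], bounds[j]  # 0-based half-open
            pep = seq[start:end]
            if len(pep) < min_length or (max_length is not None and len(pep) > max_length):
                continue
            peptides.append(
                DigestPeptide(
                    sequence=pep,
                    protein_accession=protein.accession,
                    start=start + 1,
                    end=end,
                    preceding_residue=seq[start - 1] if start > 0 else TERMINUS,
                    following_residue=seq[end] if end < len(seq) else TERMINUS,
                    missed_cleavages=m,
                )
            )
    return peptides


def write_digest_tsv(peptides: Iterable[DigestPeptide], path) -> None:
    """Write digest peptides as TSV (accession, coordinates, flanks)."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "accession": d.protein_accession,
                "start": d.start,
                "end": d.end,
                "preceding": d.preceding_residue,
                "sequence": d.sequence,
                "following": d.following_residue,
                "missed_cleavages": d.missed_cleavages,
            }
            for d in peptides
        ]
    ).to_csv(path, sep="\t", index=False)


@dataclass
class PeptideMapping:
    """Result of mapping peptide sequences onto a digested proteome."""

    mapping: dict[str, set[str]]
    unmapped: list[str]
    n_unique_proteins: int


def map_peptides_to_proteins(
    peptides: Sequence[str],
    proteome: Sequence[ProteinRecord],
    max_missed: int = 2,
) -> PeptideMapping:
    """Map peptides to proteins by exact digest-peptide matching.

    A peptide maps to a protein iff it equals one of the protein's digest
    peptides (up to ``max_missed`` missed cleavages). The unique-protein
    count is the size of the union of all matched accession sets.
    """
    if not proteome:
        raise ValueError("proteome must be non-empty")
    index: dict[str, set[str]] = {}
    for protein in proteome:
        for dp in digest(protein, max_missed=max_missed):
            index.setdefault(dp.sequence, set()).add(protein.accession)
    mapping: dict[str, set[str]] = {}
    unmapped: list[str] = []
    for pep in peptides:
        hits = index.get(pep)
        if hits:
            mapping[pep] = set(hits)
        else:
            unmapped.append(pep)
    covered: set[str] = set()
    for hits in mapping.values():
        covered |= hits
    return PeptideMapping(mapping=mapping, unmapped=unmapped, n_unique_proteins=len(covered))
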