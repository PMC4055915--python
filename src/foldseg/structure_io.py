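"""Readers/writers for the formats the pipeline touches (PDB, FASTA, aligned FASTA).

Coordinate parsing is delegated to Bio.PDB; sequence I/O to Bio.SeqIO /
Bio.AlignIO.  The domain types here are deliberately plain containers so the
analysis modules stay independent of Biopython objects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical single-letter amino-acid alphabet (plus 'X' for anything else).
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}


@dataclass
class Atom:
    """One heavy atom: PDB atom name, chemical element, Cartesian position (Å)."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)


@dataclass
class Residue:
    """A residue with its source numbering, 1-letter code and heavy atoms.

    ``number`` is the residue number as printed in the source file; internal
    positions used by the analyses are simply 1-based list indices.
    """

    number: int
    amino_acid: str
    ca_coordinate: np.ndarray
    heavy_atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ca_coordinate = np.asarray(self.ca_coordinate, dtype=float)
        if self.amino_acid not in STANDARD_AA + "X":
            raise ValueError(f"invalid amino acid code {self.amino_acid!r}")


@dataclass
class ProteinStructure:
    """An ordered single chain of residues with Cα (and optional heavy-atom) coordinates."""

    chain_id: str
    residues: list[Residue]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    @property
    def ca_coordinates(self) -> np.ndarray:
        """(N, 3) array of Cα positions in residue order."""
        return np.array([r.ca_coordinate for r in self.residues], dtype=float)

    @property
    def residue_numbers(self) -> list[int]:
        return [r.number for r in self.residues]

    def to_sequence_record(self, identifier: str | None = None) -> "SequenceRecord":
        offset = self.residues[0].number - 1 if self.residues else 0
        return SequenceRecord(identifier or self.chain_id, self.sequence, offset)


@dataclass
class SequenceRecord:
    """A named 1-letter sequence plus the offset into the source numbering.

    ``numbering_offset`` maps internal position ``p`` (1-based) to the
    reported residue number ``p + numbering_offset``; it defaults to 0.
    """

    identifier: str
    sequence: str
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Alignment:
    """A multiple sequence alignment over the 20 letters plus gap ``-``."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("alignment needs at least 2 records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        self.records = [(ident, seq.upper()) for ident, seq in self.records]

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def identifiers(self) -> list[str]:
        return [ident for ident, _ in self.records]

    def sequence_of(self, identifier: str) -> str:
        for ident, seq in self.records:
            if ident == identifier:
                return seq
        raise KeyError(f"record {identifier!r} not in alignment")


def _three_to_one(resname: str) -> str:
    return protein_letters_3to1.get(resname.strip().upper(), "X")


def read_pdb(path: str | Path, chain: str) -> ProteinStructure:
    """Read one chain of a PDB file into a :class:`ProteinStructure`.

    Only ATOM records of the first model are used; alternate locations are
    resolved to the highest-occupancy conformer (Bio.PDB default).  Residues
    lacking a resolved Cα are skipped with a warning.  Nonstandard residues
    map to ``X`` but keep their place in the chain.
    """
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PDBParser(QUIET=True).get_structure(path.stem, str(path))[0]
    chain_ids = [c.id for c in model]
    if chain not in chain_ids:
        raise KeyError(f"chain {chain!r} not found in {path} (have {chain_ids})")
    residues: list[Residue] = []
    for res in model[chain]:
        hetflag, resseq, _icode = res.id
        if hetflag != " ":  # HETATM / water
            continue
        if "CA" not in res:
            logger.warning("%s %s%d: no CA atom, residue skipped", path.name, chain, resseq)
            continue
        heavy = [
            Atom(a.get_name(), (a.element or "C").upper(), np.array(a.get_coord(), float))
            for a in res.get_atoms()
            if (a.element or "").upper() != "H"
        ]
        residues.append(
            Residue(
                number=resseq,
                amino_acid=_three_to_one(res.get_resname()),
                ca_coordinate=np.array(res["CA"].get_coord(), dtype=float),
                heavy_atoms=heavy,
            )
        )
    return ProteinStructure(chain_id=chain, residues=residues)


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write a structure as fixed-column ATOM records (heavy atoms if present, else Cα only)."""
    lines = []
    serial = 1
    for res in structure.residues:
        resname = _ONE_TO_THREE.get(res.amino_acid, "UNK")
        atoms = res.heavy_atoms or [Atom("CA", "C", res.ca_coordinate)]
        for atom in atoms:
            x, y, z = atom.coord
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{resname:>3s} {structure.chain_id:1s}"
                f"{res.number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {atom.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords; sequences are uppercased."""
    records = [
        SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.identifier, description="") for r in records],
        str(path),
        "fasta",
    )


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned-FASTA alignment; raises on ragged or empty input."""
    try:
        msa = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise ValueError(f"cannot read alignment from {path}: {exc}") from exc
    return Alignment([(rec.id, str(rec.seq).upper()) for rec in msa])


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=ident, description="") for ident, seq in alignment.records],
        str(path),
        "fasta",
    )
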