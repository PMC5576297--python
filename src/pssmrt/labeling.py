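"""Binding/non-binding labels from protein-DNA complex structures.

A protein residue counts as DNA-binding when any of its atoms (backbone
or side chain) lies within a distance cutoff — 3.5 Angstrom by default —
of any atom of the DNA in the complex.  All DNA chains of the complex
are pooled; the boundary is inclusive (distance equal to the cutoff is
binding).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1
from scipy.spatial.distance import cdist

DEFAULT_CUTOFF = 3.5

#: Residue names treated as nucleic acid (deoxy- and ribonucleotides).
DNA_RESNAMES = {"DA", "DC", "DG", "DT", "DU", "DI", "A", "C", "G", "U", "I"}

_3TO1 = {k.upper(): v for k, v in protein_letters_3to1.items()}


class StructureError(ValueError):
    """Raised when a complex lacks a protein or DNA component."""


@dataclass(frozen=True)
class ProteinResidue:
    chain_id: str
    position: int  # 1-based index along the chain's standard residues
    residue: str  # one-letter code
    coords: np.ndarray  # (n_atoms, 3), Angstrom


@dataclass(frozen=True)
class ComplexStructure:
    """Atom coordinates of one protein-DNA complex, typed by residue vocabulary."""

    name: str
    protein_residues: tuple[ProteinResidue, ...]
    dna_atoms: np.ndarray  # (n_atoms, 3) pooled over all DNA chains

    def __post_init__(self) -> None:
        if self.dna_atoms.size and not np.all(np.isfinite(self.dna_atoms)):
            raise ValueError("non-finite DNA atom coordinates")


@dataclass(frozen=True)
class ResidueLabel:
    chain_id: str
    position: int
    residue: str
    binding: bool
    min_distance: float


def load_complex(path: str | Path, name: str | None = None) -> ComplexStructure:
    """Parse a PDB file into typed protein residues and pooled DNA atoms.

    Hetero and modified residues are skipped (they have no PSSM row);
    for disordered atoms the highest-occupancy altloc is used; hydrogens
    are kept if present.
    """
    parser = PDBParser(QUIET=True)
    path = Path(path)
    structure = parser.get_structure(name or path.stem, str(path))
    model = next(structure.get_models())

    residues: list[ProteinResidue] = []
    dna: list[np.ndarray] = []
    for chain in model:
        pos = 0
        for res in chain:
            hetflag = res.id[0]
            resname = res.get_resname().strip().upper()
            coords = np.array([atom.get_coord() for atom in res], dtype=float)
            if resname in DNA_RESNAMES and hetflag == " ":
                dna.append(coords)
            elif resname in _3TO1 and hetflag == " ":
                pos += 1
                residues.append(ProteinResidue(chain.id, pos, _3TO1[resname], coords))
            # waters, ions, modified residues: skipped
    dna_atoms = np.vstack(dna) if dna else np.empty((0, 3))
    return ComplexStructure(name or path.stem, tuple(residues), dna_atoms)


def min_distance_to_dna(residue_atoms: np.ndarray, dna_atoms: np.ndarray) -> float:
    """Minimum Euclidean distance (Angstrom) over all atom pairs."""
    residue_atoms = np.atleast_2d(np.asarray(residue_atoms, dtype=float))
    dna_atoms = np.atleast_2d(np.asarray(dna_atoms, dtype=float))
    if residue_atoms.size == 0 or dna_atoms.size == 0:
        raise ValueError("empty atom set")
    return float(cdist(residue_atoms, dna_atoms).min())


def label_residues(cx: ComplexStructure, cutoff: float = DEFAULT_CUTOFF) -> list[ResidueLabel]:
    """Label every protein residue binding iff its minimum distance to any
    DNA atom of the complex is <= cutoff."""
    if not cx.protein_residues:
        raise StructureError(f"{cx.name}: no protein chain detected")
    if cx.dna_atoms.size == 0:
        raise StructureError(f"{cx.name}: no DNA chain detected")
    labels = []
    for res in cx.protein_residues:
        d = min_distance_to_dna(res.coords, cx.dna_atoms)
        labels.append(ResidueLabel(res.chain_id, res.position, res.residue, d <= cutoff, d))
    return labels


def write_labels(labels: list[ResidueLabel], path: str | Path) -> None:
    """Write labels as TSV: chain, position, residue, label, min_distance."""
    with open(path, "w") as fh:
        fh.write("chain\tposition\tresidue\tlabel\tmin_distance\n")
        for lab in labels:
            fh.write(
                f"{lab.chain_id}\t{lab.position}\t{lab.residue}\t"
                f"{'+' if lab.binding else '-'}\t{lab.min_distance:.3f}\n"
            )
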