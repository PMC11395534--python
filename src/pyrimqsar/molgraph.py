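"""Heavy-atom molecular graphs parsed from SMILES.

The QSAR pipeline works on 2D topology only: molecules are heavy-atom
graphs with implicit-hydrogen counts attached to atoms, and inter-atomic
"distance" is the number of bonds along the shortest path.  SMILES
parsing, valence/aromaticity perception and shortest paths are delegated
to RDKit; this module exposes the small, stable surface the descriptor
code relies on.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import GetDistanceMatrix

__all__ = [
    "SUPPORTED_ELEMENTS",
    "ATOMIC_WEIGHTS",
    "Atom",
    "Molecule",
    "MoleculeError",
    "parse_smiles",
    "distance_matrix",
    "molecular_weight",
    "elemental_percent",
    "molecular_formula",
    "read_smi",
    "read_molecule_csv",
    "blind_validation_compounds",
]

SUPPORTED_ELEMENTS = frozenset({"H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"})


class MoleculeError(ValueError):
    """Raised for unparseable SMILES, unsupported elements or disconnected graphs."""


def _load_element_table(name: str) -> dict[str, float]:
    text = resources.files("pyrimqsar.data").joinpath(name).read_text()
    out: dict[str, float] = {}
    for row in csv.reader(line for line in text.splitlines() if line and not line.startswith("#")):
        if row[0] in ("element",):
            continue
        out[row[0]] = float(row[1])
    return out


#: Conventional atomic weights (g/mol); versioned constant, see data file header.
ATOMIC_WEIGHTS: dict[str, float] = _load_element_table("atomic_weights.csv")


@dataclass(frozen=True)
class Atom:
    """One heavy atom: element, implicit-H count and graph degree."""

    element: str
    implicit_h: int
    aromatic: bool
    heavy_degree: int
    index: int


@dataclass
class Molecule:
    """Heavy-atom molecular graph.

    Hydrogens are never vertices: they live as counts on their heavy
    neighbour (``Atom.implicit_h``), which is how the 2D descriptors
    defined on this graph expect them.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    name: str = ""
    smiles: str = ""
    _rdmol: Chem.Mol = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def rdkit_mol(self) -> Chem.Mol:
        return self._rdmol

    def __len__(self) -> int:  # number of heavy atoms
        return len(self.atoms)


def parse_smiles(smiles: str, name: str = "") -> Molecule:
    """Parse a SMILES string into a heavy-atom :class:`Molecule`.

    Aromatic rings may be written in lowercase or Kekulé form; RDKit
    normalises both to one internal aromaticity model.  Stereochemistry
    is accepted but ignored downstream (2D descriptors only).

    Raises
    ------
    MoleculeError
        If the SMILES does not parse or contains an element outside the
        supported organic set {H, C, N, O, F, P, S, Cl, Br, I}.
    """
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise MoleculeError(f"invalid SMILES: {smiles!r}")
    atoms = []
    for a in rdmol.GetAtoms():
        sym = a.GetSymbol()
        if sym not in SUPPORTED_ELEMENTS:
            raise MoleculeError(f"unsupported element {sym!r} in {smiles!r}")
        atoms.append(
            Atom(
                element=sym,
                implicit_h=a.GetTotalNumHs(),
                aromatic=a.GetIsAromatic(),
                heavy_degree=a.GetDegree(),
                index=a.GetIdx(),
            )
        )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in rdmol.GetBonds()
    ]
    return Molecule(atoms=atoms, bonds=bonds, name=name, smiles=smiles, _rdmol=rdmol)


def distance_matrix(mol: Molecule) -> np.ndarray:
    """All-pairs shortest-path bond counts between heavy atoms.

    Raises :class:`MoleculeError` for disconnected graphs (topological
    descriptors are undefined across fragments).
    """
    d = GetDistanceMatrix(mol.rdkit_mol())
    if np.isinf(d).any() or d.max() > 1e7:
        raise MoleculeError(f"disconnected molecular graph: {mol.smiles!r}")
    return d.astype(int)


def molecular_weight(mol: Molecule) -> float:
    """Molecular weight in g/mol (implicit hydrogens included), to 2 decimals."""
    total = sum(
        ATOMIC_WEIGHTS[a.element] + a.implicit_h * ATOMIC_WEIGHTS["H"] for a in mol.atoms
    )
    return round(total, 2)


def _element_counts(mol: Molecule) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a in mol.atoms:
        counts[a.element] = counts.get(a.element, 0) + 1
        if a.implicit_h:
            counts["H"] = counts.get("H", 0) + a.implicit_h
    return counts


def molecular_formula(mol: Molecule) -> str:
    """Hill-order molecular formula, e.g. ``C7H7Cl3N2``."""
    counts = _element_counts(mol)
    parts = []
    for el in ["C", "H"] + sorted(e for e in counts if e not in ("C", "H")):
        n = counts.get(el, 0)
        if n:
            parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)


def elemental_percent(mol: Molecule, element: str) -> float:
    """Mass percent of ``element`` in the molecule (0 when absent)."""
    if element not in SUPPORTED_ELEMENTS:
        raise MoleculeError(f"unsupported element {element!r}")
    counts = _element_counts(mol)
    n = counts.get(element, 0)
    if n == 0:
        return 0.0
    total = sum(ATOMIC_WEIGHTS[el] * k for el, k in counts.items())
    return round(100.0 * ATOMIC_WEIGHTS[element] * n / total, 2)


def read_smi(path: str | Path) -> list[Molecule]:
    """Read a ``.smi`` file: one ``SMILES[<whitespace>name]`` per line."""
    mols = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        name = parts[1].strip() if len(parts) > 1 else smiles
        mols.append(parse_smiles(smiles, name=name))
    return mols


def read_molecule_csv(path: str | Path) -> tuple[list[Molecule], list[float | None]]:
    """Read molecules and activities from CSV.

    Expected columns: ``smiles``, optional ``name``, and either
    ``pic50`` or ``ic50_uM`` (converted via -log10(M)).  Returns the
    molecules and per-molecule pIC50 values (``None`` when absent).
    """
    import pandas as pd

    from .model import pic50_from_ic50

    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "smiles" not in cols:
        raise MoleculeError(f"CSV {path} lacks a 'smiles' column")
    mols, acts = [], []
    for _, row in df.iterrows():
        name = str(row[cols["name"]]) if "name" in cols else str(row[cols["smiles"]])
        mols.append(parse_smiles(str(row[cols["smiles"]]), name=name))
        if "pic50" in cols and not pd.isna(row[cols["pic50"]]):
            acts.append(float(row[cols["pic50"]]))
        elif "ic50_um" in cols and not pd.isna(row[cols["ic50_um"]]):
            acts.append(pic50_from_ic50(float(row[cols["ic50_um"]])))
        else:
            acts.append(None)
    return mols, acts


def blind_validation_compounds() -> list[Molecule]:
    """The four newly synthesised blind-validation pyrimidines (compounds 40-43)."""
    with resources.as_file(resources.files("pyrimqsar.data").joinpath("compounds_40_43.smi")) as p:
        return read_smi(p)
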