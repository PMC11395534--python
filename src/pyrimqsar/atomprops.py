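"""Per-atom weighting properties for the autocorrelation descriptors.

Four weighting schemes, keyed by the one-letter suffix used in the
descriptor names (AATSC2**s**, ATSC4**c**, ATSC3**e**, AATSC6**p**):

``s``
    Kier-Hall intrinsic state I = ((2/L)^2 * dv + 1) / d, with L the
    principal quantum number, dv the valence-electron count minus
    attached hydrogens, and d the heavy-atom degree.
``c``
    PEOE (Gasteiger-Marsili) partial charges: iterative partial
    equalisation of orbital electronegativity, implemented here with the
    classic 1980 parameter set and damped batch updates (see
    :func:`peoe_charges`).
``e``
    Sanderson electronegativity, per-element table lookup.
``p``
    Static atomic polarizability (Angstrom^3), per-element table lookup.

The PEOE implementation follows the classic descriptor-software lineage
exactly (this convention is frozen into the published model, see the
methods note): atoms are typed by element and the maximum bond order
*as written in the input SMILES* (aromatic-notation bonds count as
single), charge increments are damped by (1/2)^n, the donor atom's
cation electronegativity divides each transfer (a fixed 20.02 for
hydrogen), and iteration stops after 20 rounds or once every atom's
absolute charge changes by no more than 0.001.  An ``rdkit`` provider
(RDKit's own Gasteiger code, which uses a different parameter table) is
available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AddHs

from .molgraph import Molecule, MoleculeError, _load_element_table

__all__ = [
    "AtomWeighting",
    "SANDERSON_EN",
    "POLARIZABILITY",
    "VALENCE_ELECTRONS",
    "PRINCIPAL_QUANTUM_NUMBER",
    "PEOE_PARAMETERS",
    "intrinsic_state",
    "peoe_charges",
    "partial_charges",
    "sanderson_en",
    "polarizability",
    "atom_weighting",
    "SCHEMES",
]

#: Sanderson electronegativities, versioned table (see data file header).
SANDERSON_EN: dict[str, float] = _load_element_table("sanderson_en.csv")
#: Static atomic dipole polarizabilities in Angstrom^3, versioned table.
POLARIZABILITY: dict[str, float] = _load_element_table("polarizability.csv")

VALENCE_ELECTRONS = {
    "H": 1, "C": 4, "N": 5, "O": 6, "F": 7, "P": 5, "S": 6, "Cl": 7, "Br": 7, "I": 7,
}
PRINCIPAL_QUANTUM_NUMBER = {
    "H": 1, "C": 2, "N": 2, "O": 2, "F": 2, "P": 3, "S": 3, "Cl": 3, "Br": 4, "I": 5,
}
ATOMIC_NUMBER = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16, "Cl": 17, "Br": 35, "I": 53,
}

SCHEMES = ("s", "c", "e", "p")


@dataclass
class AtomWeighting:
    """Per-atom property vector for one weighting scheme."""

    scheme: str
    values: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def centered(self) -> np.ndarray:
        return self.values - self.mean


def intrinsic_state(mol: Molecule) -> AtomWeighting:
    """Kier-Hall intrinsic state per heavy atom (scheme ``s``).

    I = ((2/L)^2 dv + 1) / d with the generalized valence-delta
    dv = Zv - h for second-row elements and dv = (Zv - h)/(Z - Zv - 1)
    beyond (so e.g. Cl -> 1.3457, I -> 1.0249 for terminal halogens).
    Undefined for isolated atoms (heavy degree 0), which cannot occur in
    a connected multi-atom graph but is guarded anyway.
    """
    vals = np.empty(mol.n_atoms)
    for a in mol.atoms:
        if a.heavy_degree == 0:
            raise MoleculeError(f"intrinsic state undefined for isolated atom {a.index}")
        L = PRINCIPAL_QUANTUM_NUMBER[a.element]
        dv = float(VALENCE_ELECTRONS[a.element] - a.implicit_h)
        if L > 2:
            dv /= ATOMIC_NUMBER[a.element] - VALENCE_ELECTRONS[a.element] - 1
        vals[a.index] = ((2.0 / L) ** 2 * dv + 1.0) / a.heavy_degree
    return AtomWeighting("s", vals)


#: Classic PEOE electronegativity polynomial coefficients (a, b, c) of
#: chi(q) = a + b q + c q^2, keyed by (element, bond-order class) where
#: the class is the maximum bond order of the atom with aromatic bonds
#: counting as single; monovalent elements have a single class.
PEOE_PARAMETERS: dict[tuple[str, int], tuple[float, float, float]] = {
    ("H", 1): (7.17, 6.24, -0.56),
    ("C", 1): (7.98, 9.18, 1.88),
    ("C", 2): (8.79, 9.32, 1.51),
    ("C", 3): (10.39, 9.45, 0.73),
    ("N", 1): (11.54, 10.82, 1.36),
    ("N", 2): (12.87, 11.15, 0.85),
    ("N", 3): (17.68, 12.70, -0.27),
    ("O", 1): (14.18, 12.92, 1.39),
    ("O", 2): (17.07, 13.79, 0.47),
    ("F", 1): (14.66, 13.85, 2.31),
    ("Cl", 1): (12.31, 10.84, 1.512),
    ("Br", 1): (11.44, 9.63, 1.31),
    ("I", 1): (9.88, 7.95, 0.945),
    ("S", 1): (10.14, 9.13, 1.38),
    ("P", 1): (8.90, 8.32, 1.58),
}

#: PEOE iteration constants of the classic convention.
PEOE_MAX_ITERATIONS = 20
PEOE_DAMPING = 0.5
PEOE_CONVERGENCE = 1e-3
#: Fixed cation electronegativity used when hydrogen is the donor atom.
PEOE_HYDROGEN_CHI_PLUS = 20.02


def _peoe_typed_graph(
    mol: Molecule,
) -> tuple[list[tuple[float, float, float]], list[bool], list[tuple[int, int]], int]:
    """Hydrogen-expanded graph typed for PEOE.

    Atoms are typed by the maximum order of their bonds on the
    perceived graph, with aromatic bonds counting as single (the
    classic software's convention for aromatic-notation input, adopted
    here canonically so the charges do not depend on how the SMILES was
    written).  Exocyclic double bonds (e.g. the carbonyls of a
    pyrimidinedione) still promote their atoms to the double-bond type.
    """
    rdmol = AddHs(mol.rdkit_mol())
    abc, is_h = [], []
    for a in rdmol.GetAtoms():
        sym = a.GetSymbol()
        if sym in ("H", "F", "Cl", "Br", "I", "S", "P"):
            order_class = 1
        else:
            order_class = 1
            for b in a.GetBonds():
                o = 1 if b.GetIsAromatic() else int(b.GetBondTypeAsDouble())
                if o in (2, 3):
                    order_class = max(order_class, o)
        try:
            abc.append(PEOE_PARAMETERS[(sym, order_class)])
        except KeyError as e:  # pragma: no cover - supported-set guard in molgraph
            raise MoleculeError(f"no PEOE parameters for atom type {e}") from e
        is_h.append(sym == "H")
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in rdmol.GetBonds()]
    return abc, is_h, bonds, mol.n_atoms


def peoe_charges(mol: Molecule) -> np.ndarray:
    """PEOE charges on the hydrogen-expanded graph (heavy atoms first, then H).

    Damped partial equalisation of orbital electronegativity: at
    iteration n (damping factor (1/2)^n) every bond transfers

        dq = (chi_high - chi_low) / chi_plus(donor) * (1/2)^n

    from the lower- to the higher-electronegativity atom, with all
    electronegativities evaluated once per iteration from the current
    charges.  chi_plus is a + b + c of the donor, or 20.02 when the
    donor is hydrogen.  Iteration stops after 20 rounds, or early once
    no atom's absolute charge has changed by more than 0.001.
    """
    abc, is_h, bonds, _ = _peoe_typed_graph(mol)
    n = len(abc)
    q = np.zeros(n)
    q_old = np.full(n, PEOE_HYDROGEN_CHI_PLUS)
    alpha = 1.0
    for _ in range(PEOE_MAX_ITERATIONS):
        alpha *= PEOE_DAMPING
        chi = np.array([a + b * x + c * x * x for (a, b, c), x in zip(abc, q)])
        converged = bool(np.all(np.abs(np.abs(q_old) - np.abs(q)) <= PEOE_CONVERGENCE))
        q_old = q.copy()
        if converged:
            break
        for i, j in bonds:
            lo, hi = (i, j) if chi[i] <= chi[j] else (j, i)
            a, b, c = abc[lo]
            chi_plus = PEOE_HYDROGEN_CHI_PLUS if is_h[lo] else a + b + c
            dq = (chi[hi] - chi[lo]) / chi_plus * alpha
            q[lo] += dq
            q[hi] -= dq
    return q


def _rdkit_charges(mol: Molecule) -> np.ndarray:
    """RDKit's Gasteiger charges on the hydrogen-expanded graph (comparison provider)."""
    from rdkit.Chem.rdPartialCharges import ComputeGasteigerCharges

    rdmol = AddHs(mol.rdkit_mol())
    ComputeGasteigerCharges(rdmol, nIter=PEOE_MAX_ITERATIONS, throwOnParamFailure=True)
    return np.array([a.GetDoubleProp("_GasteigerCharge") for a in rdmol.GetAtoms()])


def explicit_h_charges(mol: Molecule, provider: str = "classic") -> np.ndarray:
    """PEOE charges on the hydrogen-expanded graph (heavy atoms first, then H)."""
    if provider == "classic":
        return peoe_charges(mol)
    if provider == "rdkit":
        return _rdkit_charges(mol)
    raise ValueError(f"unknown charge provider {provider!r}; expected 'classic' or 'rdkit'")


def partial_charges(
    mol: Molecule, fold_h_charges: bool = True, provider: str = "classic"
) -> AtomWeighting:
    """PEOE partial charges per heavy atom (scheme ``c``).

    Hydrogens take part in the equalisation; with ``fold_h_charges``
    their charges are summed onto the bonded heavy atom so the total
    charge of the heavy-atom vector is conserved.
    """
    q = explicit_h_charges(mol, provider=provider)
    rdmol = AddHs(mol.rdkit_mol())
    vals = np.array(q[: mol.n_atoms])
    if fold_h_charges:
        for a in rdmol.GetAtoms():
            if a.GetAtomicNum() == 1:
                heavy = a.GetNeighbors()[0].GetIdx()
                vals[heavy] += q[a.GetIdx()]
    return AtomWeighting("c", vals)


def _table_weighting(mol: Molecule, table: dict[str, float], scheme: str) -> AtomWeighting:
    if mol.n_atoms == 0:
        raise MoleculeError("empty molecule")
    try:
        vals = np.array([table[a.element] for a in mol.atoms])
    except KeyError as e:  # pragma: no cover - supported-set guard in molgraph
        raise MoleculeError(f"no {scheme!r} parameter for element {e}") from e
    return AtomWeighting(scheme, vals)


def sanderson_en(mol: Molecule) -> AtomWeighting:
    """Sanderson electronegativity per heavy atom (scheme ``e``)."""
    return _table_weighting(mol, SANDERSON_EN, "e")


def polarizability(mol: Molecule) -> AtomWeighting:
    """Static atomic polarizability per heavy atom (scheme ``p``)."""
    return _table_weighting(mol, POLARIZABILITY, "p")


_DISPATCH = {
    "s": intrinsic_state,
    "c": partial_charges,
    "e": sanderson_en,
    "p": polarizability,
}


def atom_weighting(mol: Molecule, scheme: str) -> AtomWeighting:
    """Compute the weighting for one scheme letter (``s``/``c``/``e``/``p``)."""
    try:
        fn = _DISPATCH[scheme]
    except KeyError:
        raise ValueError(f"unknown weighting scheme {scheme!r}; expected one of {SCHEMES}")
    return fn(mol)
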