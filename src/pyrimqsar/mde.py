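"""Molecular distance-edge (MDE) descriptors over typed nitrogen atoms.

A nitrogen's type is its heavy-atom degree: 1 primary, 2 secondary
(-NH- or pyridine-like ring N), 3 tertiary (-N<).  For types s <= t,

    MDEN-st = n_st / GM,   GM = (prod of d_ij) ** (1 / n_st),

where n_st counts unordered (s-type, t-type) nitrogen pairs and GM is
the geometric mean of their topological distances.  This is the n/d-bar
squared form of the original definition (d-bar_st = (prod d_ij)
** (1/(2 n_st)), so d-bar^2 = GM).  MDEN-st = 0 when no pair exists.
"""

from __future__ import annotations

import math

from .molgraph import Molecule, distance_matrix

__all__ = ["nitrogen_types", "mden"]


def nitrogen_types(mol: Molecule) -> dict[int, int]:
    """Map nitrogen atom index -> type (1, 2, 3 by heavy degree).

    Nitrogens with heavy degree outside 1..3 (e.g. quaternary) carry no
    MDE type and are omitted.
    """
    return {
        a.index: a.heavy_degree
        for a in mol.atoms
        if a.element == "N" and 1 <= a.heavy_degree <= 3
    }

def mden(mol: Molecule, s: int, t: int) -> float:
    """MDEN-st between type-s and type-t nitrogens (0 when no such pair)."""
    if not (1 <= s <= t <= 3):
        raise ValueError("nitrogen types must satisfy 1 <= s <= t <= 3")
    types = nitrogen_types(mol)
    s_atoms = [i for i, ty in types.items() if ty == s]
    t_atoms = [i for i, ty in types.items() if ty == t]
    if s == t:
        pairs = [(a, b) for ai, a in enumerate(s_atoms) for b in s_atoms[ai + 1 :]]
    else:
        pairs = [(a, b) for a in s_atoms for b in t_atoms]
    if not pairs:
        return 0.0
    d = distance_matrix(mol)
    log_gm = sum(math.log(d[i, j]) for i, j in pairs) / len(pairs)
    return len(pairs) / math.exp(log_gm)
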