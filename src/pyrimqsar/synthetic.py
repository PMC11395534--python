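"""Synthetic substituted-pyrimidine libraries with planted activities.

The curated HeLa dataset behind the published model (three assay groups
of 5, 15 and 19 compounds) is an external deposit; this module generates
stand-in data with the same statistical and chemical shape so the whole
pipeline — descriptors, split, BMLR, applicability domain — is testable
offline.  Molecules come from a small scaffold grammar (uracil
2,4-dione, 2,4-dimethoxy- and 2,4-dichloropyrimidine with N-1/N-3/C-5/
C-6 substituents); activities follow a planted linear model over
computed descriptors plus Gaussian noise, by default echoing the
published model's coefficients and residual scale (sigma ~ sqrt(0.0485)
~ 0.22 pIC50 units).

All randomness flows through one seeded generator passed explicitly; no
global state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .autocorr import DescriptorConfig, descriptor_pool
from .molgraph import Molecule, parse_smiles
from .split import GroupedDataset

__all__ = [
    "ScaffoldGrammar",
    "PlantedModel",
    "DEFAULT_GRAMMAR",
    "DEFAULT_PLANTED",
    "generate_library",
    "plant_activities",
    "grouped_fixture",
    "SyntheticStudy",
]

# 1,3-diazine ring regardless of bond-order/aromaticity notation
_PYRIMIDINE = Chem.MolFromSmarts("[#7]1~[#6]~[#7]~[#6]~[#6]~[#6]1")


@dataclass(frozen=True)
class ScaffoldGrammar:
    """SMILES templates with substitution slots.

    ``scaffolds`` are format strings whose ``{n1}``/``{n3}`` slots take
    fragments from ``n_substituents`` and ``{c5}``/``{c6}`` slots from
    ``c_substituents``; an empty fragment leaves hydrogen at that
    position (empty branches ``()`` are stripped before parsing).
    """

    scaffolds: tuple[str, ...] = (
        # uracil 2,4-dione, Kekule form; slots at N-1, N-3, C-5, C-6
        "O=C1C({c5})=C({c6})N({n1})C(=O)N1{n3}",
        # 2,4-dimethoxypyrimidine; slots at C-5, C-6
        "COc1nc(OC)c({c5})c({c6})n1",
        # 2,4-dichloropyrimidine; slots at C-5, C-6
        "Clc1nc(Cl)c({c5})c({c6})n1",
    )
    c_substituents: tuple[str, ...] = (
        "", "C", "CC", "CCC", "CCCl", "CCCCl", "C#C", "C#CC",
        "OC", "OCc1ccccc1", "CCO", "CC(C)C",
    )
    n_substituents: tuple[str, ...] = ("", "C", "CC", "COC")

    def enumerate_smiles(self) -> list[str]:
        """All template instantiations, in deterministic order."""
        out = []
        for tpl in self.scaffolds:
            slots = [s for s in ("n1", "n3", "c5", "c6") if "{" + s + "}" in tpl]
            pools = [
                self.n_substituents if s.startswith("n") else self.c_substituents
                for s in slots
            ]
            for combo in itertools.product(*pools):
                smi = tpl.format(**dict(zip(slots, combo)))
                out.append(smi.replace("()", ""))
        return out


DEFAULT_GRAMMAR = ScaffoldGrammar()


@dataclass(frozen=True)
class PlantedModel:
    """Ground-truth linear activity model for synthetic data."""

    descriptor_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    sigma: float = 0.22  # residual sd ~ sqrt of the published s2 = 0.0485
    config: DescriptorConfig = field(default_factory=DescriptorConfig)

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if len(self.coefficients) != len(self.descriptor_names):
            raise ValueError("one coefficient per descriptor required")


#: Default ground truth: the published model's descriptors and coefficients.
DEFAULT_PLANTED = PlantedModel(
    descriptor_names=("AATSC2s", "MDEN-23", "ATSC4c", "ATSC3e", "AATSC6p"),
    coefficients=(-4.66, -1.99, 3.45, 0.21, -15.28),
    intercept=4.7326,
)


def generate_library(
    n: int, grammar: ScaffoldGrammar = DEFAULT_GRAMMAR, seed: int = 0
) -> list[Molecule]:
    """n distinct, valid substituted-pyrimidine molecules (seeded shuffle).

    Raises ``ValueError`` when n exceeds the grammar's combinatorial
    space of distinct valid structures.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    candidates = grammar.enumerate_smiles()
    order = rng.permutation(len(candidates))
    mols: list[Molecule] = []
    seen: set[str] = set()
    for idx in order:
        smi = candidates[idx]
        rdmol = Chem.MolFromSmiles(smi)
        if rdmol is None or not rdmol.HasSubstructMatch(_PYRIMIDINE):
            continue
        canonical = Chem.MolToSmiles(rdmol)
        if canonical in seen:
            continue
        seen.add(canonical)
        mols.append(parse_smiles(smi, name=f"syn{len(mols):03d}"))
        if len(mols) == n:
            return mols
    raise ValueError(
        f"grammar exhausted: only {len(mols)} distinct valid structures, {n} requested"
    )


def plant_activities(
    mols: list[Molecule],
    planted: PlantedModel = DEFAULT_PLANTED,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Activities y = intercept + sum beta_j d_j(mol) + N(0, sigma^2)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    pool = descriptor_pool(mols, config=planted.config)
    X = pool[list(planted.descriptor_names)].to_numpy(dtype=float)
    signal = planted.intercept + X @ np.asarray(planted.coefficients)
    return signal + rng.normal(0.0, planted.sigma, size=len(mols))


@dataclass
class SyntheticStudy:
    """A complete synthetic dataset: molecules, activities, source groups."""

    molecules: list[Molecule]
    activities: np.ndarray
    dataset: GroupedDataset
    planted: PlantedModel

    @property
    def by_name(self) -> dict[str, Molecule]:
        return {m.name: m for m in self.molecules}


def grouped_fixture(
    sizes: tuple[int, ...] = (5, 15, 19),
    seed: int = 0,
    planted: PlantedModel = DEFAULT_PLANTED,
    grammar: ScaffoldGrammar = DEFAULT_GRAMMAR,
) -> SyntheticStudy:
    """Labelled source groups with planted activities, mirroring the
    three-assay composition of the curated dataset (default 5 + 15 + 19
    = 39 compounds)."""
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    mols = generate_library(n, grammar=grammar, seed=seed)
    y = plant_activities(mols, planted, rng=rng)
    data = GroupedDataset()
    i = 0
    for g, size in enumerate(sizes):
        for _ in range(size):
            data.add(f"group{g + 1}", mols[i].name, float(y[i]))
            i += 1
    return SyntheticStudy(molecules=mols, activities=y, dataset=data, planted=planted)
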