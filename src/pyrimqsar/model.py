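"""The frozen published QSAR model, unit conversion and prediction.

The published five-descriptor multilinear model for antiproliferative
activity against HeLa cells is

    pIC50 = -4.66 AATSC2s - 1.99 MDEN-23 + 3.45 ATSC4c
            + 0.21 ATSC3e - 15.28 AATSC6p + 4.7326

fitted on 31 training compounds (R2 = 0.85, q2_LOO = 0.797, F = 29.35,
s2 = 0.0485, external R2_test = 0.64).  The instance returned by
:func:`published_model` carries the coefficients at their printed
precision together with the pinned descriptor-computation configuration;
nothing is ever re-fitted here.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autocorr import (
    DescriptorConfig,
    DescriptorVector,
    MODEL_DESCRIPTOR_NAMES,
    model_descriptors,
)
from .molgraph import Molecule

__all__ = [
    "LinearQsarModel",
    "Activity",
    "pic50_from_ic50",
    "predict",
    "published_model",
    "PUBLISHED_CONFIG",
]

#: Descriptor conventions pinned for the published model (see autocorr docs).
PUBLISHED_CONFIG = DescriptorConfig()


@dataclass
class LinearQsarModel:
    """A multilinear descriptor->pIC50 model in natural scale."""

    descriptor_names: list[str]
    coefficients: np.ndarray
    intercept: float
    t_values: np.ndarray | None = None
    training_meta: dict = field(default_factory=dict)
    descriptor_config: DescriptorConfig = field(default_factory=DescriptorConfig)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.descriptor_names):
            raise ValueError("one coefficient per descriptor required")
        if not np.all(np.isfinite(self.coefficients)) or not math.isfinite(self.intercept):
            raise ValueError("model coefficients must be finite")

    @property
    def k(self) -> int:
        return len(self.descriptor_names)

    # -- prediction ---------------------------------------------------
    def predict_vector(self, x: DescriptorVector) -> float:
        d = x.as_dict()
        missing = [n for n in self.descriptor_names if n not in d]
        if missing:
            raise KeyError(f"descriptor(s) missing from input: {missing}")
        return float(self.intercept + sum(
            c * d[n] for c, n in zip(self.coefficients, self.descriptor_names)
        ))

    def predict_molecule(self, mol: Molecule) -> float:
        return self.predict_vector(model_descriptors(mol, self.descriptor_config))

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coefficients

    # -- serialization ------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "descriptor_names": list(self.descriptor_names),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "t_values": None if self.t_values is None else list(map(float, self.t_values)),
            "training_meta": self.training_meta,
            "descriptor_config": dataclasses.asdict(self.descriptor_config),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LinearQsarModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            descriptor_names=d["descriptor_names"],
            coefficients=np.array(d["coefficients"]),
            intercept=d["intercept"],
            t_values=None if d.get("t_values") is None else np.array(d["t_values"]),
            training_meta=d.get("training_meta", {}),
            descriptor_config=DescriptorConfig(**d.get("descriptor_config", {})),
        )


@dataclass(frozen=True)
class Activity:
    """An activity datum: IC50 in micromolar and/or pIC50.

    Assay setpoints ("> x uM": every tested concentration left more than
    half the cells alive) are carried as censored values whose pIC50 is
    the setpoint converted as if exact.
    """

    pic50: float
    ic50_uM: float | None = None
    censored: bool = False

    @classmethod
    def from_ic50(cls, ic50_uM: float | str) -> "Activity":
        censored = isinstance(ic50_uM, str) and ic50_uM.strip().startswith(">")
        value = float(str(ic50_uM).lstrip("> ")) if censored else float(ic50_uM)
        return cls(pic50=pic50_from_ic50(value), ic50_uM=value, censored=censored)


def pic50_from_ic50(ic50_uM: float) -> float:
    """pIC50 = -log10(IC50 in mol/L) for an IC50 given in micromolar."""
    if ic50_uM <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_uM}")
    return -math.log10(ic50_uM * 1e-6)


def predict(model: LinearQsarModel, x: DescriptorVector | Molecule) -> float:
    """Predicted pIC50 for a descriptor vector or a molecule."""
    if isinstance(x, Molecule):
        return model.predict_molecule(x)
    return model.predict_vector(x)


def published_model() -> LinearQsarModel:
    """The frozen published five-descriptor HeLa pIC50 model."""
    return LinearQsarModel(
        descriptor_names=list(MODEL_DESCRIPTOR_NAMES),
        coefficients=np.array([-4.66, -1.99, 3.45, 0.21, -15.28]),
        intercept=4.7326,
        t_values=np.array([-8.23321, -5.72486, 5.41163, 4.53965, -3.62229]),
        training_meta={
            "N": 31,
            "k": 5,
            "R2": 0.85,
            "q2_loo": 0.797,
            "F": 29.35,
            "s2": 0.0485,
            "R2_test": 0.64,
        },
        descriptor_config=PUBLISHED_CONFIG,
    )
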