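"""Component bookkeeping for multicomponent liquid mixtures.

A :class:`ComponentSet` fixes the component ordering used by every array in
the package (mole-fraction vectors, interaction matrices, stream flows) and
carries molar masses for mass/mole conversions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["ComponentSet", "WATER_BUTYRIC_OCTYL"]


@dataclass(frozen=True)
class ComponentSet:
    """Ordered, named components of a liquid mixture.

    Parameters
    ----------
    names
        Unique component identifiers; order defines array layout everywhere.
    molar_mass
        Molar masses in g/mol, same order as ``names``. Only used for
        mass <-> mole conversions, never in the thermodynamics.
    """

    names: tuple[str, ...]
    molar_mass: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(names) == 0:
            raise ValueError("ComponentSet requires at least one component")
        if len(set(names)) != len(names):
            raise ValueError(f"component names must be unique, got {names}")
        mm = tuple(float(m) for m in self.molar_mass)
        if mm and len(mm) != len(names):
            raise ValueError("molar_mass length must match names")
        if any(m <= 0 for m in mm):
            raise ValueError("molar masses must be positive")
        object.__setattr__(self, "molar_mass", mm)

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown component {name!r}; known: {list(self.names)}"
            ) from None

    def masses(self) -> np.ndarray:
        if not self.molar_mass:
            raise ValueError(f"no molar masses defined for {self.names}")
        return np.asarray(self.molar_mass, dtype=float)

    def mole_to_mass_fractions(self, x: Sequence[float]) -> np.ndarray:
        w = np.asarray(x, float) * self.masses()
        return w / w.sum()

    def mass_to_mole_fractions(self, w: Sequence[float]) -> np.ndarray:
        x = np.asarray(w, float) / self.masses()
        return x / x.sum()

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ComponentSet":
        return cls(tuple(mapping), tuple(mapping.values()))


#: The ternary extraction system: fermentation-broth water, the C4 acid
#: solute, and the high-boiling ester solvent.
WATER_BUTYRIC_OCTYL = ComponentSet(
    names=("water", "butyric acid", "octyl acetate"),
    molar_mass=(18.015, 88.11, 172.26),
)
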