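"""Molecular geometry container and XYZ input.

Coordinates are stored in bohr internally; XYZ files use angstrom,
following the universal convention.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

BOHR_PER_ANGSTROM = 1.8897259886

ELEMENTS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10,
}
SYMBOLS = {v: k for k, v in ELEMENTS.items()}

#: number of frozen-core spatial orbitals per element (standard chemical core)
FROZEN_CORE = {1: 0, 2: 0, 3: 1, 4: 1, 5: 1, 6: 1, 7: 1, 8: 1, 9: 1, 10: 1}


@dataclasses.dataclass(frozen=True)
class Molecule:
    symbols: tuple[str, ...]
    coords: np.ndarray            # (natom, 3) in bohr
    charge: int = 0
    multiplicity: int = 1

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, float))
        if self.coords.shape != (len(self.symbols), 3):
            raise ValueError("coordinate array must be (natom, 3)")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        n = self.n_electrons
        if (n - (self.multiplicity - 1)) % 2 != 0 or n < self.multiplicity - 1:
            raise ValueError(
                f"charge {self.charge} / multiplicity {self.multiplicity} "
                f"impossible for {n} electrons")

    @property
    def natom(self) -> int:
        return len(self.symbols)

    @property
    def charges(self) -> np.ndarray:
        return np.array([ELEMENTS[s] for s in self.symbols], float)

    @property
    def n_electrons(self) -> int:
        return int(sum(ELEMENTS[s] for s in self.symbols)) - self.charge

    @property
    def n_alpha(self) -> int:
        n = self.n_electrons
        return (n + self.multiplicity - 1) // 2

    @property
    def n_beta(self) -> int:
        return self.n_electrons - self.n_alpha

    @property
    def n_frozen_core(self) -> int:
        return int(sum(FROZEN_CORE[ELEMENTS[s]] for s in self.symbols))

    def nuclear_repulsion(self) -> float:
        z = self.charges
        e = 0.0
        for i in range(self.natom):
            for j in range(i):
                e += z[i] * z[j] / np.linalg.norm(self.coords[i] - self.coords[j])
        return e

    def to_xyz(self, comment: str = "") -> str:
        lines = [str(self.natom), comment]
        for s, r in zip(self.symbols, self.coords / BOHR_PER_ANGSTROM):
            lines.append(f"{s} {r[0]:.10f} {r[1]:.10f} {r[2]:.10f}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_xyz(cls, path: str | Path, charge: int = 0,
                 multiplicity: int = 1) -> "Molecule":
        text = Path(path).read_text().strip().splitlines()
        nat = int(text[0].split()[0])
        syms, xyz = [], []
        for line in text[2:2 + nat]:
            tok = line.split()
            syms.append(tok[0].capitalize())
            xyz.append([float(x) for x in tok[1:4]])
        coords = np.array(xyz) * BOHR_PER_ANGSTROM
        return cls(tuple(syms), coords, charge, multiplicity)
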