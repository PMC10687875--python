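"""Programmatic fixture molecules.

Small radicals and idealized alkane / alkyl-radical chains built from
standard bond parameters (C-C 1.54 A, C-H 1.09 A, tetrahedral angles,
diamond-lattice chain directions).  Geometries are deterministic given
the construction parameters; they are idealized rather than optimized,
which is sufficient because every consumer is an internal-consistency
test rather than a literature comparison.
"""
from __future__ import annotations

import numpy as np

from .mol import BOHR_PER_ANGSTROM, Molecule

CC = 1.54   # angstrom
CH = 1.09
OH_R = 0.97

_TET = np.array([[1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
                 [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]) / np.sqrt(3.0)


def _chain(n: int, radical: bool) -> Molecule:
    """Diamond-lattice carbon chain with a CH3 head and CH3/CH2* tail."""
    if n < 1:
        raise ValueError("chain length must be >= 1")
    syms, xyz = [], []
    pos = np.zeros(3)
    carbons = [pos.copy()]
    for i in range(n - 1):
        step = _TET[0] if i % 2 == 0 else -_TET[1]
        pos = pos + CC * step
        carbons.append(pos.copy())
    for i, rc in enumerate(carbons):
        syms.append("C")
        xyz.append(rc)
        sign = 1.0 if i % 2 == 0 else -1.0
        used = []
        if i > 0:
            used.append(1 if i % 2 == 0 else 0)   # incoming bond direction
        if i < n - 1:
            used.append(0 if i % 2 == 0 else 1)   # outgoing
        free = [k for k in range(4) if k not in used]
        if i == n - 1 and radical and n >= 1:
            free = free[:len(free) - 1]           # drop one H: radical site
        for k in free:
            syms.append("H")
            xyz.append(rc + CH * sign * _TET[k])
    mult = 2 if radical else 1
    return Molecule(tuple(syms), np.array(xyz) * BOHR_PER_ANGSTROM, 0, mult)


def _methyl() -> Molecule:
    # planar D3h methyl radical
    xyz = [[0.0, 0.0, 0.0]]
    for k in range(3):
        a = 2 * np.pi * k / 3
        xyz.append([CH * np.cos(a), CH * np.sin(a), 0.0])
    return Molecule(("C", "H", "H", "H"),
                    np.array(xyz) * BOHR_PER_ANGSTROM, 0, 2)


def _water(charge=0) -> Molecule:
    r, theta = 0.9572, np.deg2rad(104.52)
    xyz = np.array([[0.0, 0.0, 0.0],
                    [r, 0.0, 0.0],
                    [r * np.cos(theta), r * np.sin(theta), 0.0]])
    return Molecule(("O", "H", "H"), xyz * BOHR_PER_ANGSTROM, charge,
                    2 if charge == 1 else 1)


def _water_dimer() -> Molecule:
    w = _water()
    shift = np.array([2.98, 0.5, 0.0]) * BOHR_PER_ANGSTROM
    coords = np.vstack([w.coords, w.coords + shift])
    return Molecule(("O", "H", "H", "O", "H", "H"), coords, 0, 1)


def generate_fixture(kind: str, n: int = 1) -> Molecule:
    """Deterministic fixture molecules; see the module docstring."""
    if kind == "methyl":
        return _methyl()
    if kind == "ethyl":
        return _chain(2, radical=True)
    if kind == "hydroxyl":
        xyz = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, OH_R]])
        return Molecule(("O", "H"), xyz * BOHR_PER_ANGSTROM, 0, 2)
    if kind == "water":
        return _water()
    if kind == "water_cation":
        return _water(charge=1)
    if kind == "water_dimer":
        return _water_dimer()
    if kind == "radical_chain":
        return _methyl() if n == 1 else _chain(n, radical=True)
    if kind == "closed_chain":
        return _chain(n, radical=False)
    raise ValueError(f"unknown fixture kind '{kind}'")
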