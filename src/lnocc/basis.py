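"""Gaussian basis sets and the AO basis container.

Two orbital bases are provided:

* ``sto-3g`` — the published minimal STO-3G parameters for H, C, N, O
  (literature data).
* ``svdz`` — a split-valence double-zeta set constructed programmatically
  by decontracting the outermost STO-3G valence primitive, giving two
  radial degrees of freedom per valence shell (6-31G-style contraction
  pattern without polarization functions).

Density-fitting auxiliary bases are generated even-tempered per element
from the orbital-basis primitive exponents (products of two orbital
Gaussians have exponents in [2*a_min, 2*a_max] and angular momenta up to
the sum of the factors').
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np

from .mol import ELEMENTS, Molecule

# element -> list of (L, [exponents], [contraction coefficients])
# STO-3G: universal contraction coefficients, element-scaled exponents.
_STO3G = {
    "H": [(0, [3.42525091, 0.62391373, 0.16885540],
              [0.15432897, 0.53532814, 0.44463454])],
    "C": [(0, [71.6168370, 13.0450960, 3.53051220],
              [0.15432897, 0.53532814, 0.44463454]),
          (0, [2.94124940, 0.68348310, 0.22228990],
              [-0.09996723, 0.39951283, 0.70011547]),
          (1, [2.94124940, 0.68348310, 0.22228990],
              [0.15591627, 0.60768372, 0.39195739])],
    "N": [(0, [99.1061690, 18.0523120, 4.88566020],
              [0.15432897, 0.53532814, 0.44463454]),
          (0, [3.78045590, 0.87849660, 0.28571440],
              [-0.09996723, 0.39951283, 0.70011547]),
          (1, [3.78045590, 0.87849660, 0.28571440],
              [0.15591627, 0.60768372, 0.39195739])],
    "O": [(0, [130.709320, 23.8088610, 6.44360830],
              [0.15432897, 0.53532814, 0.44463454]),
          (0, [5.03315130, 1.16959610, 0.38038900],
              [-0.09996723, 0.39951283, 0.70011547]),
          (1, [5.03315130, 1.16959610, 0.38038900],
              [0.15591627, 0.60768372, 0.39195739])],
}


def _split_valence(shells):
    """Decontract the outermost primitive of each valence shell."""
    out = []
    for ish, (L, exps, coefs) in enumerate(shells):
        is_core = len(shells) > 1 and ish == 0
        if is_core or len(exps) < 2:
            if len(shells) == 1:        # hydrogen: split its only shell
                out.append((L, exps[:-1], coefs[:-1]))
                out.append((L, exps[-1:], [1.0]))
            else:
                out.append((L, exps, coefs))
        else:
            out.append((L, exps[:-1], coefs[:-1]))
            out.append((L, exps[-1:], [1.0]))
    return out


def _double_factorial(n: int) -> float:
    r = 1.0
    while n > 1:
        r *= n
        n -= 2
    return r


def _cart_components(L: int):
    return [(lx, ly, L - lx - ly)
            for lx in range(L, -1, -1) for ly in range(L - lx, -1, -1)]


def n_cart(L: int) -> int:
    return (L + 1) * (L + 2) // 2


def _prim_norm(L: int, a: float) -> float:
    """Norm of a primitive Cartesian Gaussian with angular momentum (L,0,0)."""
    return ((2 * a / math.pi) ** 0.75
            * (4 * a) ** (L / 2.0) / math.sqrt(_double_factorial(2 * L - 1)))


def element_shells(symbol: str, basis_name: str):
    name = basis_name.lower()
    if symbol not in _STO3G:
        raise ValueError(f"no basis data for element {symbol}")
    if name == "sto-3g":
        return [tuple(s) for s in _STO3G[symbol]]
    if name == "svdz":
        return _split_valence(_STO3G[symbol])
    raise ValueError(f"unknown basis set '{basis_name}' (available: sto-3g, svdz)")


def element_aux_shells(symbol: str, basis_name: str):
    """Even-tempered auxiliary fitting shells for one element."""
    shells = element_shells(symbol, basis_name)
    exps = np.array(sorted({e for _, es, _ in shells for e in es}))
    val = exps[exps <= 10.0]
    if len(val) == 0:
        val = exps[-1:]
    lmax = max(L for L, _, _ in shells)
    out = []
    specs = [(0, 2 * exps.min(), 2 * exps.max(), 2.5)]
    if True:  # p always present: s*p and on-center polarization of products
        specs.append((1, 2 * val.min(), 2 * val.max(), 3.0))
    if lmax >= 1:
        specs.append((2, 2 * val.min(), 2 * val.max(), 4.0))
    for L, lo, hi, beta in specs:
        n = max(1, int(math.ceil(math.log(hi / lo) / math.log(beta))) + 1)
        es = np.geomspace(lo, hi, n)
        for e in es:
            out.append((L, [float(e)], [1.0]))
    return out


@dataclasses.dataclass
class Shell:
    atom: int
    L: int
    center: np.ndarray
    exps: np.ndarray
    coefs: np.ndarray          # primitive norms folded in, contraction normalized


class AOBasis:
    """Cartesian-Gaussian AO basis over a molecule, flattened for the kernels."""

    def __init__(self, mol: Molecule, basis_name: str = "svdz", aux: bool = False):
        self.mol = mol
        self.name = basis_name
        self.shells: list[Shell] = []
        for ia, sym in enumerate(mol.symbols):
            raw = (element_aux_shells(sym, basis_name) if aux
                   else element_shells(sym, basis_name))
            for L, exps, coefs in raw:
                e = np.asarray(exps, float)
                c = np.asarray(coefs, float) * np.array(
                    [_prim_norm(L, a) for a in exps])
                # normalize the contracted (L,0,0) component
                ee = e[:, None] + e[None, :]
                s = (c[:, None] * c[None, :]
                     * (math.pi / ee) ** 1.5 / (2 * ee) ** L).sum() \
                    * _double_factorial(2 * L - 1)
                c /= math.sqrt(s)
                self.shells.append(Shell(ia, L, mol.coords[ia].copy(), e, c))
        self._build_tables()

    def _build_tables(self):
        off = 0
        self.shell_offsets = []
        self.ao_atom = []
        self.ao_comp = []          # (lx,ly,lz) per AO
        self.ao_shell = []
        for ish, sh in enumerate(self.shells):
            self.shell_offsets.append(off)
            for comp in _cart_components(sh.L):
                self.ao_atom.append(sh.atom)
                self.ao_comp.append(comp)
                self.ao_shell.append(ish)
            off += n_cart(sh.L)
        self.nao = off
        self.ao_atom = np.array(self.ao_atom)
        # flat primitive arrays for numba kernels
        self.sh_L = np.array([s.L for s in self.shells], np.int64)
        self.sh_atom = np.array([s.atom for s in self.shells], np.int64)
        self.sh_center = np.array([s.center for s in self.shells])
        self.sh_nprim = np.array([len(s.exps) for s in self.shells], np.int64)
        self.sh_ptr = np.concatenate([[0], np.cumsum(self.sh_nprim)]).astype(np.int64)
        self.prim_exp = np.concatenate([s.exps for s in self.shells])
        self.prim_coef = np.concatenate([s.coefs for s in self.shells])
        self.sh_off = np.array(self.shell_offsets, np.int64)
        # per-component angular normalization relative to (L,0,0)
        fac = []
        for sh in self.shells:
            for (lx, ly, lz) in _cart_components(sh.L):
                fac.append(math.sqrt(
                    _double_factorial(2 * sh.L - 1)
                    / (_double_factorial(2 * lx - 1)
                       * _double_factorial(2 * ly - 1)
                       * _double_factorial(2 * lz - 1))))
        self.comp_fac = np.array(fac)

    @property
    def nshell(self) -> int:
        return len(self.shells)

    def atom_ao_indices(self, atoms) -> np.ndarray:
        """AO indices (ascending) centered on the given atoms."""
        atoms = set(int(a) for a in atoms)
        return np.array([i for i, a in enumerate(self.ao_atom) if a in atoms],
                        int)
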