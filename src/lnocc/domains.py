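"""Projected atomic orbitals, Boughton-Pulay lists, primary domains and
LMO pair classification.

The virtual space is spanned by restricted PAOs (AOs with *all* occupied
orbitals, DOMOs and SOMOs alike, projected out); the spin-down virtual
space is the union of the SOMOs and the PAOs.  Around every LMO a primary
domain (PD) is built from its Boughton-Pulay (BP) atom list; approximate
MP2 pair energies evaluated with multipole-expanded integrals in the PDs
classify LMO pairs as strong or distant, with a Mulliken-overlap rescue
for borderline pairs.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import integrals as ints
from .linalg import canonical_orth, embed, project_onto_aos
from .localize import LMOSet
from .scf import ReferenceState, semicanonicalize


# ------------------------------------------------------------------- PAOs

@dataclasses.dataclass
class PAOSet:
    coefficients: np.ndarray      # AO x PAO (normalized)
    center_atom: np.ndarray       # atom index per PAO
    norms: np.ndarray             # pre-normalization norms
    degenerate: np.ndarray        # mask of near-zero-norm PAOs (flagged)


def build_paos(ref: ReferenceState, norm_floor: float = 1e-7) -> PAOSet:
    """Project all occupied orbitals (incl. frozen core and SOMOs) out of
    every AO; one PAO per AO, centered on the AO's atom."""
    S = ref.overlap
    occ = ref.mo_coeff[:, ref.occ_indices]
    P = np.eye(ref.nao) - occ @ occ.T @ S
    norms = np.sqrt(np.maximum(np.einsum("mi,mn,ni->i", P, S, P), 0.0))
    degenerate = norms <= norm_floor
    safe = np.where(degenerate, 1.0, norms)
    return PAOSet(P / safe, ref.basis.ao_atom.copy(), norms, degenerate)


# ---------------------------------------------------------------- BP lists

@dataclasses.dataclass
class BPList:
    orbital: int
    threshold: float
    atoms: np.ndarray             # ordered by Mulliken contribution
    completeness: float


def bp_atom_list(vec: np.ndarray, T: float, ref: ReferenceState,
                 orbital_id: int = -1) -> BPList:
    """Boughton-Pulay atom list of a normalized orbital.

    Atoms are ranked by Mulliken population and added until the projection
    of the orbital onto the atoms' AOs has completeness >= T.
    """
    if not (0.0 < T <= 1.0):
        raise ValueError("BP completeness threshold must be in (0, 1]")
    S = ref.overlap
    sv = S @ vec
    mull = vec * sv
    pops = np.zeros(ref.mol.natom)
    np.add.at(pops, ref.basis.ao_atom, mull)
    order = np.lexsort((np.arange(ref.mol.natom), -np.round(pops, 12)))
    chosen: list[int] = []
    comp = 0.0
    for atom in order:
        chosen.append(int(atom))
        ao_idx = ref.basis.atom_ao_indices(chosen)
        _, comp = project_onto_aos(vec, S, ao_idx)
        if comp >= T:
            break
    return BPList(orbital_id, T, np.array(chosen, int), comp)


def truncated_mulliken(vec: np.ndarray, bp: BPList,
                       ref: ReferenceState) -> dict[int, float]:
    """Per-atom Mulliken charges of the BP-truncated LMO (atom-local metric)."""
    S = ref.overlap
    ao_idx = ref.basis.atom_ao_indices(bp.atoms)
    c, _ = project_onto_aos(vec, S, ao_idx)
    full = embed(c, ao_idx, ref.nao)
    q = {}
    for atom in bp.atoms:
        idx = ref.basis.atom_ao_indices([atom])
        ca = full[idx]
        q[int(atom)] = float(ca @ S[np.ix_(idx, idx)] @ ca)
    return q


# ---------------------------------------------------------- primary domain

@dataclasses.dataclass
class PrimaryDomain:
    central: int
    atoms: np.ndarray
    ao_idx: np.ndarray
    occ_coeff: np.ndarray               # full-AO, normalized projected LMO(s)
    virt_up: np.ndarray                 # full-AO semicanonical PD virtuals
    virt_dn: np.ndarray
    eps_up: np.ndarray
    eps_dn: np.ndarray
    somo_admitted: np.ndarray           # LMO indices of admitted SOMOs
    degenerate: bool = False


class DomainBuilder:
    """Shared machinery: BP cache, PAOs and PD construction over one ref."""

    def __init__(self, ref: ReferenceState, lmos: LMOSet,
                 paos: PAOSet | None = None):
        self.ref = ref
        self.lmos = lmos
        self.paos = paos if paos is not None else build_paos(ref)
        self._bp: dict[tuple, BPList] = {}
        self._pd: dict[tuple, PrimaryDomain] = {}

    # -- cached BP lists ---------------------------------------------------
    def bp(self, kind: str, index: int, T: float) -> BPList:
        key = (kind, index, round(T, 12))
        if key not in self._bp:
            vec = (self.lmos.lmo_coefficients[:, index] if kind == "lmo"
                   else self.paos.coefficients[:, index])
            self._bp[key] = bp_atom_list(vec, T, self.ref, index)
        return self._bp[key]

    def somo_lmo_indices(self) -> np.ndarray:
        return np.where(self.lmos.somo_mask)[0]

    # -- primary domains ---------------------------------------------------
    def build_primary_domain(self, central: int, T_PDo: float = 0.999,
                             T_PDv: float = 0.98) -> PrimaryDomain:
        key = (central, round(T_PDo, 12), round(T_PDv, 12))
        if key in self._pd:
            return self._pd[key]
        ref, lmos, paos = self.ref, self.lmos, self.paos
        S = ref.overlap
        bp_c = self.bp("lmo", central, T_PDo)
        core_atoms = set(bp_c.atoms.tolist())
        pao_sel = np.where(np.isin(paos.center_atom, list(core_atoms))
                           & ~paos.degenerate)[0]
        # SOMO admission into the spin-down virtual space
        admitted = []
        for s in self.somo_lmo_indices():
            bp_s = self.bp("lmo", int(s), T_PDv)
            if core_atoms & set(bp_s.atoms.tolist()):
                admitted.append(int(s))
        atoms = set(core_atoms)
        for p in pao_sel:
            atoms |= set(self.bp("pao", int(p), T_PDv).atoms.tolist())
        for s in admitted:
            atoms |= set(self.bp("lmo", s, T_PDv).atoms.tolist())
        atoms = np.array(sorted(atoms), int)
        ao_idx = ref.basis.atom_ao_indices(atoms)

        def proj(vec):
            c, _ = project_onto_aos(vec, S, ao_idx)
            return embed(c, ao_idx, ref.nao)

        occ = proj(lmos.lmo_coefficients[:, central])
        occ /= np.sqrt(occ @ S @ occ)
        pao_p = np.column_stack([proj(paos.coefficients[:, p])
                                 for p in pao_sel]) if len(pao_sel) else \
            np.zeros((ref.nao, 0))
        central_is_domo = lmos.origin[central] == "domo"

        def virtuals(extra, project_central):
            cand = np.column_stack([extra, pao_p]) if extra is not None \
                else pao_p
            if cand.shape[1] == 0:
                return np.zeros((ref.nao, 0))
            if project_central:
                cand = cand - np.outer(occ, occ @ S @ cand)
            orth, _ = canonical_orth(cand, S, tol=1e-7)
            return orth

        v_up = virtuals(None, True)
        extra_dn = np.column_stack(
            [proj(lmos.lmo_coefficients[:, s]) for s in admitted]) \
            if admitted else None
        v_dn = virtuals(extra_dn, central_is_domo)
        if v_up.shape[1] == 0:
            pd = PrimaryDomain(central, atoms, ao_idx, occ[:, None],
                               v_up, v_dn, np.zeros(0), np.zeros(0),
                               np.array(admitted, int), degenerate=True)
            self._pd[key] = pd
            return pd
        v_up, e_up, _ = semicanonicalize(v_up, ref.fock_up)
        v_dn, e_dn, _ = semicanonicalize(v_dn, ref.fock_down)
        pd = PrimaryDomain(central, atoms, ao_idx, occ[:, None], v_up, v_dn,
                           e_up, e_dn, np.array(admitted, int))
        self._pd[key] = pd
        return pd
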