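"""Multipole-approximated MP2 pair energies and strong/distant pair
classification.

The pair energy of two LMOs k, l is an MP2-like sum over virtuals of the
two primary domains with pseudocanonical virtual energies and diagonal
occupied Fock elements in the denominator.  Integrals (k a|l b) are
expanded in point multipoles of the two charge distributions (dipole and
dipole-quadrupole order); an exact density-fitted evaluation in the union
pair domain is available as a validation fallback and for the
no-truncation limit.

Classification: |eps_kl| >= f_w * eps_w marks a strong pair, with
f_w = 1, 1/2, 1/4 for DO-DO, DO-SO, SO-SO pairs (an SO LMO carries half
as many spin cases in the pair-energy sum).  Borderline distant pairs
within a factor g_w of the threshold are promoted to strong when the
summed product of BP-truncated Mulliken charges M exceeds
h_w * |eps_kl| / f_w.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.linalg as sla

from . import integrals as ints
from .domains import DomainBuilder, PrimaryDomain, truncated_mulliken
from .linalg import canonical_orth, project_onto_aos, embed
from .scf import ReferenceState, semicanonicalize

DEFAULT_FW = {("domo", "domo"): 1.0, ("domo", "somo"): 0.5,
              ("somo", "somo"): 0.25}


@dataclasses.dataclass
class PairInfo:
    k: int
    l: int
    spin_class: str               # "DO-DO" | "DO-SO" | "SO-SO"
    f_w: float
    energy: float                 # eps_pair, hartree (<= 0)
    classification: str           # "strong" | "distant"
    m_measure: float | None = None
    promoted: bool = False


@dataclasses.dataclass
class PairList:
    pairs: list[PairInfo]
    eps_w: float
    g_w: float
    h_w: float

    def strong_partners(self, k: int) -> list[int]:
        out = []
        for p in self.pairs:
            if p.classification != "strong":
                continue
            if p.k == k:
                out.append(p.l)
            elif p.l == k:
                out.append(p.k)
        return sorted(out)

    @property
    def distant_energy(self) -> float:
        return float(sum(p.energy for p in self.pairs
                         if p.classification == "distant"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(p) for p in self.pairs])


# ------------------------------------------------------- multipole moments

def _interaction_tensors(Rvec: np.ndarray):
    """Cartesian derivative tensors of 1/R at R = C_l - C_k (orders 2-4)."""
    R = np.linalg.norm(Rvec)
    n = Rvec / R
    I = np.eye(3)
    T2 = (3.0 * np.outer(n, n) - I) / R ** 3
    T3 = np.zeros((3, 3, 3))
    for a in range(3):
        for b in range(3):
            for c in range(3):
                T3[a, b, c] = (-15.0 * n[a] * n[b] * n[c]
                               + 3.0 * (n[a] * (b == c) + n[b] * (a == c)
                                        + n[c] * (a == b))) / R ** 4
    T4 = np.zeros((3, 3, 3, 3))
    for a in range(3):
        for b in range(3):
            for c in range(3):
                for d in range(3):
                    nn = (n[a] * n[b] * (c == d) + n[a] * n[c] * (b == d)
                          + n[a] * n[d] * (b == c) + n[b] * n[c] * (a == d)
                          + n[b] * n[d] * (a == c) + n[c] * n[d] * (a == b))
                    dd = ((a == b) * (c == d) + (a == c) * (b == d)
                          + (a == d) * (b == c))
                    T4[a, b, c, d] = (105.0 * n[a] * n[b] * n[c] * n[d]
                                      - 15.0 * nn + 3.0 * dd) / R ** 5
    return T2, T3, T4


class MultipoleIntegrals:
    """AO multipole matrices about the origin, shared by all pairs."""

    def __init__(self, ref: ReferenceState):
        m = ints.multipole(ref.basis, order=3)
        self.dip = np.stack([m[(1, 0, 0)], m[(0, 1, 0)], m[(0, 0, 1)]])

        def key(*comp):
            e = [0, 0, 0]
            for c in comp:
                e[c] += 1
            return tuple(e)

        self.quad = np.array([[m[key(i, j)] for j in range(3)]
                              for i in range(3)])
        self.octu = np.array([[[m[key(i, j, k)] for k in range(3)]
                               for j in range(3)] for i in range(3)])

    def transition_moments(self, occ_vec: np.ndarray, virt: np.ndarray,
                           center: np.ndarray):
        """Raw Cartesian moments of the k*a distributions about `center`.

        Returns (d, Q, O) with shapes (3, nv), (3, 3, nv), (3, 3, 3, nv).
        The k-a overlap vanishes by construction, so the dipole is origin
        independent and higher moments shift only through lower ones.
        """
        C = center
        d = np.einsum("xmn,m,na->xa", self.dip, occ_vec, virt)
        Q0 = np.einsum("xymn,m,na->xya", self.quad, occ_vec, virt)
        O0 = np.einsum("xyzmn,m,na->xyza", self.octu, occ_vec, virt)
        Q = (Q0 - C[:, None, None] * d[None, :, :]
             - C[None, :, None] * d[:, None, :])
        O = (O0
             - C[:, None, None, None] * Q0[None, :, :, :]
             - C[None, :, None, None] * Q0[:, None, :, :]
             - C[None, None, :, None] * Q0[:, :, None, :]
             + C[:, None, None, None] * C[None, :, None, None] * d[None, None, :, :]
             + C[None, :, None, None] * C[None, None, :, None] * d[:, None, None, :]
             + C[:, None, None, None] * C[None, None, :, None] * d[None, :, None, :])
        return d, Q, O


def multipole_pair_energy(builder: DomainBuilder, mpints: MultipoleIntegrals,
                          k: int, l: int, T_PDo: float = 0.999,
                          T_PDv: float = 0.98) -> float:
    """Eq-8-style multipole pair energy of LMOs k and l (hartree, <= 0)."""
    ref, lmos = builder.ref, builder.lmos
    pd_k = builder.build_primary_domain(k, T_PDo, T_PDv)
    pd_l = builder.build_primary_domain(l, T_PDo, T_PDv)
    # the PD's own (projected, normalized) occupied orbital: exactly
    # orthogonal to the PD virtuals, so the transition densities carry no
    # spurious monopole
    ck = pd_k.occ_coeff[:, 0]
    cl = pd_l.occ_coeff[:, 0]
    Ck = np.einsum("xmn,m,n->x", mpints.dip, ck, ck)
    Cl = np.einsum("xmn,m,n->x", mpints.dip, cl, cl)
    Rvec = Cl - Ck
    if np.linalg.norm(Rvec) < 1e-6:
        raise ValueError("coincident LMO centroids in multipole pair energy")
    T2, T3, T4 = _interaction_tensors(Rvec)

    spins_k = ("up", "down") if lmos.origin[k] == "domo" else ("up",)
    spins_l = ("up", "down") if lmos.origin[l] == "domo" else ("up",)
    e = 0.0
    for sk in spins_k:
        vk = pd_k.virt_up if sk == "up" else pd_k.virt_dn
        ek = pd_k.eps_up if sk == "up" else pd_k.eps_dn
        fkk = ck @ ref.fock(sk) @ ck
        dk, Qk, Ok = mpints.transition_moments(ck, vk, Ck)
        for sl in spins_l:
            vl = pd_l.virt_up if sl == "up" else pd_l.virt_dn
            el = pd_l.eps_up if sl == "up" else pd_l.eps_dn
            fll = cl @ ref.fock(sl) @ cl
            dl, Ql, Ol = mpints.transition_moments(cl, vl, Cl)
            # fourth-order multipole expansion of (ka|lb); the expansion
            # point is A = C_k - C_l = -R, so odd-rank tensors flip sign
            eri = -np.einsum("xa,xy,yb->ab", dk, T2, dl)
            eri -= 0.5 * np.einsum("xyz,xa,yzb->ab", T3, dk, Ql)
            eri += 0.5 * np.einsum("xyz,xya,zb->ab", T3, Qk, dl)
            eri += 0.25 * np.einsum("xyzw,xya,zwb->ab", T4, Qk, Ql)
            eri -= (np.einsum("xyzw,xyza,wb->ab", T4, Ok, dl)
                    + np.einsum("xyzw,xa,yzwb->ab", T4, dk, Ol)) / 6.0
            denom = ek[:, None] + el[None, :] - fkk - fll
            if denom.size and denom.min() < 1e-6:
                raise FloatingPointError(
                    f"near-degenerate pair denominator for LMOs ({k},{l}): "
                    f"min D = {denom.min():.3e}")
            e -= float(np.sum(eri ** 2 / denom))
    return e


# -------------------------------------------------- exact pair-domain mode

def exact_pd_pair_energy(builder: DomainBuilder, df, k: int, l: int,
                         T_PDo: float = 0.999, T_PDv: float = 0.98) -> float:
    """Exact-ERI variant of the PD pair energy (validation fallback).

    Identical sum structure to :func:`multipole_pair_energy` — each LMO's
    own primary-domain virtuals, pseudocanonical energies and diagonal
    occupied Fock elements in the denominator — but with the (k a|l b)
    integrals evaluated by density fitting (auxiliaries on the union of
    the two PD atom lists) instead of the multipole expansion.  `df` is
    the whole-molecule DFTensors object.
    """
    ref, lmos = builder.ref, builder.lmos
    pd_k = builder.build_primary_domain(k, T_PDo, T_PDv)
    pd_l = builder.build_primary_domain(l, T_PDo, T_PDv)
    atoms = np.array(sorted(set(pd_k.atoms) | set(pd_l.atoms)), int)
    ck = pd_k.occ_coeff[:, 0]
    cl = pd_l.occ_coeff[:, 0]

    aux_idx = df.aux.atom_ao_indices(atoms)
    j3 = df.j3c[:, :, aux_idx]
    V = df.metric[np.ix_(aux_idx, aux_idx)]
    L = sla.cholesky(V, lower=True)

    def b_vec(occvec, virt):
        full = np.einsum("m,mnX,na->aX", occvec, j3, virt, optimize=True)
        return sla.solve_triangular(L, full.T, lower=True).T

    spins_k = ("up", "down") if lmos.origin[k] == "domo" else ("up",)
    spins_l = ("up", "down") if lmos.origin[l] == "domo" else ("up",)
    e = 0.0
    for sk in spins_k:
        vk = pd_k.virt_up if sk == "up" else pd_k.virt_dn
        ek = pd_k.eps_up if sk == "up" else pd_k.eps_dn
        fkk = ck @ ref.fock(sk) @ ck
        bk = b_vec(ck, vk)
        for sl in spins_l:
            vl = pd_l.virt_up if sl == "up" else pd_l.virt_dn
            el = pd_l.eps_up if sl == "up" else pd_l.eps_dn
            fll = cl @ ref.fock(sl) @ cl
            bl = b_vec(cl, vl)
            eri = bk @ bl.T
            denom = ek[:, None] + el[None, :] - fkk - fll
            e -= float(np.sum(eri ** 2 / denom))
    return e


# ------------------------------------------------------------ classification

def pair_spin_class(origin_k: str, origin_l: str) -> str:
    tags = sorted([origin_k, origin_l])
    return {("domo", "domo"): "DO-DO", ("domo", "somo"): "DO-SO",
            ("somo", "somo"): "SO-SO"}[tuple(tags)]


def classify_pairs(builder: DomainBuilder, energies: dict[tuple, float],
                   eps_w: float, g_w: float, h_w: float,
                   f_w: dict | None = None,
                   T_PDo: float = 0.999) -> PairList:
    """Three-way spin classing plus the Mulliken borderline extension."""
    f_w = DEFAULT_FW if f_w is None else f_w
    lmos = builder.lmos
    out = []
    for (k, l), e in sorted(energies.items()):
        ok, ol = lmos.origin[k], lmos.origin[l]
        fw = f_w[tuple(sorted([ok, ol]))]
        cls = "strong" if abs(e) >= fw * eps_w else "distant"
        m_meas, promoted = None, False
        if cls == "distant" and abs(e) >= fw * eps_w / g_w:
            bk = builder.bp("lmo", k, T_PDo)
            bl = builder.bp("lmo", l, T_PDo)
            qk = truncated_mulliken(lmos.lmo_coefficients[:, k], bk,
                                    builder.ref)
            ql = truncated_mulliken(lmos.lmo_coefficients[:, l], bl,
                                    builder.ref)
            m_meas = float(sum(qk[a] * ql[a]
                               for a in set(qk) & set(ql)))
            if m_meas >= h_w * abs(e) / fw:
                cls, promoted = "strong", True
        out.append(PairInfo(k, l, pair_spin_class(ok, ol), fw, e, cls,
                            m_meas, promoted))
    return PairList(out, eps_w, g_w, h_w)
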