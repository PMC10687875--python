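"""Local interacting subspace (LIS) integrals and bases.

The retained LNOs define the LIS of a domain.  Three-center integrals
with two virtual indices are produced in the PAO'/LNO' route: the
restricted DOMOs and SOMOs of the ED are projected out of the AOs of the
PAO-center domain (PCD) to give PAO' functions, virtual LNOs are
re-expanded in that span (LNO'), and the two-external integrals are
assembled in the LNO' basis.  Because the SOMOs play the dual role of
occupied spin-up and virtual spin-down orbitals, the SOMO-virtual and
SOMO-SOMO blocks of the spin-down two-external list are taken from the
occupied-transformed (i b'|X) and (i j|X) integrals.  Finally the
auxiliary dimension is compressed with natural auxiliary functions
(NAFs) shared by both spin channels, and everything is rotated to the
per-spin semicanonical LIS bases.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from functools import partial

_einsum = partial(np.einsum, optimize=True)
import scipy.linalg as sla

from .eddomain import EDIntegrals, ExtendedDomain
from .lno import LNOBasis
from .scf import semicanonicalize
from .spinorb import SpinOrbitalBlocks, build_spin_orbital_blocks


@dataclasses.dataclass
class NAFBasis:
    vectors: np.ndarray           # aux x kept
    eigenvalues: np.ndarray       # all eigenvalues, descending
    threshold: float

    @property
    def n_kept(self) -> int:
        return self.vectors.shape[1]


@dataclasses.dataclass
class LISSpinBlock:
    occ_mask: np.ndarray
    occ_coeff: np.ndarray
    occ_energy: np.ndarray
    occ_rot: np.ndarray
    virt_coeff: np.ndarray
    virt_energy: np.ndarray
    virt_rot: np.ndarray
    n_somo_virt: int


@dataclasses.dataclass
class LISSpace:
    """Duck-types the ExtendedDomain interface used by the MP2 machinery."""
    central: int
    central_is_somo: bool
    occ_coeff: np.ndarray         # AO x n_occ_L restricted LIS occupied
    virt_lno_coeff: np.ndarray    # AO x n_virt (LNO', prime dropped)
    up: LISSpinBlock
    down: LISSpinBlock
    naf: NAFBasis
    b_oo: dict
    b_ov: dict
    b_vv: dict
    lno_expansion_error: float    # max ||LNO - LNO'|| overlap deficit
    somo_flags: np.ndarray

    def spin(self, s: str):
        return self.up if s == "up" else self.down

    def central_image(self, s: str) -> np.ndarray:
        blk = self.spin(s)
        pos = int(np.where(np.where(blk.occ_mask)[0] == 0)[0][0])
        return blk.occ_rot[pos, :]

    @property
    def n_occ(self) -> int:
        return self.occ_coeff.shape[1]


def build_pao_prime(ed: ExtendedDomain, ref) -> np.ndarray:
    """PAO' functions: ED occupied orbitals projected out of the PCD AOs."""
    S = ref.overlap
    pcd_ao = ref.basis.atom_ao_indices(ed.pcd_atoms)
    P = np.zeros((ref.nao, len(pcd_ao)))
    P[pcd_ao, np.arange(len(pcd_ao))] = 1.0
    P -= ed.occ_coeff @ (ed.occ_coeff.T @ S @ P)
    return P


def lno_prime_expansion(ed: ExtendedDomain, ref, lno_virt_ao: np.ndarray,
                        pao_prime: np.ndarray):
    """Least-squares re-expansion of the virtual LNOs in the PAO' span.

    Returns (AO coefficients of the LNO' set, max per-orbital overlap
    deficit ||LNO - LNO'||).
    """
    S = ref.overlap
    G = pao_prime.T @ S @ pao_prime
    rhs = pao_prime.T @ S @ lno_virt_ao
    w, v = np.linalg.eigh(G)
    keep = w > 1e-10 * max(w.max(), 1.0)
    Ginv = (v[:, keep] / w[keep]) @ v[:, keep].T
    A = Ginv @ rhs
    lno_p = pao_prime @ A
    diff = lno_virt_ao - lno_p
    errs = np.sqrt(np.maximum(_einsum("mi,mn,ni->i", diff, S, diff), 0.0))
    return lno_p, float(errs.max()) if errs.size else 0.0


def naf_compress(tensors: list, eps_naf: float) -> NAFBasis:
    """Shared NAF basis from the spin-averaged W = (W_up + W_dn)/2."""
    naux = tensors[0][0].shape[-1]
    W = {"up": np.zeros((naux, naux)), "down": np.zeros((naux, naux))}
    for t, spin in tensors:
        flat = t.reshape(-1, naux)
        W[spin] += flat.T @ flat
    Wavg = 0.5 * (W["up"] + W["down"])
    w, v = np.linalg.eigh(0.5 * (Wavg + Wavg.T))
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    # deterministic sign fix: largest component positive
    for k in range(v.shape[1]):
        imax = int(np.argmax(np.abs(v[:, k])))
        if v[imax, k] < 0:
            v[:, k] = -v[:, k]
    keep = w > eps_naf
    return NAFBasis(v[:, keep], w, eps_naf)


def build_lis(ed: ExtendedDomain, ref, df, lnos: LNOBasis,
              eps_naf: float = 1e-2) -> LISSpace:
    """Assemble the LIS bases and its NAF-compressed DF integrals."""
    S = ref.overlap
    occ_L = ed.occ_coeff @ lnos.occ_vectors          # restricted LIS occupied
    virt_lno = ed.pao_coeff @ lnos.virt_vectors
    pao_p = build_pao_prime(ed, ref)
    virt_p, expansion_err = lno_prime_expansion(ed, ref, virt_lno, pao_p)
    # re-orthonormalize the LNO' set among themselves and against the
    # occupied space (the projection is approximate)
    virt_p = virt_p - occ_L @ (occ_L.T @ S @ virt_p)
    g = virt_p.T @ S @ virt_p
    w, v = np.linalg.eigh(0.5 * (g + g.T))
    if w.min() < 1e-8:
        # rank deficiency: fall back to the exact-LNO expansion
        virt_p = virt_lno - occ_L @ (occ_L.T @ S @ virt_lno)
        g = virt_p.T @ S @ virt_p
        w, v = np.linalg.eigh(0.5 * (g + g.T))
    virt_p = virt_p @ (v / np.sqrt(w)) @ v.T

    aux_idx = df.aux.atom_ao_indices(ed.pcd_atoms)
    j3 = df.j3c[:, :, aux_idx]
    V = df.metric[np.ix_(aux_idx, aux_idx)]
    L = sla.cholesky(V, lower=True)

    half_occ = _einsum("mi,mnX->inX", occ_L, j3, optimize=True)
    r_oo = _einsum("inX,nj->ijX", half_occ, occ_L, optimize=True)
    r_ov = _einsum("inX,na->iaX", half_occ, virt_p, optimize=True)
    half_v = _einsum("ma,mnX->anX", virt_p, j3, optimize=True)
    r_vv = _einsum("anX,nb->abX", half_v, virt_p, optimize=True)

    somo_flags = np.zeros(occ_L.shape[1], bool)
    somo_flags[1:1 + lnos.n_somo] = True
    if ed.central_is_somo:
        somo_flags[0] = True
    n_s = int(somo_flags.sum())
    nv = virt_p.shape[1]
    # spin-down restricted virtual basis: [SOMOs | LNO virtuals]; complete
    # the SOMO blocks of the two-external list from the occupied integrals
    vv_dn = np.zeros((n_s + nv, n_s + nv, len(aux_idx)))
    s_idx = np.where(somo_flags)[0]
    vv_dn[:n_s, :n_s] = r_oo[np.ix_(s_idx, s_idx)]
    vv_dn[:n_s, n_s:] = r_ov[s_idx]
    vv_dn[n_s:, :n_s] = r_ov[s_idx].transpose(1, 0, 2)
    vv_dn[n_s:, n_s:] = r_vv

    def whiten(t):
        flat = t.reshape(-1, len(aux_idx))
        return sla.solve_triangular(L, flat.T, lower=True).T.reshape(t.shape)

    w_oo = whiten(r_oo)
    w_ov = whiten(r_ov)
    w_vv = whiten(r_vv)
    w_vv_dn = whiten(vv_dn)

    naf = naf_compress(
        [(w_oo, "up"), (w_ov, "up"), (w_vv, "up"),
         (w_oo[np.ix_(~somo_flags, ~somo_flags)], "down"),
         (w_ov[~somo_flags], "down"), (w_vv_dn, "down")], eps_naf)
    N = naf.vectors

    # per-spin semicanonical LIS bases
    blocks = {}
    for s in ("up", "down"):
        F = ed.fock[s]
        if s == "up":
            occ_mask = np.ones(occ_L.shape[1], bool)
            occ_sub = occ_L
            virt_restricted = virt_p
            n_somo_virt = 0
            oo_r, ov_r, vv_r = w_oo, w_ov, w_vv
        else:
            occ_mask = ~somo_flags
            occ_sub = occ_L[:, occ_mask]
            somo_cols = occ_L[:, somo_flags]
            virt_restricted = np.column_stack([somo_cols, virt_p]) \
                if n_s else virt_p
            n_somo_virt = n_s
            oo_r = w_oo[np.ix_(occ_mask, occ_mask)]
            ov_full = np.concatenate(
                [w_oo[np.ix_(occ_mask, somo_flags)], w_ov[occ_mask]],
                axis=1)
            ov_r = ov_full
            vv_r = w_vv_dn
        oc, oe, orot = semicanonicalize(occ_sub, F)
        vc, ve, vrot = semicanonicalize(virt_restricted, F)
        b_oo = _einsum("pi,pqX,qj->ijX", orot, oo_r, orot, optimize=True)
        b_ov = _einsum("pi,pqX,qa->iaX", orot, ov_r, vrot, optimize=True)
        b_vv = _einsum("pa,pqX,qb->abX", vrot, vv_r, vrot, optimize=True)
        blocks[s] = (LISSpinBlock(occ_mask, oc, oe, orot, vc, ve, vrot,
                                  n_somo_virt),
                     b_oo @ N, b_ov @ N, b_vv @ N)

    lis = LISSpace(
        central=ed.central, central_is_somo=ed.central_is_somo,
        occ_coeff=occ_L, virt_lno_coeff=virt_p,
        up=blocks["up"][0], down=blocks["down"][0], naf=naf,
        b_oo={s: blocks[s][1] for s in ("up", "down")},
        b_ov={s: blocks[s][2] for s in ("up", "down")},
        b_vv={s: blocks[s][3] for s in ("up", "down")},
        lno_expansion_error=expansion_err, somo_flags=somo_flags)
    return lis


def lis_spin_orbital_blocks(lis: LISSpace, ed: ExtendedDomain,
                            ref) -> SpinOrbitalBlocks:
    """Spin-orbital container for the LIS CCSD(T) solver."""
    f_blocks, eps_o, eps_v = {}, {}, {}
    for s in ("up", "down"):
        F = ed.fock[s]
        blk = lis.spin(s)
        f_blocks[(s, "oo")] = blk.occ_coeff.T @ F @ blk.occ_coeff
        f_blocks[(s, "ov")] = blk.occ_coeff.T @ F @ blk.virt_coeff
        f_blocks[(s, "vv")] = blk.virt_coeff.T @ F @ blk.virt_coeff
        eps_o[s], eps_v[s] = blk.occ_energy, blk.virt_energy
    return build_spin_orbital_blocks(lis.b_oo, lis.b_ov, lis.b_vv,
                                     f_blocks, eps_o, eps_v)


def central_spin_orbital_projectors(lis: LISSpace):
    """Central-LMO projector vectors in the occupied spin-orbital basis."""
    no_up = len(lis.up.occ_energy)
    no_dn = len(lis.down.occ_energy)
    out = []
    u = np.zeros(no_up + no_dn)
    u[:no_up] = lis.central_image("up")
    out.append(u)
    if not lis.central_is_somo:
        u = np.zeros(no_up + no_dn)
        u[no_up:] = lis.central_image("down")
        out.append(u)
    return out
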