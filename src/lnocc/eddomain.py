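"""Extended domains: assembly, DF integrals, MP1 amplitudes and domain MP2.

The extended domain (ED) of a central LMO collects the central orbital
and its strong pair partners; its atoms are the union of the extensive
(T_EDo) BP lists of those LMOs, and the PAO-center domain (PCD) is the
union of their compact (T_0) BP lists.  Occupied orbitals are projected
onto the ED AOs and re-orthogonalized by a Gram-Schmidt + Loewdin (GSL)
scheme that keeps the central LMO and the SOMOs unchanged; the virtual
space is spanned by PAOs centered on PCD atoms (plus the SOMOs for the
spin-down electrons).  Per-spin semicanonical bases make iteration-free
MP1 amplitudes possible through a factorized energy denominator; fixing
one occupied index to the central LMO yields the domain's MP2 energy
contribution, with singles evaluated from the off-diagonal part of the
full-molecule Fock matrix only (truncation-induced singles discarded).
"""
from __future__ import annotations

import dataclasses

import numpy as np
from functools import partial

_einsum = partial(np.einsum, optimize=True)
import scipy.linalg as sla

from .domains import DomainBuilder
from .laplace import (LaplaceQuadrature, cauchy_cholesky, laplace_quadrature)
from .linalg import canonical_orth, embed, lowdin, project_onto_aos
from .pairs import PairList
from .scf import ReferenceState, semicanonicalize

SPIN_CASES = (("up", "up"), ("up", "down"), ("down", "up"), ("down", "down"))


class DomainError(RuntimeError):
    pass


@dataclasses.dataclass
class SpinBlock:
    """One spin channel of an ED: semicanonical occupied/virtual bases."""
    occ_mask: np.ndarray          # restricted occ columns active in this spin
    occ_coeff: np.ndarray         # AO x n_occ_sigma, semicanonical
    occ_energy: np.ndarray
    occ_rot: np.ndarray           # restricted(masked) -> semicanonical
    virt_coeff: np.ndarray        # AO x n_virt_sigma, semicanonical
    virt_energy: np.ndarray
    virt_rot: np.ndarray          # restricted virtual basis -> semicanonical
    n_somo_virt: int              # leading restricted virtual cols = SOMOs


@dataclasses.dataclass
class ExtendedDomain:
    central: int
    occ_ids: list                 # restricted order: central, SOMOs, DOMOs
    atoms: np.ndarray
    pcd_atoms: np.ndarray
    ao_idx: np.ndarray
    occ_coeff: np.ndarray         # AO x n_occ, GSL-orthonormalized restricted
    pao_coeff: np.ndarray         # AO x n_vp, orthonormal restricted PAOs
    up: SpinBlock
    down: SpinBlock
    spin_free: bool
    spin_averaged: bool
    fock: dict                    # spin -> AO Fock actually used
    central_is_somo: bool

    @property
    def n_occ(self) -> int:
        return self.occ_coeff.shape[1]

    @property
    def somo_positions(self) -> np.ndarray:
        flags = self.somo_flags
        return np.where(flags)[0]

    @property
    def somo_flags(self) -> np.ndarray:
        return np.array([f for f in self._somo_flags])

    def spin(self, s: str) -> SpinBlock:
        return self.up if s == "up" else self.down

    def central_image(self, s: str) -> np.ndarray:
        """Row of the semicanonical transform giving the central LMO."""
        blk = self.spin(s)
        pos = int(np.where(np.where(blk.occ_mask)[0] == 0)[0][0])
        return blk.occ_rot[pos, :]


def assemble_ed(builder: DomainBuilder, central: int, pair_list: PairList,
                T_EDo: float = 0.9999, T_0: float = 0.985,
                spin_polarization_approx: bool = False) -> ExtendedDomain:
    ref, lmos = builder.ref, builder.lmos
    S = ref.overlap
    partners = pair_list.strong_partners(central)
    somo_ids = [i for i in partners if lmos.origin[i] == "somo"]
    domo_ids = [i for i in partners if lmos.origin[i] == "domo"]
    occ_ids = [central] + sorted(somo_ids) + sorted(domo_ids)
    atoms = set()
    pcd = set()
    for i in occ_ids:
        atoms |= set(builder.bp("lmo", i, T_EDo).atoms.tolist())
        pcd |= set(builder.bp("lmo", i, T_0).atoms.tolist())
    atoms = np.array(sorted(atoms), int)
    pcd_atoms = np.array(sorted(pcd), int)
    ao_idx = ref.basis.atom_ao_indices(atoms)

    def proj(vec):
        c, comp = project_onto_aos(vec, S, ao_idx)
        return embed(c, ao_idx, ref.nao), comp

    cvec, comp = proj(lmos.lmo_coefficients[:, central])
    if 1.0 - comp > 2.0 * (1.0 - T_EDo) + 1e-10:
        raise DomainError(
            f"central LMO {central} loses {1-comp:.2e} norm on its ED "
            f"(> {1-T_EDo:.0e}): domain too small")
    cols = [cvec / np.sqrt(cvec @ S @ cvec)]
    # Gram-Schmidt: SOMOs in ascending index order after the central LMO
    for i in sorted(somo_ids):
        v, _ = proj(lmos.lmo_coefficients[:, i])
        for u in cols:
            v = v - u * (u @ S @ v)
        nrm = v @ S @ v
        if nrm < 1e-8:
            raise DomainError(f"SOMO {i} lost in GSL orthogonalization")
        cols.append(v / np.sqrt(nrm))
    # Loewdin on the remaining (projected) DOMOs
    if domo_ids:
        D = np.column_stack([proj(lmos.lmo_coefficients[:, i])[0]
                             for i in sorted(domo_ids)])
        fixed = np.column_stack(cols)
        D = D - fixed @ (fixed.T @ S @ D)
        D = lowdin(D, S)
        C_occ = np.column_stack([fixed, D])
    else:
        C_occ = np.column_stack(cols)

    # virtual space: PAOs centered on PCD atoms, projected to ED AOs,
    # occupied space projected out, Loewdin canonical orthogonalization
    pao_sel = np.where(np.isin(builder.paos.center_atom, pcd_atoms)
                       & ~builder.paos.degenerate)[0]
    P = np.column_stack([proj(builder.paos.coefficients[:, p])[0]
                         for p in pao_sel])
    P = P - C_occ @ (C_occ.T @ S @ P)
    C_pao, _ = canonical_orth(P, S, tol=1e-7)
    if C_pao.shape[1] == 0:
        raise DomainError(f"ED of LMO {central} has an empty virtual space")

    somo_flags = [lmos.origin[i] == "somo" for i in occ_ids]
    spin_free = not any(somo_flags)
    spin_averaged = spin_polarization_approx and spin_free
    if spin_averaged:
        Favg = 0.5 * (ref.fock_up + ref.fock_down)
        focks = {"up": Favg, "down": Favg}
    else:
        focks = {"up": ref.fock_up, "down": ref.fock_down}

    mask_up = np.ones(len(occ_ids), bool)
    mask_dn = ~np.array(somo_flags)
    somo_cols = C_occ[:, np.array(somo_flags)]

    def make_block(spin, occ_mask, virt_restricted, n_somo_virt):
        occ_sub = C_occ[:, occ_mask]
        oc, oe, orot = semicanonicalize(occ_sub, focks[spin])
        vc, ve, vrot = semicanonicalize(virt_restricted, focks[spin])
        return SpinBlock(occ_mask, oc, oe, orot, vc, ve, vrot, n_somo_virt)

    up = make_block("up", mask_up, C_pao, 0)
    virt_dn = np.column_stack([somo_cols, C_pao]) if somo_cols.shape[1] \
        else C_pao
    down = make_block("down", mask_dn, virt_dn, somo_cols.shape[1])

    ed = ExtendedDomain(central, occ_ids, atoms, pcd_atoms, ao_idx, C_occ,
                        C_pao, up, down, spin_free, spin_averaged, focks,
                        lmos.origin[central] == "somo")
    ed._somo_flags = somo_flags
    return ed


# ------------------------------------------------------------ DF integrals

@dataclasses.dataclass
class EDIntegrals:
    """Cholesky-decomposed DF factors in the ED bases.

    b_ov[s]: (n_occ_s, n_virt_s, nX); b_oo[s]; b_vv[s]; all in the
    semicanonical per-spin bases, auxiliary functions restricted to PCD
    atoms and whitened with the inverse Cholesky factor of the metric, so
    (pq|rs) = b_pq . b_rs.
    """
    b_ov: dict
    b_oo: dict
    b_vv: dict
    aux_idx: np.ndarray


def transform_df_integrals(ed: ExtendedDomain, df,
                           aux_atoms=None) -> EDIntegrals:
    """DF integrals in the ED bases; auxiliaries on the PCD atoms by
    default (pass `aux_atoms` to override, e.g. for full-aux checks)."""
    ref_aux = df.aux
    aux_idx = ref_aux.atom_ao_indices(
        ed.pcd_atoms if aux_atoms is None else aux_atoms)
    V = df.metric[np.ix_(aux_idx, aux_idx)]
    try:
        L = sla.cholesky(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise DomainError(
            f"PCD-restricted auxiliary metric not positive definite "
            f"(atoms {ed.pcd_atoms.tolist()})") from exc
    j3 = df.j3c[:, :, aux_idx]
    # first transformation index: the restricted occupied basis
    half_occ = _einsum("mi,mnX->inX", ed.occ_coeff, j3, optimize=True)
    half_pao = _einsum("ma,mnX->anX", ed.pao_coeff, j3, optimize=True)

    def whiten(t):
        flat = t.reshape(-1, len(aux_idx))
        return sla.solve_triangular(L, flat.T, lower=True).T.reshape(t.shape)

    b_ov, b_oo, b_vv = {}, {}, {}
    for s in ("up", "down"):
        blk = ed.spin(s)
        occ_half = half_occ[blk.occ_mask]            # restricted occ rows
        occ_half = _einsum("po,pnX->onX", blk.occ_rot, occ_half)
        oo = _einsum("onX,nq->oqX", occ_half,
                       blk.occ_coeff, optimize=True)
        ov = _einsum("onX,nq->oqX", occ_half,
                       blk.virt_coeff, optimize=True)
        # vir-vir with the restricted PAO (plus SOMO) first index
        if blk.n_somo_virt:
            somo_half = half_occ[np.array(ed._somo_flags)]
            virt_half = np.concatenate([somo_half, half_pao], axis=0)
        else:
            virt_half = half_pao
        virt_half = _einsum("pa,pnX->anX", blk.virt_rot, virt_half)
        vv = _einsum("anX,nb->abX", virt_half,
                       blk.virt_coeff, optimize=True)
        b_oo[s] = whiten(oo)
        b_ov[s] = whiten(ov)
        b_vv[s] = whiten(vv)
    return EDIntegrals(b_ov, b_oo, b_vv, aux_idx)


# -------------------------------------------------- denominator machinery

def denominator_range(ed: ExtendedDomain):
    """Pooled single-excitation gap range over both spins."""
    gmin, gmax = np.inf, -np.inf
    for s in ("up", "down"):
        blk = ed.spin(s)
        if not len(blk.occ_energy) or not len(blk.virt_energy):
            continue
        gmin = min(gmin, blk.virt_energy.min() - blk.occ_energy.max())
        gmax = max(gmax, blk.virt_energy.max() - blk.occ_energy.min())
    return 2.0 * gmin, 2.0 * gmax


def ed_quadrature(ed: ExtendedDomain, tol: float = 1e-2) -> LaplaceQuadrature:
    lo, hi = denominator_range(ed)
    return laplace_quadrature(lo, hi, tol)


def build_fock_offdiagonal(ref: ReferenceState) -> dict:
    """Off-diagonal part of the per-spin Fock matrices in the AO basis.

    F_OD = F - S C diag(C^T F C) C^T S vanishes for a self-consistent
    (RHF/UHF) reference; for a restricted open-shell reference it carries
    the only singles contribution retained in the domain MP2 energies.
    """
    out = {}
    S, C = ref.overlap, ref.mo_coeff
    for s, F in (("up", ref.fock_up), ("down", ref.fock_down)):
        eps = np.diag(C.T @ F @ C)
        out[s] = F - S @ C @ np.diag(eps) @ C.T @ S
    return out


# ---------------------------------------------------------- MP1 amplitudes

def mp1_amplitudes(ed: ExtendedDomain, ints: EDIntegrals,
                   quad: LaplaceQuadrature,
                   factorization: str = "laplace") -> dict:
    """MP1 doubles amplitudes with one occupied index fixed to the central
    LMO, for all spin cases present.

    Returns {(s_central, s_other): t} with t[j, a, b] =
    <central_s j_t || ...> MP1 amplitude = (K_ca,jb) / D in closed form via
    the factorized denominator; t is the plain (non-antisymmetrized)
    amplitude t_{cj}^{ab} = (c a|j b)/(e_c + e_j - e_a - e_b).
    """
    cases = {}
    spins_c = ("up",) if ed.central_is_somo else ("up", "down")
    if factorization == "laplace":
        facs = _laplace_factors(ed, quad)
    elif factorization == "cholesky":
        facs = _cholesky_factors(ed, quad)
    elif factorization == "exact":
        facs = None
    else:
        raise ValueError(f"unknown denominator factorization {factorization}")
    for sc in spins_c:
        u_c = ed.central_image(sc)
        for so in ("up", "down"):
            bc = ints.b_ov[sc]
            bo = ints.b_ov[so]
            if facs is None:
                t = _exact_amplitudes(ed, u_c, sc, so, bc, bo)
            else:
                t = _factorized_amplitudes(ed, u_c, sc, so, bc, bo, facs)
            cases[(sc, so)] = t
    return cases


def _exact_amplitudes(ed, u_c, sc, so, bc, bo):
    """Reference path: explicit denominators, then central transform."""
    K = _einsum("iaX,jbX->iajb", bc, bo, optimize=True)
    ec_o, ec_v = ed.spin(sc).occ_energy, ed.spin(sc).virt_energy
    eo_o, eo_v = ed.spin(so).occ_energy, ed.spin(so).virt_energy
    D = (ec_o[:, None, None, None] + eo_o[None, None, :, None]
         - ec_v[None, :, None, None] - eo_v[None, None, None, :])
    t_full = K / D
    return _einsum("i,iajb->jab", u_c, t_full)


def _laplace_factors(ed, quad):
    return ("laplace", quad)


def _cholesky_factors(ed, quad):
    # pooled composite (i,a) gaps over both spins; pivoted Cholesky of the
    # Cauchy kernel at a tolerance tied to the quadrature's T_LT
    xs, slices = [], {}
    off = 0
    for s in ("up", "down"):
        blk = ed.spin(s)
        g = (blk.virt_energy[None, :] - blk.occ_energy[:, None]).ravel()
        xs.append(g)
        slices[s] = slice(off, off + g.size)
        off += g.size
    L = cauchy_cholesky(np.concatenate(xs), tol=(quad.tol * 1e-4) ** 2)
    return ("cholesky", L, slices)


def _factorized_amplitudes(ed, u_c, sc, so, bc, bo, facs):
    no_c, nv_c, nX = bc.shape
    no_o, nv_o, _ = bo.shape
    t = np.zeros((no_o, nv_c, nv_o))
    if facs[0] == "laplace":
        quad = facs[1]
        ec_o, ec_v = ed.spin(sc).occ_energy, ed.spin(sc).virt_energy
        eo_o, eo_v = ed.spin(so).occ_energy, ed.spin(so).virt_energy
        for t_w, w_w in zip(quad.points, quad.weights):
            ui = u_c * np.exp(ec_o * t_w)            # dressed central row
            fa = np.exp(-ec_v * t_w)
            fj = np.exp(eo_o * t_w)
            fb = np.exp(-eo_v * t_w)
            left = _einsum("i,iaX->aX", ui, bc) * fa[:, None]
            right = bo * fj[:, None, None] * fb[None, :, None]
            t -= w_w * _einsum("aX,jbX->jab", left, right, optimize=True)
    else:
        _, L, slices = facs
        Lc = L[slices[sc]].reshape(no_c, nv_c, -1)
        Lo = L[slices[so]].reshape(no_o, nv_o, -1)
        nw = L.shape[1]
        for w in range(nw):
            left = _einsum("i,ia,iaX->aX", u_c, Lc[:, :, w], bc,
                             optimize=True)
            right = bo * Lo[:, :, w][:, :, None]
            t -= _einsum("aX,jbX->jab", left, right, optimize=True)
    return t


# ------------------------------------------------------------- ED MP2 energy

def ed_mp2_energy(ed: ExtendedDomain, ints: EDIntegrals, amplitudes: dict,
                  f_od: dict | None) -> float:
    """MP2 energy contribution of the central LMO in its ED.

    Doubles from the central-fixed MP1 amplitudes (all spin cases);
    singles evaluated with the off-diagonal full-molecule Fock matrix
    only.  Both spin components are included for a DO central, one for an
    SO central.
    """
    e = 0.0
    spins_c = ("up",) if ed.central_is_somo else ("up", "down")
    for sc in spins_c:
        u_c = ed.central_image(sc)
        bc_c = _einsum("i,iaX->aX", u_c, ints.b_ov[sc])
        for so in ("up", "down"):
            t = amplitudes[(sc, so)]
            K = _einsum("aX,jbX->jab", bc_c, ints.b_ov[so], optimize=True)
            if sc == so:
                tbar = t - t.swapaxes(1, 2)
                Kbar = K - K.swapaxes(1, 2)
                e += 0.25 * float(np.sum(tbar * Kbar))
            else:
                e += 0.5 * float(np.sum(t * K))
        if f_od is not None:
            blk = ed.spin(sc)
            F = f_od[sc]
            f_ov = blk.occ_coeff.T @ F @ blk.virt_coeff
            denom = blk.occ_energy[:, None] - blk.virt_energy[None, :]
            t1 = f_ov / denom
            e += float((u_c @ f_ov) @ (u_c @ t1))
    return e
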