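"""Brute-force canonical references: DF-MP2, DF-CCSD and (T).

This module provides the independent yardstick against which the local
pipeline is validated: canonical correlated energies over the whole
molecule in the semicanonical per-spin basis of the restricted
open-shell reference, computed with explicit denominators and
contraction routines written separately from the local-subspace solver.
Frozen-core orbitals are excluded throughout.  A size guard refuses
systems beyond desk scale.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from functools import partial

_einsum = partial(np.einsum, optimize=True)
import scipy.linalg as sla

from .ccsd import CCSDConvergenceError, _AmplitudeDIIS
from .scf import DFTensors, ReferenceState, semicanonicalize
from .spinorb import SpinOrbitalBlocks, build_spin_orbital_blocks
from .triples import triples_energy_explicit

MAX_SPIN_ORBITALS = 260


@dataclasses.dataclass
class OracleResult:
    method: str
    scf_energy: float
    corr_mp2: float
    corr_ccsd: float | None = None
    corr_t: float | None = None
    mp2_partition: np.ndarray | None = None
    ccsd_partition: np.ndarray | None = None
    t_partition: np.ndarray | None = None

    @property
    def corr_total(self) -> float:
        e = self.corr_mp2 if self.corr_ccsd is None else self.corr_ccsd
        if self.corr_t is not None:
            e = e + self.corr_t
        return e

    @property
    def total_energy(self) -> float:
        return self.scf_energy + self.corr_total

    def to_json(self) -> str:
        import json
        return json.dumps({
            "method": self.method,
            "scf_energy": self.scf_energy,
            "corr_mp2": self.corr_mp2,
            "corr_ccsd": self.corr_ccsd,
            "corr_t": self.corr_t,
            "corr_total": self.corr_total,
            "total_energy": self.total_energy,
        }, indent=1)


def canonical_blocks(ref: ReferenceState, df: DFTensors) -> SpinOrbitalBlocks:
    """Whole-molecule spin-orbital blocks in semicanonical per-spin bases."""
    C = ref.mo_coeff
    fz = set(ref.frozen_core_indices.tolist())
    occ_up = [i for i in ref.occ_indices if i not in fz]
    occ_dn = [i for i in ref.domo_indices if i not in fz]
    vir_up = list(ref.virtual_indices)
    vir_dn = list(ref.somo_indices) + list(ref.virtual_indices)
    spaces = {}
    for s, occ, vir in (("up", occ_up, vir_up), ("down", occ_dn, vir_dn)):
        F = ref.fock(s)
        co, eo, _ = semicanonicalize(C[:, occ], F)
        cv, ev, _ = semicanonicalize(C[:, vir], F)
        spaces[s] = (co, eo, cv, ev, F)
    nso = sum(len(spaces[s][1]) + len(spaces[s][3]) for s in ("up", "down"))
    if nso > MAX_SPIN_ORBITALS:
        raise ValueError(
            f"{nso} spin orbitals exceed the oracle size guard "
            f"({MAX_SPIN_ORBITALS}); the canonical reference is desk-scale "
            "only")
    L = sla.cholesky(df.metric, lower=True)

    def whiten(t):
        flat = t.reshape(-1, df.aux.nao)
        return sla.solve_triangular(L, flat.T, lower=True).T.reshape(t.shape)

    b_oo, b_ov, b_vv, f_blocks, eps_o, eps_v = {}, {}, {}, {}, {}, {}
    for s in ("up", "down"):
        co, eo, cv, ev, F = spaces[s]
        half = _einsum("mi,mnX->inX", co, df.j3c, optimize=True)
        b_oo[s] = whiten(_einsum("inX,nj->ijX", half, co, optimize=True))
        b_ov[s] = whiten(_einsum("inX,na->iaX", half, cv, optimize=True))
        halfv = _einsum("ma,mnX->anX", cv, df.j3c, optimize=True)
        b_vv[s] = whiten(_einsum("anX,nb->abX", halfv, cv, optimize=True))
        f_blocks[(s, "oo")] = co.T @ F @ co
        f_blocks[(s, "ov")] = co.T @ F @ cv
        f_blocks[(s, "vv")] = cv.T @ F @ cv
        eps_o[s], eps_v[s] = eo, ev
    return build_spin_orbital_blocks(b_oo, b_ov, b_vv, f_blocks, eps_o, eps_v)


def oracle_mp2(b: SpinOrbitalBlocks):
    """Exact-denominator MP2 energy and per-occupied partition (doubles
    plus the non-Brillouin singles of a restricted open-shell reference)."""
    D1 = b.eps_o[:, None] - b.eps_v[None, :]
    D2 = (b.eps_o[:, None, None, None] + b.eps_o[None, :, None, None]
          - b.eps_v[None, None, :, None] - b.eps_v[None, None, None, :])
    t2 = b.oovv / D2
    t1 = b.f_ov / D1
    part = (0.125 * _einsum("ijab,ijab->i", b.oovv, t2)
            + 0.125 * _einsum("ijab,ijab->j", b.oovv, t2)
            + _einsum("ia,ia->i", b.f_ov, t1))
    return float(part.sum()), part


def _oracle_ccsd(b: SpinOrbitalBlocks, conv_tol=1e-9, max_iter=120):
    """Independently coded spin-orbital CCSD iteration (oracle route)."""
    e = _einsum
    D1 = b.eps_o[:, None] - b.eps_v[None, :]
    D2 = (b.eps_o[:, None, None, None] + b.eps_o[None, :, None, None]
          - b.eps_v[None, None, :, None] - b.eps_v[None, None, None, :])
    foo_od = b.f_oo - np.diag(np.diag(b.f_oo))
    fvv_od = b.f_vv - np.diag(np.diag(b.f_vv))
    mbej = -b.ovov.swapaxes(2, 3)
    t1 = b.f_ov / D1
    t2 = b.oovv / D2
    diis = _AmplitudeDIIS(8)
    history = []
    for it in range(1, max_iter + 1):
        tt = e("ia,jb->ijab", t1, t1)
        tau = t2 + tt - tt.swapaxes(2, 3)
        taut = t2 + 0.5 * (tt - tt.swapaxes(2, 3))

        fae = (fvv_od - 0.5 * e("me,ma->ae", b.f_ov, t1)
               + e("mf,mafe->ae", t1, b.ovvv)
               - 0.5 * e("mnaf,mnef->ae", taut, b.oovv, optimize=True))
        fmi = (foo_od + 0.5 * e("ie,me->mi", t1, b.f_ov)
               + e("ne,mnie->mi", t1, b.ooov)
               + 0.5 * e("inef,mnef->mi", taut, b.oovv, optimize=True))
        fme = b.f_ov + e("nf,mnef->me", t1, b.oovv)

        r1 = (b.f_ov
              + e("ie,ae->ia", t1, fae)
              - e("ma,mi->ia", t1, fmi)
              + e("imae,me->ia", t2, fme)
              - e("nf,naif->ia", t1, b.ovov)
              - 0.5 * e("imef,maef->ia", t2, b.ovvv, optimize=True)
              + 0.5 * e("mnae,nmie->ia", t2, b.ooov, optimize=True))

        wmnij = (b.oooo
                 + e("je,mnie->mnij", t1, b.ooov)
                 - e("ie,mnje->mnij", t1, b.ooov)
                 + 0.25 * e("ijef,mnef->mnij", tau, b.oovv, optimize=True))
        wabef = (b.vvvv
                 + e("mb,maef->abef", t1, b.ovvv)
                 - e("ma,mbef->abef", t1, b.ovvv)
                 + 0.25 * e("mnab,mnef->abef", tau, b.oovv, optimize=True))
        wmbej = (mbej
                 + e("jf,mbef->mbej", t1, b.ovvv)
                 + e("nb,mnje->mbej", t1, b.ooov)
                 - e("jnfb,mnef->mbej", 0.5 * t2 + e("jf,nb->jnfb", t1, t1),
                     b.oovv, optimize=True))

        r2 = b.oovv.copy()
        x = e("ijae,be->ijab", t2, fae - 0.5 * e("mb,me->be", t1, fme))
        r2 += x - x.swapaxes(2, 3)
        x = e("imab,mj->ijab", t2, fmi + 0.5 * e("je,me->mj", t1, fme))
        r2 -= x - x.swapaxes(0, 1)
        r2 += 0.5 * e("mnab,mnij->ijab", tau, wmnij, optimize=True)
        r2 += 0.5 * e("ijef,abef->ijab", tau, wabef, optimize=True)
        x = (e("imae,mbej->ijab", t2, wmbej, optimize=True)
             - e("ie,ma,mbej->ijab", t1, t1, mbej, optimize=True))
        x = x - x.swapaxes(0, 1)
        r2 += x - x.swapaxes(2, 3)
        x = -e("ie,jeab->ijab", t1, b.ovvv)
        r2 += x - x.swapaxes(0, 1)
        x = -e("ma,ijmb->ijab", t1, b.ooov)
        r2 += x - x.swapaxes(2, 3)

        res1, res2 = r1 - t1 * D1, r2 - t2 * D2
        rnorm = max(np.abs(res1).max(), np.abs(res2).max())
        history.append(rnorm)
        if rnorm < conv_tol:
            return t1, t2, it, history
        vec = diis.update(np.concatenate([(r1 / D1).ravel(),
                                          (r2 / D2).ravel()]),
                          np.concatenate([(res1 / D1).ravel(),
                                          (res2 / D2).ravel()]))
        t1 = vec[:t1.size].reshape(t1.shape)
        t2 = vec[t1.size:].reshape(t2.shape)
    raise CCSDConvergenceError("oracle CCSD not converged", history)


def ccsd_energy_and_partition(b, t1, t2):
    tt = _einsum("ia,jb->ijab", t1, t1)
    tau = t2 + tt - tt.swapaxes(2, 3)
    part = (_einsum("ia,ia->i", b.f_ov, t1)
            + 0.125 * _einsum("ijab,ijab->i", b.oovv, tau)
            + 0.125 * _einsum("ijab,ijab->j", b.oovv, tau))
    return float(part.sum()), part


def canonical_ccsdt_oracle(ref: ReferenceState, df: DFTensors | None = None,
                           level: str = "ccsd(t)",
                           conv_tol: float = 1e-9) -> OracleResult:
    """Canonical DF-CCSD(T) (or MP2/CCSD) with explicit denominators."""
    if df is None:
        df = DFTensors(ref.basis, ref.aux)
    b = canonical_blocks(ref, df)
    e2, p2 = oracle_mp2(b)
    if level == "mp2":
        return OracleResult("mp2", ref.scf_energy, e2, mp2_partition=p2)
    t1, t2, _, _ = _oracle_ccsd(b, conv_tol=conv_tol)
    ecc, pcc = ccsd_energy_and_partition(b, t1, t2)
    if level == "ccsd":
        return OracleResult("ccsd", ref.scf_energy, e2, ecc,
                            mp2_partition=p2, ccsd_partition=pcc)
    et, pt = triples_energy_explicit(b, t1, t2, partition=True)
    return OracleResult("ccsd(t)", ref.scf_energy, e2, ecc, et,
                        mp2_partition=p2, ccsd_partition=pcc, t_partition=pt)
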