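"""Spin-orbital CCSD with a general (non-diagonal) Fock matrix.

Solves the CCSD amplitude equations over a spin-orbital block container
using the standard one/two-particle intermediates, DIIS acceleration and
semicanonical denominators.  The occupied-virtual Fock block, generally
nonzero for ROHF-derived semicanonical references, enters the residuals
in full.

The correlation energy is partitioned exactly over occupied orbitals;
projecting the partition index onto the central LMO of a domain gives
that domain's CCSD energy contribution.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from functools import partial

_einsum = partial(np.einsum, optimize=True)

from .blocked import SpinLayout, blocked_einsum
from .spinorb import SpinOrbitalBlocks


class CCSDConvergenceError(RuntimeError):
    def __init__(self, msg, residuals):
        super().__init__(msg + f" (residual history tail: {residuals[-5:]})")
        self.residuals = residuals


@dataclasses.dataclass
class CCAmplitudes:
    t1: np.ndarray
    t2: np.ndarray
    energy: float                 # total CCSD correlation energy of the block
    iterations: int
    residual_norms: list


class _AmplitudeDIIS:
    def __init__(self, size=6):
        self.size = size
        self.vecs, self.errs = [], []

    def update(self, vec, err):
        self.vecs.append(vec)
        self.errs.append(err)
        if len(self.vecs) > self.size:
            self.vecs.pop(0)
            self.errs.pop(0)
        n = len(self.vecs)
        if n < 2:
            return vec
        B = np.empty((n + 1, n + 1))
        B[:n, :n] = np.array([[e1 @ e2 for e2 in self.errs]
                              for e1 in self.errs])
        B[n, :n] = B[:n, n] = -1.0
        B[n, n] = 0.0
        rhs = np.zeros(n + 1)
        rhs[n] = -1.0
        try:
            c = np.linalg.solve(B, rhs)[:n]
        except np.linalg.LinAlgError:
            return vec
        return sum(ci * vi for ci, vi in zip(c, self.vecs))


def ccsd_energy_expression(b: SpinOrbitalBlocks, t1, t2) -> float:
    t1t1 = _einsum("ia,jb->ijab", t1, t1)
    tau = t2 + t1t1 - t1t1.swapaxes(2, 3)
    return float(np.sum(b.f_ov * t1)
                 + 0.25 * _einsum("ijab,ijab->", b.oovv, tau))


def _rhs(b: SpinOrbitalBlocks, t1, t2):
    """RHS(t) of the amplitude equations: t D = RHS at the solution."""
    e = _einsum
    lay = SpinLayout(int((b.spin_o == 1).sum()), b.no,
                     int((b.spin_v == 1).sum()), b.nv)

    def bes(expr, ops, axt, scale=1.0, out=None):
        return blocked_einsum(expr, ops, axt, lay, out=out, scale=scale)
    ovvo = -b.ovov.swapaxes(2, 3)                 # <mb||ej>
    t1t1 = e("ia,jb->ijab", t1, t1)
    tau_t = t2 + 0.5 * (t1t1 - t1t1.swapaxes(2, 3))
    tau = t2 + t1t1 - t1t1.swapaxes(2, 3)

    Fae = (b.f_vv - np.diag(np.diag(b.f_vv))
           - 0.5 * e("me,ma->ae", b.f_ov, t1)
           + e("mf,mafe->ae", t1, b.ovvv))
    bes("mnaf,mnef->ae", [tau_t, b.oovv], ["oovv", "oovv", "vv"],
        scale=-0.5, out=Fae)
    Fmi = (b.f_oo - np.diag(np.diag(b.f_oo))
           + 0.5 * e("ie,me->mi", t1, b.f_ov)
           + e("ne,mnie->mi", t1, b.ooov))
    bes("inef,mnef->mi", [tau_t, b.oovv], ["oovv", "oovv", "oo"],
        scale=0.5, out=Fmi)
    Fme = b.f_ov + e("nf,mnef->me", t1, b.oovv)

    tmp = e("je,mnie->mnij", t1, b.ooov)
    Wmnij = b.oooo + tmp - tmp.swapaxes(2, 3)
    bes("ijef,mnef->mnij", [tau, b.oovv], ["oovv", "oovv", "oooo"],
        scale=0.25, out=Wmnij)
    tmp = e("mb,maef->abef", t1, b.ovvv)
    Wabef = b.vvvv + tmp - tmp.swapaxes(0, 1)
    bes("mnab,mnef->abef", [tau, b.oovv], ["oovv", "oovv", "vvvv"],
        scale=0.25, out=Wabef)
    Wmbej = (ovvo
             + e("jf,mbef->mbej", t1, b.ovvv)
             + e("nb,mnje->mbej", t1, b.ooov))
    bes("jnfb,mnef->mbej", [0.5 * t2 + e("jf,nb->jnfb", t1, t1), b.oovv],
        ["oovv", "oovv", "ovvo"], scale=-1.0, out=Wmbej)

    r1 = (b.f_ov
          + e("ie,ae->ia", t1, Fae)
          - e("ma,mi->ia", t1, Fmi)
          + e("imae,me->ia", t2, Fme)
          - e("nf,naif->ia", t1, b.ovov)
          - 0.5 * e("imef,maef->ia", t2, b.ovvv)
          + 0.5 * e("mnae,nmie->ia", t2, b.ooov))

    Fbe_h = Fae - 0.5 * e("mb,me->be", t1, Fme)
    Fmj_h = Fmi + 0.5 * e("je,me->mj", t1, Fme)
    r2 = b.oovv.copy()
    tmp = e("ijae,be->ijab", t2, Fbe_h)
    r2 += tmp - tmp.swapaxes(2, 3)
    tmp = e("imab,mj->ijab", t2, Fmj_h)
    r2 -= tmp - tmp.swapaxes(0, 1)
    bes("mnab,mnij->ijab", [tau, Wmnij], ["oovv", "oooo", "oovv"],
        scale=0.5, out=r2)
    bes("ijef,abef->ijab", [tau, Wabef], ["oovv", "vvvv", "oovv"],
        scale=0.5, out=r2)
    tmp = bes("imae,mbej->ijab", [t2, Wmbej], ["oovv", "ovvo", "oovv"])
    tmp -= e("ie,ma,mbej->ijab", t1, t1, ovvo, optimize=True)
    tmp = tmp - tmp.swapaxes(0, 1)
    r2 += tmp - tmp.swapaxes(2, 3)
    # + P_(ij) sum_e t_i^e <ab||ej>, with <ab||ej> = -<je||ab>
    tmp = -e("ie,jeab->ijab", t1, b.ovvv)
    r2 += tmp - tmp.swapaxes(0, 1)
    # - P_(ab) sum_m t_m^a <mb||ij>, with <mb||ij> = <ij||mb>
    tmp = -e("ma,ijmb->ijab", t1, b.ooov)
    r2 += tmp - tmp.swapaxes(2, 3)
    return r1, r2


def solve_ccsd(blocks: SpinOrbitalBlocks, conv_tol: float = 1e-8,
               max_iter: int = 100, diis_size: int = 6) -> CCAmplitudes:
    """Iterate the spin-orbital CCSD equations to convergence."""
    b = blocks
    if b.no == 0 or b.nv == 0:
        return CCAmplitudes(np.zeros((b.no, b.nv)),
                            np.zeros((b.no, b.no, b.nv, b.nv)), 0.0, 0, [])
    D1 = b.eps_o[:, None] - b.eps_v[None, :]
    D2 = (b.eps_o[:, None, None, None] + b.eps_o[None, :, None, None]
          - b.eps_v[None, None, :, None] - b.eps_v[None, None, None, :])
    t1 = b.f_ov / D1
    t2 = b.oovv / D2
    diis = _AmplitudeDIIS(diis_size)
    resids = []
    for it in range(1, max_iter + 1):
        r1, r2 = _rhs(b, t1, t2)
        res1 = r1 - t1 * D1
        res2 = r2 - t2 * D2
        rnorm = max(np.abs(res1).max() if res1.size else 0.0,
                    np.abs(res2).max() if res2.size else 0.0)
        resids.append(rnorm)
        if rnorm < conv_tol:
            return CCAmplitudes(t1, t2, ccsd_energy_expression(b, t1, t2),
                                it, resids)
        vec = diis.update(np.concatenate([(r1 / D1).ravel(),
                                          (r2 / D2).ravel()]),
                          np.concatenate([(res1 / D1).ravel(),
                                          (res2 / D2).ravel()]))
        t1 = vec[:t1.size].reshape(t1.shape)
        t2 = vec[t1.size:].reshape(t2.shape)
    raise CCSDConvergenceError(
        f"CCSD not converged in {max_iter} iterations", resids)


def ccsd_contribution(b: SpinOrbitalBlocks, amps: CCAmplitudes,
                      proj: np.ndarray) -> float:
    """CCSD correlation energy contribution of the occupied projector.

    `proj` is either a vector u over occupied spin orbitals (rank-one
    projector u u^T) or a full (no, no) projector matrix.  Summing the
    contributions over a resolution of the identity recovers the total
    CCSD energy exactly.
    """
    if proj.ndim == 1:
        P = np.outer(proj, proj)
    else:
        P = proj
    t1, t2 = amps.t1, amps.t2
    t1t1 = _einsum("ia,jb->ijab", t1, t1)
    tau = t2 + t1t1 - t1t1.swapaxes(2, 3)
    e = float(_einsum("ik,ia,ka->", P, b.f_ov, t1))
    e += 0.25 * float(_einsum("ik,ijab,kjab->", P, b.oovv, tau,
                                optimize=True))
    return e
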