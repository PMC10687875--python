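"""Perturbative triples corrections in spin orbitals.

Two routes to (T):

* :func:`triples_energy_explicit` — brute force with explicit triples
  denominators, batched over one occupied index (the oracle route; also
  yields an exact per-occupied-orbital partition).
* :func:`triples_contribution_laplace` — the Laplace-transform route: the
  denominator 1/D is replaced by a quadrature sum of exponentials whose
  single-orbital factors are absorbed into the tensors entering the
  triples amplitudes, so the amplitudes with one occupied index projected
  onto a central orbital can be formed directly, without the other
  occupied indices' amplitudes ever existing.

Both evaluate E(T) = (1/36) sum W (W + V) / D with
W = P(i/jk) P(a/bc) [ sum_e t_jk^ae <ei||bc> - sum_m t_im^bc <ma||jk> ]
and V = P(i/jk) P(a/bc) t_i^a <jk||bc>, using CCSD-converged amplitudes.
"""
from __future__ import annotations

import numpy as np
from functools import partial

_einsum = partial(np.einsum, optimize=True)

from .blocked import SpinLayout, blocked_einsum
from .laplace import LaplaceQuadrature
from .spinorb import SpinOrbitalBlocks


def _layout(b: SpinOrbitalBlocks) -> SpinLayout:
    return SpinLayout(int((b.spin_o == 1).sum()), b.no,
                      int((b.spin_v == 1).sum()), b.nv)


def _pabc(t):
    """Apply P(a/bc) over the last three (virtual) axes of (..., a, b, c)."""
    return (t - np.swapaxes(t, -3, -2) - np.swapaxes(t, -3, -1))


def _w_v_batch(b, t1, t2, i, j):
    """W and V slices over (k, a, b, c) for fixed occupied (i, j)."""
    e = _einsum
    lay = _layout(b)
    bes = blocked_einsum
    # A(s1,s2,s3) = -sum_e t2[s2,s3,a,e] <s1 e||bc> - sum_m t2[s1,m,b,c]
    #               <s2 s3||m a>;  <ie||bc> stored as ovvv, <jk||ma> as ooov
    # W(ijk) = A(ijk) - A(jik) - A(kji), free k in the third slot
    A = bes("kae,ebc->kabc", [t2[j], b.ovvv[i]], ["ovv", "vvv", "ovvv"],
            lay, scale=-1.0)
    bes("mbc,kma->kabc", [t2[i], b.ooov[j]], ["ovv", "oov", "ovvv"],
        lay, out=A, scale=-1.0)
    bes("kae,ebc->kabc", [t2[i], b.ovvv[j]], ["ovv", "vvv", "ovvv"],
        lay, out=A, scale=+1.0)
    bes("mbc,kma->kabc", [t2[j], b.ooov[i]], ["ovv", "oov", "ovvv"],
        lay, out=A, scale=+1.0)
    bes("ae,kebc->kabc", [t2[j, i], b.ovvv], ["vv", "ovvv", "ovvv"],
        lay, out=A, scale=+1.0)
    bes("kmbc,ma->kabc", [t2, b.ooov[j, i]], ["oovv", "ov", "ovvv"],
        lay, out=A, scale=+1.0)
    W = _pabc(A)
    V1 = e("a,kbc->kabc", t1[i], b.oovv[j])
    V2 = e("a,kbc->kabc", t1[j], b.oovv[i])
    V3 = e("ka,bc->kabc", t1, b.oovv[j, i])
    V = _pabc(V1 - V2 - V3)
    return W, V


def triples_energy_explicit(b: SpinOrbitalBlocks, t1, t2,
                            partition: bool = False):
    """(T) with explicit denominators; optionally the exact per-occupied
    partition (equal attribution over the three occupied indices of each
    fully symmetric summand)."""
    no = b.no
    eo, ev = b.eps_o, b.eps_v
    Dv = (-ev[:, None, None] - ev[None, :, None] - ev[None, None, :])
    energy = 0.0
    part = np.zeros(no)
    for i in range(no):
        for j in range(i + 1, no):
            W, V = _w_v_batch(b, t1, t2, i, j)
            D = (eo[i] + eo[j] + eo[:, None, None, None]
                 + Dv[None, :, :, :])
            s_k = _einsum("kabc,kabc->k", W, (W + V) / D)
            contrib = (2.0 / 36.0) * s_k
            energy += float(contrib.sum())
            if partition:
                part[i] += contrib.sum() / 3.0
                part[j] += contrib.sum() / 3.0
                part += contrib / 3.0
    return (energy, part) if partition else energy


def triples_contribution_explicit(b: SpinOrbitalBlocks, t1, t2,
                                  u_central: np.ndarray) -> float:
    """(T) contribution of a central orbital with explicit denominators.

    Used when the Laplace quadrature is disabled (exact-denominator
    runs); summing over a complete set of projectors reproduces
    :func:`triples_energy_explicit` exactly.
    """
    no = b.no
    eo, ev = b.eps_o, b.eps_v
    Dv = (-ev[:, None, None] - ev[None, :, None] - ev[None, None, :])
    total = 0.0
    for j in range(no):
        T3c = None
        WVc = None
        for i in range(no):
            if abs(u_central[i]) < 1e-14 and T3c is not None:
                continue
            W, V = _w_v_batch(b, t1, t2, i, j)
            D = eo[i] + eo[j] + eo[:, None, None, None] + Dv[None]
            if T3c is None:
                T3c = u_central[i] * W / D
                WVc = u_central[i] * (W + V)
            else:
                T3c += u_central[i] * W / D
                WVc += u_central[i] * (W + V)
        total += float(np.sum(T3c * WVc)) / 36.0
    return total


def triples_contribution_laplace(b: SpinOrbitalBlocks, t1, t2,
                                 quad: LaplaceQuadrature,
                                 u_central: np.ndarray) -> float:
    """(T) energy contribution of one central orbital via Laplace."""
    return triples_contributions_laplace(b, t1, t2, quad, [u_central])[0]


def triples_contributions_laplace(b: SpinOrbitalBlocks, t1, t2,
                                  quad: LaplaceQuadrature,
                                  projectors: list) -> list:
    """(T) energy contributions of central projectors via Laplace.

    The denominator exponentials split into three factors: a dressing of
    the central (projected) index, a dressing of the remaining external
    indices, and nothing on internal summation indices.  The first is
    absorbed into per-quadrature-point central weight vectors, the second
    is applied elementwise after assembly, so the six tensor contractions
    building the triples amplitudes run once over the *undressed* shared
    t2/integral tensors with all quadrature points (and all projectors)
    fused into one small leading axis -- pure matrix multiplications.
    Summed over a complete set of projectors this reproduces the
    explicit-denominator (T) up to the quadrature error.
    """
    no, nv = b.no, b.nv
    if no == 0 or nv == 0:
        return [0.0] * len(projectors)
    eo, ev = b.eps_o, b.eps_v
    nq = quad.n
    ohs = [np.ones(no)] + [np.exp(eo * t) for t in quad.points]
    # weight rows: for each projector, [undressed, point 1, ..., point nq]
    U = np.vstack([u * oh for u in projectors for oh in ohs])
    nrow = 1 + nq
    e = _einsum

    pv = e("wi,iebc->webc", U, b.ovvv)
    pt2 = e("wi,imbc->wmbc", U, t2)
    q1 = e("wi,ikae->wkae", U, t2)
    po = e("wi,ikma->wkma", U, b.ooov)
    t1p = U @ t1

    totals = [0.0] * len(projectors)
    for j in range(no):
        r1 = e("wi,iae->wae", U, t2[j])
        r2 = e("wi,ima->wma", U, b.ooov[j])
        A = e("kae,webc->wkabc", t2[j], -pv, optimize=True)
        A -= e("wmbc,kma->wkabc", pt2, b.ooov[j], optimize=True)
        A += e("wkae,ebc->wkabc", q1, b.ovvv[j], optimize=True)
        A += e("mbc,wkma->wkabc", t2[j], po, optimize=True)
        A += e("wae,kebc->wkabc", r1, b.ovvv, optimize=True)
        A += e("kmbc,wma->wkabc", t2, r2, optimize=True)
        # undressed V (needed once per projector, at its w0 row);
        # the dressed rows of A are contracted *without* applying
        # P(a/bc): for fully antisymmetric X, <P(a/bc) A, X> = 3 <A, X>,
        # and the external dressing is symmetric in (a, b, c)
        for iu in range(len(projectors)):
            w0 = iu * nrow
            V = (e("a,kbc->kabc", t1p[w0], b.oovv[j])
                 - e("ka,bc->kabc", t1,
                     e("i,ibc->bc", U[w0], b.oovv[j]))
                 - e("a,kbc->kabc", t1[j],
                     e("i,ikbc->kbc", U[w0], b.oovv)))
            WV0 = _pabc(A[w0] + V)
            for q in range(nq):
                vh = np.exp(-ev * quad.points[q])
                val = e("kabc,k,a,b,c->", A[w0 + 1 + q] * WV0,
                        ohs[1 + q], vh, vh, vh, optimize=True)
                # D < 0 for triples: 1/D = -sum_q w_q exp(+D t_q)
                totals[iu] -= (3.0 * quad.weights[q] / 36.0
                               * ohs[1 + q][j] * float(val))
    return totals
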