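"""Tiny determinant-based full CI, used as an independent oracle.

Spatial-orbital one- and two-electron integrals in, ground-state energy
out, by explicit enumeration of all determinants and Slater-Condon
rules.  Only suitable for a handful of electrons/orbitals.
"""
from itertools import combinations

import numpy as np


def _excitation(d1, d2):
    """Spin orbitals removed from d1 and added in d2."""
    return sorted(set(d1) - set(d2)), sorted(set(d2) - set(d1))


def fci_ground_state(h, eri, n_alpha, n_beta):
    """Ground-state electronic energy (no nuclear repulsion included).

    h: (n, n) spatial core Hamiltonian; eri: (n, n, n, n) chemist-notation
    spatial ERIs (pq|rs).
    """
    n = h.shape[0]
    # spin orbitals: 2p = alpha_p, 2p+1 = beta_p
    def sp(p):
        return p // 2

    def spin(p):
        return p % 2

    def h1(p, q):
        return h[sp(p), sp(q)] if spin(p) == spin(q) else 0.0

    def g(p, q, r, s):
        # <pq||rs> antisymmetrized physicist integrals over spin orbitals
        d1 = eri[sp(p), sp(r), sp(q), sp(s)] \
            if (spin(p) == spin(r) and spin(q) == spin(s)) else 0.0
        d2 = eri[sp(p), sp(s), sp(q), sp(r)] \
            if (spin(p) == spin(s) and spin(q) == spin(r)) else 0.0
        return d1 - d2

    alphas = [tuple(2 * p for p in c)
              for c in combinations(range(n), n_alpha)]
    betas = [tuple(2 * p + 1 for p in c)
             for c in combinations(range(n), n_beta)]
    dets = [tuple(sorted(a + b)) for a in alphas for b in betas]
    ndet = len(dets)
    H = np.zeros((ndet, ndet))
    for I in range(ndet):
        dI = dets[I]
        for J in range(I + 1):
            dJ = dets[J]
            rem, add = _excitation(dI, dJ)
            if len(rem) > 2:
                continue
            if len(rem) == 0:
                val = sum(h1(p, p) for p in dI)
                val += 0.5 * sum(g(p, q, p, q) for p in dI for q in dI)
            elif len(rem) == 1:
                m, p = rem[0], add[0]
                phase = _phase_single(dI, m, p)
                val = phase * (h1(m, p)
                               + sum(g(m, q, p, q) for q in dI if q != m))
            else:
                (m, nn), (p, q) = rem, add
                phase = _phase_double(dI, m, nn, p, q)
                val = phase * g(m, nn, p, q)
            H[I, J] = H[J, I] = val
    return float(np.linalg.eigvalsh(H)[0])


def _phase_single(det, m, p):
    det = list(det)
    i = det.index(m)
    new = sorted(set(det) - {m} | {p})
    j = new.index(p)
    return (-1) ** (i + j)


def _phase_double(det, m, n, p, q):
    s1 = _phase_single(det, m, p)
    mid = tuple(sorted(set(det) - {m} | {p}))
    s2 = _phase_single(mid, n, q)
    return s1 * s2
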