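"""Restricted Boys localization of the occupied space.

The correlated DOMOs and the SOMOs are localized *separately* (the two
subspaces are never mixed), keeping the restricted open-shell structure
of the reference intact.  Localization maximizes the sum of squared
orbital centroids (the Boys objective) by Jacobi 2x2 rotations applied
in deterministic index order from an identity start, so the resulting
LMO set is reproducible bit-for-bit for a given reference.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from . import integrals as ints
from .scf import ReferenceState


@dataclasses.dataclass
class LMOSet:
    lmo_coefficients: np.ndarray     # AO x LMO
    occupation: np.ndarray           # 2 for DOMO-origin, 1 for SOMO-origin
    origin: list                     # "domo" | "somo" per LMO
    centroids: np.ndarray            # (nlmo, 3), bohr

    @property
    def n(self) -> int:
        return self.lmo_coefficients.shape[1]

    @property
    def domo_mask(self) -> np.ndarray:
        return np.array([o == "domo" for o in self.origin])

    @property
    def somo_mask(self) -> np.ndarray:
        return np.array([o == "somo" for o in self.origin])


class LocalizationError(RuntimeError):
    pass


def _cholesky_start(coeff: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Deterministic localized starting guess: full-pivoted Cholesky of the
    subspace density matrix, Loewdin-orthonormalized.

    A plain identity (canonical) start can leave Jacobi sweeps trapped at
    pairwise-stationary saddle points on symmetric chains; the Cholesky
    orbitals are already atom-centered and break those symmetries while
    remaining fully deterministic.
    """
    import scipy.linalg as sla
    D = coeff @ coeff.T
    c, piv, rank, _ = sla.lapack.dpstrf(D, lower=1)
    n = coeff.shape[1]
    L = np.tril(c)[:, :n]
    P = np.zeros_like(D)
    P[piv - 1, np.arange(len(piv))] = 1.0
    cand = P @ L
    g = cand.T @ S @ cand
    w, v = np.linalg.eigh(g)
    if w.min() < 1e-10:
        return coeff            # fall back to the canonical start
    return cand @ (v / np.sqrt(w)) @ v.T


def boys_objective(coeff: np.ndarray, dip: list[np.ndarray]) -> float:
    """Sum of squared orbital centroids for the given orbitals."""
    val = 0.0
    for d in dip:
        val += float(np.sum(np.diag(coeff.T @ d @ coeff) ** 2))
    return val


def _boys_jacobi(coeff: np.ndarray, dip: list[np.ndarray],
                 grad_tol: float = 1e-8, max_sweeps: int = 300) -> np.ndarray:
    """Jacobi sweeps maximizing the Boys objective; returns rotated orbitals."""
    C = coeff.copy()
    n = C.shape[1]
    if n < 2:
        return C
    d = [C.T @ m @ C for m in dip]        # dipole matrices in the orbital basis
    for sweep in range(max_sweeps):
        gmax = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                A = B = 0.0
                for m in d:
                    dij, dii, djj = m[i, j], m[i, i], m[j, j]
                    A += dij * dij - 0.25 * (dii - djj) ** 2
                    B += dij * (dii - djj)
                gmax = max(gmax, abs(B))
                if A * A + B * B < 1e-24:
                    continue
                gamma = 0.25 * np.arctan2(B, -A)
                if abs(gamma) < 1e-13:
                    continue
                c, s = np.cos(gamma), np.sin(gamma)
                for m in d:
                    mi, mj = m[:, i].copy(), m[:, j].copy()
                    m[:, i] = c * mi + s * mj
                    m[:, j] = -s * mi + c * mj
                    ri, rj = m[i, :].copy(), m[j, :].copy()
                    m[i, :] = c * ri + s * rj
                    m[j, :] = -s * ri + c * rj
                ci, cj = C[:, i].copy(), C[:, j].copy()
                C[:, i] = c * ci + s * cj
                C[:, j] = -s * ci + c * cj
        if gmax < grad_tol:
            return C
    raise LocalizationError(
        f"Boys localization not converged in {max_sweeps} sweeps "
        f"(final gradient {gmax:.3e})")


def _fix_phase_and_order(C: np.ndarray, dip: list[np.ndarray]) -> np.ndarray:
    """Largest-|coefficient| AO component positive; centroid-sorted columns."""
    C = C.copy()
    for k in range(C.shape[1]):
        imax = int(np.argmax(np.abs(C[:, k])))
        if C[imax, k] < 0:
            C[:, k] = -C[:, k]
    cent = np.stack([np.diag(C.T @ m @ C) for m in dip], axis=1)
    key = np.round(cent, 6)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    return C[:, order]


def localize_boys_restricted(ref: ReferenceState,
                             grad_tol: float = 1e-8) -> LMOSet:
    """Boys-localize the correlated DOMOs and the SOMOs, separately.

    Frozen-core orbitals are excluded from localization and from the LMO
    set; they remain canonical and frozen downstream.
    """
    dip_dict = ints.multipole(ref.basis, order=1)
    dip = [dip_dict[(1, 0, 0)], dip_dict[(0, 1, 0)], dip_dict[(0, 0, 1)]]
    blocks, occs, orig = [], [], []
    dom = ref.correlated_domo_indices
    if len(dom):
        C0 = _cholesky_start(ref.mo_coeff[:, dom], ref.overlap)
        C = _boys_jacobi(C0, dip, grad_tol)
        blocks.append(_fix_phase_and_order(C, dip))
        occs += [2] * len(dom)
        orig += ["domo"] * len(dom)
    if len(ref.somo_indices):
        C = _boys_jacobi(ref.mo_coeff[:, ref.somo_indices], dip, grad_tol)
        blocks.append(_fix_phase_and_order(C, dip))
        occs += [1] * len(ref.somo_indices)
        orig += ["somo"] * len(ref.somo_indices)
    coeff = np.hstack(blocks) if blocks else np.zeros((ref.nao, 0))
    cent = np.stack([np.diag(coeff.T @ m @ coeff) for m in dip], axis=1) \
        if coeff.shape[1] else np.zeros((0, 3))
    return LMOSet(coeff, np.array(occs), orig, cent)
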