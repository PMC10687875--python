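"""Local natural orbitals from MP1 density-matrix fragments.

The occupied-occupied and virtual-virtual blocks of the second-order
(MP1) density matrix restricted to the amplitudes of one central LMO are
built per spin in the semicanonical ED bases, transformed to the
restricted occupied / restricted PAO bases, and spin-summed.  Before
diagonalization the central LMO's row and column and all SOMO couplings
are zeroed, so the central LMO and the SOMOs survive the truncation
unchanged; domains with a singly occupied central carry a factor 2 on
the density (selection only — energies are never scaled) to put SO and
DO domains on the same occupation-number scale.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from functools import partial

_einsum = partial(np.einsum, optimize=True)

from .eddomain import ExtendedDomain


@dataclasses.dataclass
class DensityFragment:
    block: str                    # "occupied" | "virtual"
    matrix: np.ndarray            # restricted basis, coupling blocks zeroed
    raw_matrix: np.ndarray        # before zeroing (diagnostics)
    scale: float


@dataclasses.dataclass
class LNOBasis:
    occ_vectors: np.ndarray       # restricted-occ coords, n_occ x n_kept_occ
    occ_occupations: np.ndarray   # occupation numbers of kept DOMO-LNOs
    occ_spectrum: np.ndarray      # full occupied occupation spectrum
    virt_vectors: np.ndarray      # restricted-PAO coords, n_vp x n_kept_virt
    virt_occupations: np.ndarray
    virt_spectrum: np.ndarray
    eps_o: float
    eps_v: float
    n_somo: int                   # SOMOs (kept unconditionally, lead cols)

    @property
    def n_occ(self) -> int:
        return self.occ_vectors.shape[1]

    @property
    def n_virt(self) -> int:
        return self.virt_vectors.shape[1]

    def spectra_frame(self):
        """Occupation spectra (kept and discarded) as a tidy table."""
        import pandas as pd
        rows = [{"block": "occupied", "occupation": float(x),
                 "kept": x >= self.eps_o - 1e-12}
                for x in self.occ_spectrum]
        rows += [{"block": "virtual", "occupation": float(x),
                  "kept": x >= self.eps_v - 1e-12}
                 for x in self.virt_spectrum]
        return pd.DataFrame(rows)


class DegenerateDomainError(RuntimeError):
    def __init__(self, msg, spectrum):
        super().__init__(msg + f"; occupation spectrum {spectrum}")
        self.spectrum = spectrum


def _spin_cases(ed: ExtendedDomain):
    spins_c = ("up",) if ed.central_is_somo else ("up", "down")
    return [(sc, so) for sc in spins_c for so in ("up", "down")]


def occupied_density_fragment(ed: ExtendedDomain,
                              amplitudes: dict) -> DensityFragment:
    """Spin-summed occupied-occupied MP1 density fragment of the central
    LMO in the restricted occupied basis of the ED."""
    n = ed.n_occ
    D = np.zeros((n, n))
    for (sc, so) in _spin_cases(ed):
        t = amplitudes[(sc, so)]
        if sc == so:
            tb = t - t.swapaxes(1, 2)
            d = 0.5 * _einsum("jab,kab->jk", tb, tb, optimize=True)
        else:
            d = _einsum("jab,kab->jk", t, t, optimize=True)
        blk = ed.spin(so)
        U = blk.occ_rot                      # restricted(masked) -> semicanon
        d_restr = U @ d @ U.T
        idx = np.where(blk.occ_mask)[0]
        D[np.ix_(idx, idx)] += d_restr
    raw = D.copy()
    scale = 2.0 if ed.central_is_somo else 1.0
    D = D * scale
    # zero the central row/column and all SOMO-DOMO couplings
    D[0, :] = D[:, 0] = 0.0
    for p in np.where(ed.somo_flags)[0]:
        D[p, :] = D[:, p] = 0.0
    return DensityFragment("occupied", D, raw, scale)


def select_occupied_lnos(ed: ExtendedDomain, frag: DensityFragment,
                         eps_o: float) -> tuple:
    """Kept occupied set: central, SOMOs, and DOMO-LNOs above eps_o."""
    n = ed.n_occ
    somo_pos = np.where(ed.somo_flags)[0]
    fixed = [0] + [int(p) for p in somo_pos if p != 0]
    free = [p for p in range(n) if p not in fixed]
    vecs = [np.eye(n)[:, p] for p in fixed]
    occs = []
    spectrum = np.zeros(0)
    if free:
        sub = frag.matrix[np.ix_(free, free)]
        w, v = np.linalg.eigh(0.5 * (sub + sub.T))
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        spectrum = w.copy()
        keep = w >= eps_o - 1e-12
        for k in np.where(keep)[0]:
            col = np.zeros(n)
            col[free] = v[:, k]
            vecs.append(col)
            occs.append(w[k])
    return np.column_stack(vecs), np.array(occs), spectrum, len(fixed) - 1


def virtual_density_fragment(ed: ExtendedDomain, amplitudes: dict,
                             kept_occ: np.ndarray) -> DensityFragment:
    """Virtual-virtual MP1 density fragment, with the free occupied index
    transformed to the retained occupied LNOs first (spin-balanced form:
    both virtual indices of the mixed-spin amplitudes contribute to their
    respective spin's density)."""
    nv = ed.pao_coeff.shape[1]
    D = np.zeros((nv, nv))
    for (sc, so) in _spin_cases(ed):
        t = amplitudes[(sc, so)]
        blk_o = ed.spin(so)
        idx = np.where(blk_o.occ_mask)[0]
        # kept occupied LNOs in the semicanonical basis of spin `so`
        V = blk_o.occ_rot.T @ kept_occ[idx, :]
        tk = _einsum("jm,jab->mab", V, t, optimize=True)
        if sc == so:
            tb = tk - tk.swapaxes(1, 2)
            d = _einsum("mac,mbc->ab", tb, tb, optimize=True)
            D += _to_restricted_pao(ed, sc, d)
        else:
            d_b = _einsum("mab,mac->bc", tk, tk, optimize=True)
            D += _to_restricted_pao(ed, so, d_b)
            d_a = _einsum("mab,mcb->ac", tk, tk, optimize=True)
            D += _to_restricted_pao(ed, sc, d_a)
    raw = D.copy()
    scale = 2.0 if ed.central_is_somo else 1.0
    return DensityFragment("virtual", D * scale, raw, scale)


def _to_restricted_pao(ed, spin, d_semicanonical):
    """Back-transform a semicanonical virtual density block to the
    restricted PAO basis, discarding SOMO (dual-role) couplings."""
    blk = ed.spin(spin)
    W = blk.virt_rot                        # restricted virt -> semicanonical
    d = W @ d_semicanonical @ W.T
    ns = blk.n_somo_virt
    return d[ns:, ns:]


def select_virtual_lnos(ed: ExtendedDomain, frag: DensityFragment,
                        eps_v: float) -> tuple:
    sub = 0.5 * (frag.matrix + frag.matrix.T)
    w, v = np.linalg.eigh(sub)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    keep = w >= eps_v - 1e-12
    if not keep.any():
        raise DegenerateDomainError(
            f"no virtual LNO survives eps_v={eps_v} for LMO {ed.central}",
            w[:10])
    return v[:, keep], w[keep], w


def select_lnos(ed: ExtendedDomain, occ_frag: DensityFragment,
                amplitudes: dict, eps_o: float, eps_v: float) -> LNOBasis:
    """Full LNO selection: occupied first, then virtuals built for the
    retained occupied set."""
    occ_vecs, occ_occ, occ_spec, n_somo = select_occupied_lnos(
        ed, occ_frag, eps_o)
    vir_frag = virtual_density_fragment(ed, amplitudes, occ_vecs)
    vir_vecs, vir_occ, vir_spec = select_virtual_lnos(ed, vir_frag, eps_v)
    return LNOBasis(occ_vecs, occ_occ, occ_spec, vir_vecs, vir_occ,
                    vir_spec, eps_o, eps_v, n_somo)
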