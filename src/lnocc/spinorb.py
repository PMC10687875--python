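"""Spin-orbital containers assembled from per-spin spatial DF blocks.

A :class:`SpinOrbitalBlocks` object carries the Fock blocks and the
antisymmetrized two-electron integrals <pq||rs> over an (occupied,
virtual) spin-orbital partition, built from whitened three-center DF
factors of the two spin channels (which must share one auxiliary basis).
Both the local-subspace CCSD(T) solver and the canonical brute-force
oracle consume this container.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from functools import partial

_einsum = partial(np.einsum, optimize=True)

from .blocked import SpinLayout, blocked_einsum


@dataclasses.dataclass
class SpinOrbitalBlocks:
    eps_o: np.ndarray
    eps_v: np.ndarray
    spin_o: np.ndarray            # +1 for up, -1 for down
    spin_v: np.ndarray
    f_oo: np.ndarray
    f_ov: np.ndarray
    f_vv: np.ndarray
    oooo: np.ndarray              # <ij||kl>
    ooov: np.ndarray              # <ij||ka>
    oovv: np.ndarray              # <ij||ab>
    ovov: np.ndarray              # <ia||jb>
    ovvv: np.ndarray              # <ia||bc>
    vvvv: np.ndarray              # <ab||cd>

    @property
    def no(self) -> int:
        return len(self.eps_o)

    @property
    def nv(self) -> int:
        return len(self.eps_v)


def _stack(b_up, b_dn):
    """Stack per-spin (p, q, X) DF factors block-diagonally in spin."""
    n1u, n2u, nX = b_up.shape
    n1d, n2d, _ = b_dn.shape
    out = np.zeros((n1u + n1d, n2u + n2d, nX))
    out[:n1u, :n2u] = b_up
    out[n1u:, n2u:] = b_dn
    return out


def build_spin_orbital_blocks(b_oo, b_ov, b_vv, f_blocks, eps_o, eps_v,
                              ) -> SpinOrbitalBlocks:
    """Assemble spin-orbital blocks.

    Parameters are dicts keyed "up"/"down": whitened DF factors (occ occ|X),
    (occ vir|X), (vir vir|X); f_blocks[(s, "oo"|"ov"|"vv")] Fock blocks in
    the same bases; eps/eps_v per spin semicanonical energies.
    """
    Boo = _stack(b_oo["up"], b_oo["down"])
    Bov = _stack(b_ov["up"], b_ov["down"])
    Bvv = _stack(b_vv["up"], b_vv["down"])
    nou, nvu = b_ov["up"].shape[0], b_ov["up"].shape[1]

    def block(f_key):
        fu = f_blocks[("up", f_key)]
        fd = f_blocks[("down", f_key)]
        out = np.zeros((fu.shape[0] + fd.shape[0], fu.shape[1] + fd.shape[1]))
        out[:fu.shape[0], :fu.shape[1]] = fu
        out[fu.shape[0]:, fu.shape[1]:] = fd
        return out

    lay = SpinLayout(nou, Boo.shape[0], nvu, Bvv.shape[0])
    lay.cuts["x"] = (Boo.shape[-1], Boo.shape[-1])

    def anti(expr1, ops1, axt1, expr2, ops2, axt2, out_axt):
        out = blocked_einsum(expr1, ops1, axt1, lay)
        return blocked_einsum(expr2, ops2, axt2, lay, out=out, scale=-1.0)

    oooo = anti("ikX,jlX->ijkl", [Boo, Boo], ["oox", "oox", "oooo"],
                "ilX,jkX->ijkl", [Boo, Boo], ["oox", "oox", "oooo"], None)
    ooov = anti("ikX,jaX->ijka", [Boo, Bov], ["oox", "ovx", "ooov"],
                "iaX,jkX->ijka", [Bov, Boo], ["ovx", "oox", "ooov"], None)
    oovv = anti("iaX,jbX->ijab", [Bov, Bov], ["ovx", "ovx", "oovv"],
                "ibX,jaX->ijab", [Bov, Bov], ["ovx", "ovx", "oovv"], None)
    ovov = anti("ijX,abX->iajb", [Boo, Bvv], ["oox", "vvx", "ovov"],
                "ibX,jaX->iajb", [Bov, Bov], ["ovx", "ovx", "ovov"], None)
    ovvv = anti("ibX,acX->iabc", [Bov, Bvv], ["ovx", "vvx", "ovvv"],
                "icX,abX->iabc", [Bov, Bvv], ["ovx", "vvx", "ovvv"], None)
    vvvv = anti("acX,bdX->abcd", [Bvv, Bvv], ["vvx", "vvx", "vvvv"],
                "adX,bcX->abcd", [Bvv, Bvv], ["vvx", "vvx", "vvvv"], None)
    spin_o = np.array([1] * nou + [-1] * (Boo.shape[0] - nou))
    spin_v = np.array([1] * nvu + [-1] * (Bvv.shape[0] - nvu))
    return SpinOrbitalBlocks(
        np.concatenate([eps_o["up"], eps_o["down"]]),
        np.concatenate([eps_v["up"], eps_v["down"]]),
        spin_o, spin_v, block("oo"), block("ov"), block("vv"),
        oooo, ooov, oovv, ovov, ovvv, vvvv)
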