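"""Restricted open-shell reference determinants.

Self-consistent field solvers (RHF as the closed-shell limit of ROHF,
UHF, ROHF with the Roothaan effective Fock) over density-fitted
two-electron integrals, plus quasi-restricted orbitals (QROs) built from
a converged UHF solution.  The product of this module is a
:class:`ReferenceState`: a restricted spatial orbital set partitioned
into DOMOs, SOMOs and virtuals together with the per-spin Fock matrices
of the converged density.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg as sla

from .basis import AOBasis
from .mol import FROZEN_CORE, ELEMENTS, Molecule
from . import integrals as ints


class SCFConvergenceError(RuntimeError):
    def __init__(self, msg, history):
        super().__init__(msg + f" (last energies: {history[-4:]})")
        self.history = history


@dataclasses.dataclass
class ReferenceState:
    """Restricted open-shell reference determinant."""
    mol: Molecule
    basis: AOBasis
    aux: AOBasis
    mo_coeff: np.ndarray          # AO x MO, restricted spatial orbitals
    mo_energy: np.ndarray         # effective (Roothaan/spin-averaged) energies
    domo_indices: np.ndarray
    somo_indices: np.ndarray
    fock_up: np.ndarray           # AO basis
    fock_down: np.ndarray
    overlap: np.ndarray
    hcore: np.ndarray
    scf_energy: float
    frozen_core_indices: np.ndarray
    mode: str = "rohf"

    @property
    def nao(self) -> int:
        return self.basis.nao

    @property
    def n_occ(self) -> int:
        return len(self.domo_indices) + len(self.somo_indices)

    @property
    def occ_indices(self) -> np.ndarray:
        return np.concatenate([self.domo_indices, self.somo_indices])

    @property
    def virtual_indices(self) -> np.ndarray:
        occ = set(self.occ_indices.tolist())
        return np.array([i for i in range(self.mo_coeff.shape[1])
                         if i not in occ], int)

    @property
    def correlated_domo_indices(self) -> np.ndarray:
        fz = set(self.frozen_core_indices.tolist())
        return np.array([i for i in self.domo_indices if i not in fz], int)

    def fock(self, spin: str) -> np.ndarray:
        return self.fock_up if spin == "up" else self.fock_down


class DFTensors:
    """Whole-molecule density-fitting machinery (B such that (pq|rs)=B.B)."""

    def __init__(self, basis: AOBasis, aux: AOBasis):
        self.basis, self.aux = basis, aux
        self.j3c = ints.eri_3c(basis, aux)          # (nao, nao, naux)
        self.metric = ints.eri_2c(aux)
        try:
            self._L = sla.cholesky(self.metric, lower=True)
        except sla.LinAlgError as exc:  # pragma: no cover - degenerate aux
            raise RuntimeError(
                f"auxiliary metric not positive definite for {aux.name}") from exc
        nao, naux = basis.nao, aux.nao
        flat = self.j3c.reshape(nao * nao, naux)
        self.b = sla.solve_triangular(
            self._L, flat.T, lower=True).T.reshape(nao, nao, naux)

    def jk(self, dm: np.ndarray):
        """Coulomb and exchange matrices for one spin density matrix."""
        gamma = np.einsum("mnX,mn->X", self.b, dm)
        J = np.einsum("mnX,X->mn", self.b, gamma)
        half = np.einsum("mlX,ls->msX", self.b, dm)
        K = np.einsum("msX,snX->mn", half, self.b)
        return J, K


def _orthogonalizer(S):
    w, v = np.linalg.eigh(S)
    if w.min() < 1e-9:
        keep = w > 1e-9
        w, v = w[keep], v[:, keep]
    return v / np.sqrt(w)


class _DIIS:
    def __init__(self, size=8):
        self.size = size
        self.focks, self.errs = [], []

    def update(self, fock_vec, err_vec):
        self.focks.append(fock_vec)
        self.errs.append(err_vec)
        if len(self.focks) > self.size:
            self.focks.pop(0)
            self.errs.pop(0)
        n = len(self.focks)
        if n < 2:
            return fock_vec
        B = -np.ones((n + 1, n + 1))
        B[n, n] = 0.0
        for i in range(n):
            for j in range(n):
                B[i, j] = np.dot(self.errs[i], self.errs[j])
        rhs = np.zeros(n + 1)
        rhs[n] = -1.0
        try:
            c = np.linalg.solve(B, rhs)[:n]
        except np.linalg.LinAlgError:
            return fock_vec
        return sum(ci * fi for ci, fi in zip(c, self.focks))


def _roothaan_effective(Fa_mo, Fb_mo, nb, na, nmo):
    """Guest–Saunders effective Fock in the current MO basis."""
    Fc = 0.5 * (Fa_mo + Fb_mo)
    R = Fc.copy()
    c, o, v = slice(0, nb), slice(nb, na), slice(na, nmo)
    R[c, o] = Fb_mo[c, o]
    R[o, c] = Fb_mo[o, c]
    R[o, v] = Fa_mo[o, v]
    R[v, o] = Fa_mo[v, o]
    return R


def _scf_restricted_open(mol, basis, df, conv_tol=1e-10, grad_tol=1e-8,
                         max_iter=200):
    """ROHF (RHF when multiplicity is 1) via the Roothaan effective Fock."""
    S = ints.overlap(basis)
    h = ints.kinetic(basis) + ints.nuclear_attraction(basis)
    X = _orthogonalizer(S)
    na, nb = mol.n_alpha, mol.n_beta
    e, C = np.linalg.eigh(X.T @ h @ X)
    C = X @ C
    nmo = C.shape[1]
    diis = _DIIS(10)
    enuc = mol.nuclear_repulsion()
    e_old, history = np.inf, []
    R_prev = None
    for it in range(max_iter):
        Da = C[:, :na] @ C[:, :na].T
        Db = C[:, :nb] @ C[:, :nb].T
        Ja, Ka = df.jk(Da)
        Jb, Kb = df.jk(Db)
        Fa = h + Ja + Jb - Ka
        Fb = h + Ja + Jb - Kb
        energy = 0.5 * (np.sum(Da * (h + Fa)) + np.sum(Db * (h + Fb))) + enuc
        history.append(energy)
        # effective (Roothaan) Fock as an AO-basis operator; DIIS is run on
        # this operator with its own commutator error, so the extrapolation
        # and the diagonalization update are mutually consistent
        R_mo = _mo_effective(Fa, Fb, C, nb, na, nmo)
        R_ao = S @ C @ R_mo @ C.T @ S
        Dw = 2.0 * Db + (Da - Db)              # occupation-weighted density
        err = X.T @ (R_ao @ Dw @ S - S @ Dw @ R_ao) @ X
        gnorm = np.abs(err).max()
        if abs(energy - e_old) < conv_tol and gnorm < grad_tol and it > 1:
            return C, np.diag(R_mo).copy(), Fa, Fb, energy, S, h, it
        e_old = energy
        if it < 4 and R_prev is not None:      # light early damping
            R_ao = 0.7 * R_ao + 0.3 * R_prev
        R_prev = R_ao
        R_x = diis.update(R_ao.ravel(), err.ravel()).reshape(S.shape)
        w, U = np.linalg.eigh(X.T @ R_x @ X)
        C = X @ U
    raise SCFConvergenceError(f"ROHF not converged in {max_iter} iterations",
                              history)


def _mo_effective(Fa, Fb, C, nb, na, nmo):
    Fa_mo = C.T @ Fa @ C
    Fb_mo = C.T @ Fb @ C
    return _roothaan_effective(Fa_mo, Fb_mo, nb, na, nmo)


def _scf_uhf(mol, basis, df, conv_tol=1e-10, grad_tol=1e-8, max_iter=200):
    S = ints.overlap(basis)
    h = ints.kinetic(basis) + ints.nuclear_attraction(basis)
    X = _orthogonalizer(S)
    na, nb = mol.n_alpha, mol.n_beta
    e, C0 = np.linalg.eigh(X.T @ h @ X)
    Ca = Cb = X @ C0
    diis = _DIIS()
    enuc = mol.nuclear_repulsion()
    e_old, history = np.inf, []
    for it in range(max_iter):
        Da = Ca[:, :na] @ Ca[:, :na].T
        Db = Cb[:, :nb] @ Cb[:, :nb].T
        Ja, Ka = df.jk(Da)
        Jb, Kb = df.jk(Db)
        Fa = h + Ja + Jb - Ka
        Fb = h + Ja + Jb - Kb
        energy = 0.5 * (np.sum(Da * (h + Fa)) + np.sum(Db * (h + Fb))) + enuc
        history.append(energy)
        err = X.T @ (Fa @ Da @ S - S @ Da @ Fa
                     + Fb @ Db @ S - S @ Db @ Fb) @ X
        gnorm = np.abs(err).max()
        fvec = diis.update(np.concatenate([Fa.ravel(), Fb.ravel()]),
                           err.ravel())
        Fa_x = fvec[:S.size].reshape(S.shape)
        Fb_x = fvec[S.size:].reshape(S.shape)
        if abs(energy - e_old) < conv_tol and gnorm < grad_tol and it > 1:
            ea, _ = np.linalg.eigh(X.T @ Fa @ X)
            eb, _ = np.linalg.eigh(X.T @ Fb @ X)
            return Ca, Cb, Fa, Fb, energy, S, h, it
        e_old = energy
        wa, Ua = np.linalg.eigh(X.T @ Fa_x @ X)
        wb, Ub = np.linalg.eigh(X.T @ Fb_x @ X)
        Ca, Cb = X @ Ua, X @ Ub
    raise SCFConvergenceError(f"UHF not converged in {max_iter} iterations",
                              history)


def _quasi_restricted(mol, S, Ca, Cb):
    """QROs: natural orbitals of the total UHF density, aufbau-partitioned."""
    na, nb = mol.n_alpha, mol.n_beta
    D = Ca[:, :na] @ Ca[:, :na].T + Cb[:, :nb] @ Cb[:, :nb].T
    # generalized eigenproblem S D S C = S C n
    X = _orthogonalizer(S)
    n, U = np.linalg.eigh(X.T @ S @ D @ S @ X)
    order = np.argsort(n)[::-1]
    return X @ U[:, order]


def semicanonicalize(orbitals: np.ndarray, fock_ao: np.ndarray,
                     check_overlap: np.ndarray | None = None):
    """Rotate an orthonormal orbital block so it diagonalizes the Fock matrix.

    Returns (rotated orbitals, orbital energies, rotation matrix U) with the
    input-to-output unitary ``U`` (columns: rotated orbitals in the input
    orbital basis).  Raises if the input block is not orthonormal.
    """
    if check_overlap is not None:
        g = orbitals.T @ check_overlap @ orbitals
        if np.abs(g - np.eye(g.shape[0])).max() > 1e-8:
            raise ValueError("orbital block not orthonormal in the AO metric")
    f = orbitals.T @ fock_ao @ orbitals
    eps, U = np.linalg.eigh(0.5 * (f + f.T))
    return orbitals @ U, eps, U


def build_reference(mol: Molecule, basis_name: str = "svdz",
                    mode: str = "rohf", df: DFTensors | None = None,
                    frozen_core: int | None = None,
                    conv_tol: float = 1e-11) -> ReferenceState:
    """Converge the SCF and assemble the restricted open-shell reference.

    mode "rohf" runs a restricted open-shell SCF directly; "uhf_qro" runs
    UHF and constructs quasi-restricted orbitals from the total density.
    In both cases the returned per-spin Fock matrices are rebuilt from the
    *restricted* determinant's density, so they reflect the reference
    actually used downstream.
    """
    basis = AOBasis(mol, basis_name)
    aux = AOBasis(mol, basis_name, aux=True)
    if df is None:
        df = DFTensors(basis, aux)
    na, nb = mol.n_alpha, mol.n_beta
    if mode == "rohf":
        C, mo_e, Fa, Fb, energy, S, h, _ = _scf_restricted_open(
            mol, basis, df, conv_tol=conv_tol)
    elif mode == "uhf_qro":
        Ca, Cb, _, _, _, S, h, _ = _scf_uhf(mol, basis, df, conv_tol=conv_tol)
        C = _quasi_restricted(mol, S, Ca, Cb)
        # rebuild per-spin Fock matrices and the energy from the restricted
        # determinant defined by the QROs
        Da = C[:, :na] @ C[:, :na].T
        Db = C[:, :nb] @ C[:, :nb].T
        Ja, Ka = df.jk(Da)
        Jb, Kb = df.jk(Db)
        Fa = h + Ja + Jb - Ka
        Fb = h + Ja + Jb - Kb
        energy = 0.5 * (np.sum(Da * (h + Fa)) + np.sum(Db * (h + Fb))) \
            + mol.nuclear_repulsion()
        mo_e = np.diag(C.T @ (0.5 * (Fa + Fb)) @ C)
    else:
        raise ValueError(f"unknown reference mode '{mode}'")

    # aufbau order under the effective energies; DOMOs then SOMOs
    nmo = C.shape[1]
    domo = np.arange(nb)
    somo = np.arange(nb, na)
    nfz = mol.n_frozen_core if frozen_core is None else frozen_core
    core = domo[np.argsort(mo_e[:nb])[:nfz]] if nfz else np.array([], int)
    return ReferenceState(
        mol=mol, basis=basis, aux=aux, mo_coeff=C, mo_energy=np.asarray(mo_e),
        domo_indices=domo, somo_indices=somo,
        fock_up=Fa, fock_down=Fb, overlap=S, hcore=h, scf_energy=energy,
        frozen_core_indices=np.sort(core), mode=mode)
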