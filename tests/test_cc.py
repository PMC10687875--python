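"""Spin-orbital CCSD and perturbative triples."""
import numpy as np
import pytest
import scipy.linalg as sla

from detfci import fci_ground_state
from lnocc import Molecule, build_reference, generate_fixture
from lnocc.ccsd import ccsd_contribution, solve_ccsd
from lnocc.laplace import laplace_quadrature
from lnocc.oracle import (_oracle_ccsd, canonical_blocks,
                          ccsd_energy_and_partition, canonical_ccsdt_oracle,
                          oracle_mp2)
from lnocc.scf import DFTensors
from lnocc.triples import (triples_contribution_explicit,
                           triples_contributions_laplace,
                           triples_energy_explicit)


@pytest.fixture(scope="module")
def h2_setup():
    mol = Molecule(("H", "H"), np.array([[0, 0, 0], [0, 0, 1.4]]), 0, 1)
    ref = build_reference(mol, "sto-3g")
    df = DFTensors(ref.basis, ref.aux)
    return ref, df


@pytest.fixture(scope="module")
def ethyl_blocks(ethyl_ref, ethyl_df):
    b = canonical_blocks(ethyl_ref, ethyl_df)
    amps = solve_ccsd(b, conv_tol=1e-9)
    return b, amps


def test_two_electron_ccsd_equals_fci(h2_setup):
    """CCSD is exact for two electrons: H2 CCSD matches determinant FCI."""
    ref, df = h2_setup
    b = canonical_blocks(ref, df)
    amps = solve_ccsd(b, conv_tol=1e-10)
    C = ref.mo_coeff
    L = sla.cholesky(df.metric, lower=True)
    Bmo = np.einsum("mp,mnX,nq->pqX", C, df.j3c, C, optimize=True)
    Bmo = sla.solve_triangular(
        L, Bmo.reshape(-1, df.aux.nao).T, lower=True).T.reshape(2, 2, -1)
    eri = np.einsum("pqX,rsX->pqrs", Bmo, Bmo)
    h = C.T @ ref.hcore @ C
    e_fci = fci_ground_state(h, eri, 1, 1) + ref.mol.nuclear_repulsion()
    assert ref.scf_energy + amps.energy == pytest.approx(e_fci, abs=1e-9)


def test_zero_integrals_give_zero_correlation(ethyl_blocks):
    import dataclasses
    b, _ = ethyl_blocks
    z = dataclasses.replace(
        b, f_ov=np.zeros_like(b.f_ov),
        oooo=np.zeros_like(b.oooo), ooov=np.zeros_like(b.ooov),
        oovv=np.zeros_like(b.oovv), ovov=np.zeros_like(b.ovov),
        ovvv=np.zeros_like(b.ovvv), vvvv=np.zeros_like(b.vvvv))
    amps = solve_ccsd(z)
    assert amps.energy == 0.0
    assert np.abs(amps.t2).max() == 0.0


def test_solver_agrees_with_independent_oracle_solver(ethyl_blocks,
                                                      ethyl_ref):
    b, amps = ethyl_blocks
    t1o, t2o, _, _ = _oracle_ccsd(b, conv_tol=1e-9)
    e_o, _ = ccsd_energy_and_partition(b, t1o, t2o)
    assert amps.energy == pytest.approx(e_o, abs=1e-8)


def test_per_orbital_partition_resolves_identity(ethyl_blocks):
    b, amps = ethyl_blocks
    total = sum(ccsd_contribution(b, amps, np.eye(b.no)[i])
                for i in range(b.no))
    assert total == pytest.approx(amps.energy, abs=1e-10)


def test_partition_invariant_under_occupied_rotation(ethyl_blocks, rng):
    """Summing the per-orbital CCSD contributions over any orthonormal
    occupied basis gives the same total."""
    b, amps = ethyl_blocks
    no = b.no
    q, _ = np.linalg.qr(rng.normal(size=(no, no)))
    total = sum(ccsd_contribution(b, amps, q[:, i]) for i in range(no))
    assert total == pytest.approx(amps.energy, abs=1e-10)


def test_triples_laplace_tracks_explicit(ethyl_blocks):
    b, amps = ethyl_blocks
    et = triples_energy_explicit(b, amps.t1, amps.t2)
    lo = 3.0 * (b.eps_v.min() - b.eps_o.max())
    hi = 3.0 * (b.eps_v.max() - b.eps_o.min())
    devs = []
    for tol in (1e-2, 1e-4):
        quad = laplace_quadrature(lo, hi, tol)
        tot = sum(triples_contributions_laplace(
            b, amps.t1, amps.t2, quad,
            [np.eye(b.no)[i] for i in range(b.no)]))
        devs.append(abs(tot - et))
        assert abs(tot - et) <= max(1e-6, tol * abs(et))
    assert devs[1] < devs[0]        # tighter T_LT shrinks the deviation


def test_triples_explicit_projection_resolves_identity(ethyl_blocks):
    b, amps = ethyl_blocks
    et = triples_energy_explicit(b, amps.t1, amps.t2)
    tot = sum(triples_contribution_explicit(b, amps.t1, amps.t2,
                                            np.eye(b.no)[i])
              for i in range(b.no))
    assert tot == pytest.approx(et, abs=1e-12)


def test_triples_zero_doubles_gives_zero(ethyl_blocks):
    b, amps = ethyl_blocks
    et = triples_energy_explicit(b, np.zeros_like(amps.t1),
                                 np.zeros_like(amps.t2))
    assert et == 0.0


def test_triples_negative_at_equilibrium(ethyl_blocks):
    b, amps = ethyl_blocks
    assert triples_energy_explicit(b, amps.t1, amps.t2) < 0.0


def test_oracle_partitions_sum_to_totals(ethyl_ref, ethyl_df):
    o = canonical_ccsdt_oracle(ethyl_ref, ethyl_df)
    assert o.mp2_partition.sum() == pytest.approx(o.corr_mp2, abs=1e-10)
    assert o.ccsd_partition.sum() == pytest.approx(o.corr_ccsd, abs=1e-10)
    assert o.t_partition.sum() == pytest.approx(o.corr_t, abs=1e-10)


def test_oracle_size_guard(ethyl_ref, ethyl_df, monkeypatch):
    """The canonical reference refuses systems beyond its size guard."""
    import lnocc.oracle as om
    monkeypatch.setattr(om, "MAX_SPIN_ORBITALS", 10)
    with pytest.raises(ValueError):
        om.canonical_blocks(ethyl_ref, ethyl_df)


def test_mp2_nonpositive_and_matches_partition(ethyl_ref, ethyl_df):
    b = canonical_blocks(ethyl_ref, ethyl_df)
    e2, part = oracle_mp2(b)
    assert e2 < 0.0
    assert part.sum() == pytest.approx(e2, abs=1e-12)
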