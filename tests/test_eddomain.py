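"""Extended-domain assembly, DF integrals, MP1 amplitudes, domain MP2."""
import itertools

import numpy as np
import pytest

from lnocc import localize_boys_restricted
from lnocc.domains import DomainBuilder
from lnocc.eddomain import (assemble_ed, build_fock_offdiagonal,
                            ed_mp2_energy, ed_quadrature, mp1_amplitudes,
                            transform_df_integrals)
from lnocc.pairs import MultipoleIntegrals, classify_pairs, multipole_pair_energy


def _pair_list(ref, builder, eps_w):
    mp = MultipoleIntegrals(ref)
    energies = {(k, l): multipole_pair_energy(builder, mp, k, l)
                for k, l in itertools.combinations(range(builder.lmos.n), 2)}
    return classify_pairs(builder, energies, eps_w, 5.0, 50.0)


@pytest.fixture(scope="module")
def ethyl_setup(ethyl_ref, ethyl_df):
    lmos = localize_boys_restricted(ethyl_ref)
    builder = DomainBuilder(ethyl_ref, lmos)
    plist = _pair_list(ethyl_ref, builder, 0.0)      # everything strong
    return ethyl_ref, ethyl_df, builder, plist


def test_gsl_preserves_central_and_somos(ethyl_setup):
    ref, df, builder, plist = ethyl_setup
    lmos = builder.lmos
    ed = assemble_ed(builder, 0, plist, T_EDo=1.0, T_0=1.0)
    S = ref.overlap
    # central LMO is column 0 and unchanged up to the (here exact)
    # projection; SOMOs keep their span
    c0 = lmos.lmo_coefficients[:, 0]
    assert abs(abs(c0 @ S @ ed.occ_coeff[:, 0]) - 1.0) < 1e-8
    for pos in np.where(ed.somo_flags)[0]:
        if pos == 0:
            continue
        v = ed.occ_coeff[:, pos]
        somos = lmos.lmo_coefficients[:, lmos.somo_mask]
        proj = somos @ (somos.T @ S @ v)
        assert np.linalg.norm(proj - v) < 1e-8


def test_ed_occupied_virtual_orthogonal(ethyl_setup):
    ref, df, builder, plist = ethyl_setup
    ed = assemble_ed(builder, 1, plist)
    S = ref.overlap
    cross = ed.occ_coeff.T @ S @ ed.pao_coeff
    assert np.abs(cross).max() < 1e-8
    g = ed.occ_coeff.T @ S @ ed.occ_coeff
    assert np.abs(g - np.eye(ed.n_occ)).max() < 1e-8


def test_ed_atoms_superset_of_central_bp(ethyl_setup):
    ref, df, builder, plist = ethyl_setup
    ed = assemble_ed(builder, 2, plist, T_EDo=0.9999)
    bp = builder.bp("lmo", 2, 0.9999)
    assert set(bp.atoms.tolist()) <= set(ed.atoms.tolist())


def test_assembled_eri_symmetry(ethyl_setup):
    ref, df, builder, plist = ethyl_setup
    ed = assemble_ed(builder, 0, plist, T_EDo=1.0, T_0=1.0)
    ints = transform_df_integrals(ed, df)
    b = ints.b_ov["up"]
    K = np.einsum("iaX,jbX->iajb", b, b)
    assert np.abs(K - K.transpose(2, 3, 0, 1)).max() < 1e-10


def test_fock_offdiagonal_contract(water_ref, methyl_ref):
    # self-consistent closed-shell reference: F_OD vanishes
    fod = build_fock_offdiagonal(water_ref)
    assert np.linalg.norm(fod["up"]) < 1e-8
    # restricted open-shell reference: nonzero and symmetric per spin
    fod = build_fock_offdiagonal(methyl_ref)
    assert np.linalg.norm(fod["up"]) > 1e-4
    for s in ("up", "down"):
        assert np.abs(fod[s] - fod[s].T).max() < 1e-10


def test_mp1_amplitudes_match_explicit_division(ethyl_setup):
    ref, df, builder, plist = ethyl_setup
    ed = assemble_ed(builder, 0, plist)
    ints = transform_df_integrals(ed, df)
    quad = ed_quadrature(ed, 1e-4)
    t_lap = mp1_amplitudes(ed, ints, quad, "laplace")
    t_chol = mp1_amplitudes(ed, ints, quad, "cholesky")
    t_exact = mp1_amplitudes(ed, ints, None, "exact")
    for case in t_exact:
        scale = max(np.abs(t_exact[case]).max(), 1e-10)
        assert np.abs(t_lap[case] - t_exact[case]).max() / scale < 1e-3
        assert np.abs(t_chol[case] - t_exact[case]).max() / scale < 1e-3


def test_same_spin_amplitude_antisymmetry(ethyl_setup):
    """Antisymmetrized same-spin amplitudes change sign under virtual
    exchange."""
    ref, df, builder, plist = ethyl_setup
    ed = assemble_ed(builder, 0, plist)
    ints = transform_df_integrals(ed, df)
    t = mp1_amplitudes(ed, ints, None, "exact")[("up", "up")]
    tbar = t - t.swapaxes(1, 2)
    assert np.abs(tbar + tbar.swapaxes(1, 2)).max() < 1e-12


def test_zero_integrals_give_zero_amplitudes(ethyl_setup):
    ref, df, builder, plist = ethyl_setup
    ed = assemble_ed(builder, 0, plist)
    ints = transform_df_integrals(ed, df)
    for s in ints.b_ov:
        ints.b_ov[s] = np.zeros_like(ints.b_ov[s])
    t = mp1_amplitudes(ed, ints, None, "exact")
    assert all(np.abs(v).max() == 0.0 for v in t.values())


def test_ed_mp2_sums_to_canonical_mp2(ethyl_setup):
    """No-truncation EDs: per-LMO MP2 contributions sum to the canonical
    UMP2 correlation energy (incl. open-shell singles)."""
    from lnocc.oracle import canonical_blocks, oracle_mp2
    ref, df, builder, plist = ethyl_setup
    f_od = build_fock_offdiagonal(ref)
    tot = 0.0
    for c in range(builder.lmos.n):
        ed = assemble_ed(builder, c, plist, T_EDo=1.0, T_0=1.0)
        ints = transform_df_integrals(ed, df)
        amps = mp1_amplitudes(ed, ints, None, "exact")
        tot += ed_mp2_energy(ed, ints, amps, f_od)
    e2 = oracle_mp2(canonical_blocks(ref, df))[0]
    assert tot == pytest.approx(e2, abs=1e-10)


def test_domain_mp2_nonpositive(ethyl_setup):
    ref, df, builder, plist = ethyl_setup
    f_od = build_fock_offdiagonal(ref)
    for c in range(builder.lmos.n):
        ed = assemble_ed(builder, c, plist)
        ints = transform_df_integrals(ed, df)
        amps = mp1_amplitudes(ed, ints, None, "exact")
        assert ed_mp2_energy(ed, ints, amps, f_od) <= 0.0


def test_pcd_restricted_aux_close_to_full_aux(hexane_ref):
    """Restricting the auxiliary set to PCD atoms reproduces the full-aux
    domain MP2 energy to 1e-5 hartree (same domain, only the fitting
    basis differs)."""
    from lnocc.scf import DFTensors
    ref = hexane_ref
    df = DFTensors(ref.basis, ref.aux)
    lmos = localize_boys_restricted(ref)
    builder = DomainBuilder(ref, lmos)
    plist = _pair_list(ref, builder, 1e-5)
    f_od = build_fock_offdiagonal(ref)
    ed = assemble_ed(builder, 0, plist)      # defaults: PCD proper subset
    assert len(ed.pcd_atoms) < ref.mol.natom
    vals = []
    for aux_atoms in (None, range(ref.mol.natom)):
        ints = transform_df_integrals(ed, df, aux_atoms=aux_atoms)
        amps = mp1_amplitudes(ed, ints, None, "exact")
        vals.append(ed_mp2_energy(ed, ints, amps, f_od))
    assert abs(vals[0] - vals[1]) < 1e-5


def test_spin_averaged_routing_flags(ethyl_setup):
    ref, df, builder, plist = ethyl_setup
    # every ED of the ethyl radical contains the SOMO (all pairs strong)
    for c in range(builder.lmos.n):
        ed = assemble_ed(builder, c, plist, spin_polarization_approx=True)
        assert not ed.spin_free
        assert not ed.spin_averaged
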