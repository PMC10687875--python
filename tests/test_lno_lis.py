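"""LNO construction and LIS integral machinery."""
import itertools

import numpy as np
import pytest

from lnocc import localize_boys_restricted
from lnocc.domains import DomainBuilder
from lnocc.eddomain import (EDIntegrals, assemble_ed, ed_mp2_energy,
                            build_fock_offdiagonal, mp1_amplitudes,
                            transform_df_integrals)
from lnocc.lis import build_lis, lis_spin_orbital_blocks, naf_compress
from lnocc.lno import (DegenerateDomainError, occupied_density_fragment,
                       select_lnos, virtual_density_fragment)
from lnocc.pairs import MultipoleIntegrals, classify_pairs, multipole_pair_energy


@pytest.fixture(scope="module")
def ethyl_domain(ethyl_ref, ethyl_df):
    lmos = localize_boys_restricted(ethyl_ref)
    builder = DomainBuilder(ethyl_ref, lmos)
    mp = MultipoleIntegrals(ethyl_ref)
    energies = {(k, l): multipole_pair_energy(builder, mp, k, l)
                for k, l in itertools.combinations(range(lmos.n), 2)}
    plist = classify_pairs(builder, energies, 0.0, 5.0, 50.0)
    ed = assemble_ed(builder, 0, plist, T_EDo=1.0, T_0=1.0)
    ints = transform_df_integrals(ed, ethyl_df)
    amps = mp1_amplitudes(ed, ints, None, "exact")
    return ethyl_ref, ethyl_df, builder, ed, ints, amps


def test_zero_amplitudes_give_zero_fragments(ethyl_domain):
    ref, df, builder, ed, ints, amps = ethyl_domain
    zero = {k: np.zeros_like(v) for k, v in amps.items()}
    occ = occupied_density_fragment(ed, zero)
    assert np.abs(occ.matrix).max() == 0.0
    vir = virtual_density_fragment(ed, zero, np.eye(ed.n_occ))
    assert np.abs(vir.matrix).max() == 0.0


def test_occupied_fragment_zeroed_blocks_and_psd(ethyl_domain):
    ref, df, builder, ed, ints, amps = ethyl_domain
    frag = occupied_density_fragment(ed, amps)
    assert np.abs(frag.matrix[0, :]).max() == 0.0      # central row zeroed
    for p in np.where(ed.somo_flags)[0]:
        assert np.abs(frag.matrix[p, :]).max() == 0.0
    w = np.linalg.eigvalsh(0.5 * (frag.matrix + frag.matrix.T))
    assert w.min() > -1e-9
    assert np.trace(frag.raw_matrix) > 0.0


def test_so_central_scaling_and_vanishing_down_amplitudes(ethyl_domain):
    """For an SO central the spin-down-central amplitude cases do not
    exist and the density fragment carries the factor-2 balance scale."""
    ref, df, builder, ed0, ints0, amps0 = ethyl_domain
    lmos = builder.lmos
    somo = int(np.where(lmos.somo_mask)[0][0])
    plist = classify_pairs(builder, {(k, l): -1.0 for k, l in
                                     itertools.combinations(range(lmos.n), 2)},
                           0.0, 5.0, 50.0)
    ed = assemble_ed(builder, somo, plist, T_EDo=1.0, T_0=1.0)
    ints = transform_df_integrals(ed, df)
    amps = mp1_amplitudes(ed, ints, None, "exact")
    assert ed.central_is_somo
    assert ("down", "up") not in amps and ("down", "down") not in amps
    frag = occupied_density_fragment(ed, amps)
    assert frag.scale == 2.0


def test_lno_selection_keeps_everything_at_zero_thresholds(ethyl_domain):
    ref, df, builder, ed, ints, amps = ethyl_domain
    occ_frag = occupied_density_fragment(ed, amps)
    lnos = select_lnos(ed, occ_frag, amps, 0.0, 0.0)
    assert lnos.n_occ == ed.n_occ
    assert lnos.n_virt == ed.pao_coeff.shape[1]


def test_lno_counts_monotone_in_thresholds(ethyl_domain):
    ref, df, builder, ed, ints, amps = ethyl_domain
    occ_frag = occupied_density_fragment(ed, amps)
    counts = []
    for eps_o in (1e-7, 1e-5, 1e-3):
        lnos = select_lnos(ed, occ_frag, amps, eps_o, eps_o / 10.0)
        counts.append((lnos.n_occ, lnos.n_virt))
    assert counts[0][0] >= counts[1][0] >= counts[2][0]
    assert counts[0][1] >= counts[1][1] >= counts[2][1]


def test_occupation_spectra_sorted_descending(ethyl_domain):
    ref, df, builder, ed, ints, amps = ethyl_domain
    occ_frag = occupied_density_fragment(ed, amps)
    lnos = select_lnos(ed, occ_frag, amps, 1e-5, 1e-6)
    assert np.all(np.diff(lnos.occ_spectrum) <= 1e-12)
    assert np.all(np.diff(lnos.virt_spectrum) <= 1e-12)
    assert np.all(lnos.occ_occupations >= 1e-5 - 1e-12)
    assert np.all(lnos.virt_occupations >= 1e-6 - 1e-12)


def test_impossible_virtual_threshold_raises(ethyl_domain):
    ref, df, builder, ed, ints, amps = ethyl_domain
    occ_frag = occupied_density_fragment(ed, amps)
    with pytest.raises(DegenerateDomainError):
        select_lnos(ed, occ_frag, amps, 1e-5, 1e6)


def test_central_preserved_in_lis(ethyl_domain):
    ref, df, builder, ed, ints, amps = ethyl_domain
    occ_frag = occupied_density_fragment(ed, amps)
    lnos = select_lnos(ed, occ_frag, amps, 1e-4, 1e-5)
    lis = build_lis(ed, ref, df, lnos, eps_naf=0.0)
    S = ref.overlap
    central_ao = ed.occ_coeff[:, 0]
    proj = lis.occ_coeff @ (lis.occ_coeff.T @ S @ central_ao)
    assert np.linalg.norm(proj - central_ao) < 1e-10


def test_closed_shell_fragments_spin_symmetric(water_ref, water_df):
    lmos = localize_boys_restricted(water_ref)
    builder = DomainBuilder(water_ref, lmos)
    plist = classify_pairs(builder, {(k, l): -1.0 for k, l in
                                     itertools.combinations(range(lmos.n), 2)},
                           0.0, 5.0, 50.0)
    ed = assemble_ed(builder, 0, plist, T_EDo=1.0, T_0=1.0)
    ints = transform_df_integrals(ed, water_df)
    amps = mp1_amplitudes(ed, ints, None, "exact")
    assert np.abs(amps[("up", "up")] - amps[("down", "down")]).max() < 1e-10
    assert np.abs(amps[("up", "down")] - amps[("down", "up")]).max() < 1e-10


def test_naf_compression_monotone_and_exact_at_zero(ethyl_domain):
    ref, df, builder, ed, ints, amps = ethyl_domain
    occ_frag = occupied_density_fragment(ed, amps)
    lnos = select_lnos(ed, occ_frag, amps, 1e-5, 1e-6)
    counts = []
    for eps in (0.0, 1e-4, 1e-2, 1.0):
        lis = build_lis(ed, ref, df, lnos, eps_naf=eps)
        counts.append(lis.naf.n_kept)
    assert counts[0] >= counts[1] >= counts[2] >= counts[3]
    lis0 = build_lis(ed, ref, df, lnos, eps_naf=0.0)
    # eps_NAF = 0: the NAF rotation is unitary on the auxiliary space, so
    # assembled ERIs are unchanged
    K0 = np.einsum("iaX,jbX->iajb", lis0.b_ov["up"], lis0.b_ov["up"])
    lis2 = build_lis(ed, ref, df, lnos, eps_naf=1e-2)
    # sanity: same shapes of the compressed tensor families
    assert lis2.b_ov["up"].shape[:2] == lis0.b_ov["up"].shape[:2]
    assert K0.shape[0] == lis0.b_ov["up"].shape[0]


def test_lis_mp2_equals_ed_mp2_without_truncation(ethyl_domain):
    """LIS = ED when nothing is truncated: the MP2 correction vanishes."""
    ref, df, builder, ed, ints, amps = ethyl_domain
    f_od = build_fock_offdiagonal(ref)
    e_ed = ed_mp2_energy(ed, ints, amps, f_od)
    occ_frag = occupied_density_fragment(ed, amps)
    lnos = select_lnos(ed, occ_frag, amps, 0.0, 0.0)
    lis = build_lis(ed, ref, df, lnos, eps_naf=0.0)
    lis_ints = EDIntegrals(lis.b_ov, lis.b_oo, lis.b_vv, np.zeros(0))
    amps_lis = mp1_amplitudes(lis, lis_ints, None, "exact")
    e_lis = ed_mp2_energy(lis, lis_ints, amps_lis, f_od)
    assert e_lis == pytest.approx(e_ed, abs=1e-10)


def test_lno_prime_expansion_error_small(ethyl_domain):
    ref, df, builder, ed, ints, amps = ethyl_domain
    occ_frag = occupied_density_fragment(ed, amps)
    lnos = select_lnos(ed, occ_frag, amps, 1e-5, 1e-6)
    lis = build_lis(ed, ref, df, lnos, eps_naf=1e-2)
    assert lis.lno_expansion_error <= 0.05
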