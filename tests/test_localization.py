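"""Restricted Boys localization."""
import numpy as np
import pytest

from lnocc import build_reference, generate_fixture, localize_boys_restricted
from lnocc import integrals as ints
from lnocc.localize import boys_objective


def _dipoles(ref):
    m = ints.multipole(ref.basis, 1)
    return [m[(1, 0, 0)], m[(0, 1, 0)], m[(0, 0, 1)]]


def test_objective_strictly_increases_on_ethane_like_chain(hexane_ref):
    ref = hexane_ref
    dip = _dipoles(ref)
    before = boys_objective(ref.mo_coeff[:, ref.correlated_domo_indices],
                            dip)
    lmos = localize_boys_restricted(ref)
    after = boys_objective(
        lmos.lmo_coefficients[:, lmos.domo_mask], dip)
    assert after > before + 1.0


def test_density_invariant_under_localization(methyl_ref):
    ref = methyl_ref
    lmos = localize_boys_restricted(ref)
    corr = np.concatenate([ref.correlated_domo_indices, ref.somo_indices])
    D0 = ref.mo_coeff[:, corr] @ ref.mo_coeff[:, corr].T
    D1 = lmos.lmo_coefficients @ lmos.lmo_coefficients.T
    assert np.abs(D0 - D1).max() < 1e-8


def test_domo_and_somo_subspaces_not_mixed(methyl_ref):
    ref = methyl_ref
    lmos = localize_boys_restricted(ref)
    S = ref.overlap
    dom_canon = ref.mo_coeff[:, ref.correlated_domo_indices]
    som_canon = ref.mo_coeff[:, ref.somo_indices]
    dom_loc = lmos.lmo_coefficients[:, lmos.domo_mask]
    som_loc = lmos.lmo_coefficients[:, lmos.somo_mask]
    # cross overlaps vanish: each localized block stays in its span
    assert np.abs(dom_loc.T @ S @ som_canon).max() < 1e-10
    assert np.abs(som_loc.T @ S @ dom_canon).max() < 1e-10
    P = dom_canon @ dom_canon.T @ S
    assert np.abs(P @ dom_loc - dom_loc).max() < 1e-8


def test_single_orbital_subspace_returned_unchanged():
    ref = build_reference(generate_fixture("hydroxyl"), "sto-3g")
    lmos = localize_boys_restricted(ref)
    # exactly one SOMO: a 1x1 "rotation" can only change the phase
    S = ref.overlap
    somo = ref.mo_coeff[:, ref.somo_indices[0]]
    loc = lmos.lmo_coefficients[:, lmos.somo_mask][:, 0]
    assert abs(abs(loc @ S @ somo) - 1.0) < 1e-10


def test_lmos_orthonormal(hexane_ref):
    lmos = localize_boys_restricted(hexane_ref)
    g = lmos.lmo_coefficients.T @ hexane_ref.overlap @ lmos.lmo_coefficients
    assert np.abs(g - np.eye(lmos.n)).max() < 1e-10


def test_localization_deterministic(methyl_ref):
    a = localize_boys_restricted(methyl_ref)
    b = localize_boys_restricted(methyl_ref)
    assert np.array_equal(a.lmo_coefficients, b.lmo_coefficients)


def test_chain_lmos_are_at_most_two_center(hexane_ref):
    """Boys bonds on an alkane: every valence LMO lives on <= 2 atoms."""
    ref = hexane_ref
    lmos = localize_boys_restricted(ref)
    for k in range(lmos.n):
        v = lmos.lmo_coefficients[:, k]
        pops = np.zeros(ref.mol.natom)
        np.add.at(pops, ref.basis.ao_atom, v * (ref.overlap @ v))
        assert np.sort(pops)[::-1][:2].sum() > 0.9
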