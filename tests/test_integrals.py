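"""Integral engine checks against independent analytic references."""
import math

import numpy as np
import pytest

from lnocc import integrals as ints
from lnocc.basis import AOBasis, _prim_norm
from lnocc.mol import Molecule


def _single_s_basis(exps_centers):
    class _B:
        pass

    b = _B()
    n = len(exps_centers)
    b.sh_L = np.zeros(n, np.int64)
    b.sh_center = np.array([c for _, c in exps_centers], float)
    b.sh_nprim = np.ones(n, np.int64)
    b.sh_ptr = np.arange(n + 1, dtype=np.int64)
    b.prim_exp = np.array([a for a, _ in exps_centers])
    b.prim_coef = np.array([_prim_norm(0, a) for a, _ in exps_centers])
    b.sh_off = np.arange(n, dtype=np.int64)
    b.nao = n
    b.comp_fac = np.ones(n)
    return b


def test_two_center_eri_matches_analytic_s_formula(rng):
    """(X|Y) for s Gaussians equals the closed-form Boys expression."""
    specs = [(0.8, rng.normal(size=3)), (1.7, rng.normal(size=3) + 2.0),
             (0.3, rng.normal(size=3) - 1.0)]
    aux = _single_s_basis(specs)
    V = ints.eri_2c(aux)
    for i, (ai, Ai) in enumerate(specs):
        for j, (aj, Aj) in enumerate(specs):
            alpha = ai * aj / (ai + aj)
            T = alpha * float(np.dot(Ai - Aj, Ai - Aj))
            from scipy.special import erf
            F0 = (0.5 * math.sqrt(math.pi / T) * erf(math.sqrt(T))
                  if T > 1e-12 else 1.0 - T / 3.0)
            pref = (2.0 * math.pi ** 2.5
                    / (ai * aj * math.sqrt(ai + aj)))
            want = _prim_norm(0, ai) * _prim_norm(0, aj) * pref * F0
            assert V[i, j] == pytest.approx(want, rel=1e-12)


def test_three_center_eri_matches_analytic_s_formula(rng):
    """(mu nu|X) for s functions equals the independent closed form."""
    mol = Molecule(("H", "H"), np.array([[0.0, 0, 0], [0, 0, 1.5]]), 0, 1)
    basis = AOBasis(mol, "sto-3g")
    aux = _single_s_basis([(0.9, np.array([0.3, -0.2, 0.7]))])
    out = ints.eri_3c(basis, aux)
    # reference: contract primitives of the two contracted AOs explicitly
    from scipy.special import erf
    C = aux.sh_center[0]
    ref = 0.0
    sh0, sh1 = basis.shells[0], basis.shells[1]
    for a, ca in zip(sh0.exps, sh0.coefs):
        for b, cb in zip(sh1.exps, sh1.coefs):
            pp = a + b
            P = (a * sh0.center + b * sh1.center) / pp
            mu = a * b / pp
            kab = math.exp(-mu * float(np.dot(sh0.center - sh1.center,
                                              sh0.center - sh1.center)))
            q = 0.9
            alpha = pp * q / (pp + q)
            T = alpha * float(np.dot(P - C, P - C))
            F0 = (0.5 * math.sqrt(math.pi / T) * erf(math.sqrt(T))
                  if T > 1e-12 else 1.0 - T / 3.0)
            pref = 2.0 * math.pi ** 2.5 / (pp * q * math.sqrt(pp + q))
            ref += ca * cb * _prim_norm(0, q) * pref * kab * F0
    assert out[0, 1, 0] == pytest.approx(ref, rel=1e-10)


@pytest.mark.parametrize("key", ["overlap", "kinetic", "nuclear"])
def test_one_electron_rotation_invariance(key, rng):
    from scipy.spatial.transform import Rotation
    coords = rng.normal(size=(3, 3)) * 1.4
    R = Rotation.from_rotvec([0.4, -0.3, 0.9]).as_matrix()
    f = {"overlap": ints.overlap, "kinetic": ints.kinetic,
         "nuclear": ints.nuclear_attraction}[key]
    vals = []
    for c in (coords, coords @ R.T):
        mol = Molecule(("C", "O", "H"), c, 0, 2)
        vals.append(np.sort(np.linalg.eigvalsh(f(AOBasis(mol, "sto-3g")))))
    assert np.abs(vals[0] - vals[1]).max() < 1e-10


def test_multipole_translation_identities(rng):
    coords = rng.normal(size=(2, 3)) * 1.2
    t = np.array([0.6, -0.4, 1.1])
    m1 = Molecule(("C", "H"), coords, 0, 2)
    m2 = Molecule(("C", "H"), coords + t, 0, 2)
    b1, b2 = AOBasis(m1, "sto-3g"), AOBasis(m2, "sto-3g")
    S = ints.overlap(b1)
    d1, d2 = ints.multipole(b1, 2), ints.multipole(b2, 2)
    X1, Y1 = d1[(1, 0, 0)], d1[(0, 1, 0)]
    assert np.abs(d2[(1, 0, 0)] - (X1 + t[0] * S)).max() < 1e-12
    assert np.abs(d2[(2, 0, 0)]
                  - (d1[(2, 0, 0)] + 2 * t[0] * X1
                     + t[0] ** 2 * S)).max() < 1e-12
    assert np.abs(d2[(1, 1, 0)]
                  - (d1[(1, 1, 0)] + t[0] * Y1 + t[1] * X1
                     + t[0] * t[1] * S)).max() < 1e-12


def test_contracted_functions_are_normalized():
    mol = Molecule(("C", "O", "H"), np.eye(3) * 2.0, 0, 2)
    for name in ("sto-3g", "svdz"):
        S = ints.overlap(AOBasis(mol, name))
        assert np.abs(np.diag(S) - 1.0).max() < 1e-10


def test_aux_metric_positive_definite():
    mol = Molecule(("C", "O", "H"), np.eye(3) * 2.2, 0, 2)
    for name in ("sto-3g", "svdz"):
        V = ints.eri_2c(AOBasis(mol, name, aux=True))
        assert np.linalg.eigvalsh(V).min() > 0.0
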