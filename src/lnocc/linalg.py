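"""Small orthogonalization / projection helpers used by the domain code."""
from __future__ import annotations

import numpy as np
import scipy.linalg as sla


def lowdin(C: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Loewdin symmetric orthogonalization of columns of C in metric S."""
    g = C.T @ S @ C
    w, v = np.linalg.eigh(g)
    if w.min() <= 1e-12:
        raise np.linalg.LinAlgError("singular overlap in Loewdin step")
    return C @ (v / np.sqrt(w)) @ v.T


def canonical_orth(C: np.ndarray, S: np.ndarray, tol: float = 1e-7):
    """Canonical orthogonalization dropping near-null-space columns.

    Returns (orthonormal columns, number dropped).  `tol` is applied to
    the eigenvalues of the overlap of the input columns.
    """
    g = C.T @ S @ C
    w, v = np.linalg.eigh(g)
    keep = w > tol
    return C @ (v[:, keep] / np.sqrt(w[keep])), int((~keep).sum())


def project_onto_aos(vec: np.ndarray, S: np.ndarray, ao_idx: np.ndarray):
    """Least-squares expansion of an orbital in a subset of AOs.

    Returns (coefficients over the AO subset, completeness), where the
    completeness is <p|p> of the projected orbital (1 for a perfect span).
    """
    rhs = (S @ vec)[ao_idx]
    Saa = S[np.ix_(ao_idx, ao_idx)]
    c = sla.solve(Saa, rhs, assume_a="pos")
    return c, float(c @ rhs)


def embed(coeff_sub: np.ndarray, ao_idx: np.ndarray, nao: int) -> np.ndarray:
    """Scatter AO-subset coefficients back into full-AO vectors."""
    out = np.zeros((nao,) + coeff_sub.shape[1:])
    out[ao_idx] = coeff_sub
    return out
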