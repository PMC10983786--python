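"""Small linear-algebra helpers shared across fitters.

Coordinate vectors follow the vec(Aᵀ) convention for an n×3 coordinate
matrix A: entry (atom a, axis k) sits at index 3a+k.  For a row-major
numpy array this is simply ``A.ravel()``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "vec_coords",
    "unvec_coords",
    "symmetrize",
    "ridge_stabilize",
    "rotate_covariance",
    "atom_weights_from_covariance",
]


def vec_coords(A: np.ndarray) -> np.ndarray:
    """n×3 coordinates -> length-3n vector, (atom, axis) ↦ 3a+k."""
    return np.asarray(A, dtype=float).ravel()


def unvec_coords(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Length-3n vector -> n×3 coordinates (inverse of :func:`vec_coords`)."""
    y = np.asarray(y, dtype=float)
    if n is None:
        n = y.size // 3
    return y.reshape(n, 3)


def symmetrize(C: np.ndarray) -> np.ndarray:
    return 0.5 * (C + C.T)


def ridge_stabilize(C: np.ndarray, ridge: float) -> np.ndarray:
    """Add a relative ridge ``ridge * (tr C / dim) * I``.

    Needed because maximum-likelihood 3n×3n covariance estimates are
    rank-deficient whenever the effective sample size is below 3n.  A zero
    matrix is returned unchanged (its ridge scale is zero).
    """
    C = np.asarray(C, dtype=float)
    if ridge <= 0:
        return C
    scale = np.trace(C) / C.shape[0]
    if scale <= 0:
        return C
    return C + ridge * scale * np.eye(C.shape[0])


def clip_eigenvalues(C: np.ndarray, floor_rel: float) -> np.ndarray:
    """Clamp eigenvalues of a symmetric PSD matrix at ``floor_rel * tr(C)/dim``.

    A no-op when the smallest eigenvalue already exceeds the floor.  Used to
    keep covariance iterates invertible in degenerate problems where the ML
    estimate collapses along exactly-fit directions.
    """
    C = symmetrize(np.asarray(C, dtype=float))
    if floor_rel <= 0:
        return C
    floor = floor_rel * max(np.trace(C), 0.0) / C.shape[0]
    vals, vecs = np.linalg.eigh(C)
    if vals[0] >= floor:
        return C
    return (vecs * np.maximum(vals, floor)) @ vecs.T


def rotate_covariance(C: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Transform a 3n×3n covariance under the global rotation Y -> Y R.

    Per-atom 3-subvectors transform as d ↦ Rᵀ d, so C ↦ (I⊗Rᵀ) C (I⊗R).
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0] // 3
    # C'[3i+k,3j+l] = Σ_ab R[a,k] C[3i+a,3j+b] R[b,l], no Kronecker built
    C4 = C.reshape(n, 3, n, 3)
    out = np.einsum("ak,iajb,bl->ikjl", R, C4, R, optimize=True)
    return out.reshape(3 * n, 3 * n)


def atom_weights_from_covariance(C: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Scalar per-atom weights w_a = 3 / tr(C_aa), variances floored.

    ``floor`` (Å²) clamps the per-axis variance tr(C_aa)/3 from below so
    weights cannot diverge on (near-)rigid atoms.
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0] // 3
    d = np.diagonal(C).reshape(n, 3)
    var = np.maximum(d.mean(axis=1), floor)  # per-axis variance of atom a
    return 1.0 / var
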