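"""Rigid-body superposition of a single conformational ensemble.

The transform convention used throughout the package is

    Y = (X - 1_n tᵀ) R

i.e. translate by ``t`` first, then rotate by right-multiplication with the
proper rotation ``R``.  ``optimal_transform`` solves the weighted Procrustes
subproblem in closed form (Kabsch with per-atom scalar weights);
``ols_superpose`` and ``iwls_superpose`` alternate transform and mean/variance
updates for homoscedastic and heteroscedastic errors respectively.

Under heteroscedasticity, weighting atoms by their inverse variance makes the
superposition lock onto the rigid core and lets flexible regions (termini,
loops) float — the statistically efficient behaviour for Gaussian errors with
unequal per-atom variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._linalg import atom_weights_from_covariance, symmetrize, vec_coords

__all__ = [
    "RigidTransform",
    "SingleFit",
    "optimal_transform",
    "optimal_transforms_batch",
    "ols_superpose",
    "iwls_superpose",
    "sample_covariance",
]

#: Å² floor applied to per-atom variances before inversion to weights.
VARIANCE_FLOOR = 1e-6


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion ``Y = (X - 1 tᵀ) R`` with proper rotation R."""

    t: np.ndarray  # (3,)
    R: np.ndarray  # (3, 3)

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float).reshape(3))
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float).reshape(3, 3))

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.t) @ self.R

    def inverse(self) -> "RigidTransform":
        # X = Y Rᵀ + 1 tᵀ  =  (Y - 1(-t R)ᵀ) Rᵀ
        return RigidTransform(t=-self.t @ self.R, R=self.R.T)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform applying ``self`` first, then ``other``."""
        return RigidTransform(t=self.t + self.R @ other.t, R=self.R @ other.R)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(t=np.zeros(3), R=np.eye(3))


@dataclass
class SingleFit:
    """Result of a single-ensemble superposition.

    ``objective_trace`` is a weighted residual sum of squares for OLS
    (non-increasing) and a heteroscedastic Gaussian log-likelihood for IWLS
    (non-decreasing); ``objective`` names which.
    """

    M_hat: np.ndarray
    Sigma_hat: np.ndarray
    transforms: list[RigidTransform]
    n_iter: int
    converged: bool
    objective_trace: list[float]
    objective: str = "rss"
    weights: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)


def _coords(member) -> np.ndarray:
    """Accept a Conformation-like object or a bare n×3 array."""
    return np.asarray(getattr(member, "coords", member), dtype=float)


def optimal_transform(X, M, w=None) -> RigidTransform:
    """Closed-form weighted Procrustes: minimise Σ_a w_a ‖row_a((X-1tᵀ)R) - row_a(M)‖².

    Parameters
    ----------
    X, M : (n, 3) arrays
        Mobile and target coordinates.
    w : (n,) positive weights, optional
        Defaults to unit weights.

    Raises
    ------
    ValueError
        If the weighted cross-covariance has rank < 2 ("ill-conditioned
        superposition": the rotation is not identifiable).
    """
    X = _coords(X)
    M = _coords(M)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms for a rigid superposition")
    if w is None:
        w = np.ones(n)
    w = np.asarray(w, dtype=float)
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be finite and positive")

    wsum = w.sum()
    xbar = w @ X / wsum
    mbar = w @ M / wsum
    Xc = X - xbar
    Mc = M - mbar
    A = Xc.T @ (w[:, None] * Mc)  # maximise tr(Rᵀ A)
    U, s, Vt = np.linalg.svd(A)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise ValueError("ill-conditioned superposition: cross-covariance rank < 2")
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    t = xbar - mbar @ R.T
    return RigidTransform(t=t, R=R)


def optimal_transforms_batch(Xs: np.ndarray, M: np.ndarray, w=None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised weighted Procrustes of a stack ``Xs`` (m, n, 3) onto one target.

    Returns ``(ts, Rs)`` of shapes (m, 3) and (m, 3, 3).  Same objective as
    :func:`optimal_transform`, solved with a batched 3×3 SVD.
    """
    Xs = np.asarray(Xs, dtype=float)
    m, n, _ = Xs.shape
    if w is None:
        w = np.ones(n)
    w = np.asarray(w, dtype=float)
    wsum = w.sum()
    xbar = np.einsum("a,jak->jk", w, Xs) / wsum  # (m, 3)
    mbar = w @ M / wsum
    Xc = Xs - xbar[:, None, :]
    Mc = M - mbar
    A = np.einsum("jak,a,al->jkl", Xc, w, Mc)  # (m, 3, 3)
    U, s, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.repeat(np.eye(3)[None], m, axis=0)
    D[:, 2, 2] = d
    Rs = U @ D @ Vt
    ts = xbar - np.einsum("k,jlk->jl", mbar, Rs)
    return ts, Rs


def apply_transforms_batch(Xs: np.ndarray, ts: np.ndarray, Rs: np.ndarray) -> np.ndarray:
    return np.einsum("jak,jkl->jal", Xs - ts[:, None, :], Rs)


def sample_covariance(aligned, M=None, divisor: str = "unbiased") -> np.ndarray:
    """3n×3n sample covariance of aligned structures in vec(Yᵀ) convention.

    ``divisor='ml'`` divides by m, ``'unbiased'`` by m-1.  When ``M`` is given
    it is used as the (known) mean, otherwise the sample mean is used.
    """
    Y = np.stack([_coords(a) for a in aligned])
    m = Y.shape[0]
    if m < 2:
        raise ValueError("need at least 2 structures for a sample covariance")
    ys = Y.reshape(m, -1)
    mu = vec_coords(_coords(M)) if M is not None else ys.mean(axis=0)
    D = ys - mu
    if divisor == "ml":
        den = m
    elif divisor == "unbiased":
        den = m - 1
    else:
        raise ValueError(f"unknown divisor {divisor!r}")
    return symmetrize(D.T @ D / den)


def _gauge_center(M: np.ndarray, ts: np.ndarray, Rs: np.ndarray):
    """Translate the mean to zero centroid, absorbing the shift into t."""
    c = M.mean(axis=0)
    # shifting every aligned Y by -c means t -> t + R c
    ts = ts + np.einsum("k,jlk->jl", c, Rs)
    return M - c, ts


def ols_superpose(members, tol: float = 1e-8, max_iter: int = 200) -> SingleFit:
    """Homoscedastic (unit-weight) alternating superposition.

    Alternates a mean update (plain average of the aligned structures) with
    unit-weight Procrustes updates until the relative drop in residual sum of
    squares falls below ``tol``.  The mean is centred at the origin; the
    orientation is anchored by initialising the mean from the first member's
    frame, which makes the fit deterministic given the input order.
    """
    Xs = np.stack([_coords(c) for c in members])
    m, n, _ = Xs.shape
    if m < 2:
        raise ValueError("need at least 2 members")
    M = Xs[0] - Xs[0].mean(axis=0)
    trace: list[float] = []
    converged = False
    prev = np.inf
    ts = np.zeros((m, 3))
    Rs = np.repeat(np.eye(3)[None], m, axis=0)
    for it in range(1, max_iter + 1):
        ts, Rs = optimal_transforms_batch(Xs, M)
        Y = apply_transforms_batch(Xs, ts, Rs)
        M = Y.mean(axis=0)
        M, ts = _gauge_center(M, ts, Rs)
        rss = float(np.sum((Y - Y.mean(axis=0)) ** 2))
        trace.append(rss)
        if prev - rss <= tol * max(abs(prev), 1.0) and it > 1:
            converged = True
            break
        prev = rss
    Y = apply_transforms_batch(Xs, ts, Rs)
    Sigma = sample_covariance(Y, M, divisor="ml")
    return SingleFit(
        M_hat=M,
        Sigma_hat=Sigma,
        transforms=[RigidTransform(t=ts[j], R=Rs[j]) for j in range(m)],
        n_iter=it,
        converged=converged,
        objective_trace=trace,
        objective="rss",
        weights=np.ones(n),
        metadata={"method": "ols"},
    )


def iwls_superpose(
    members,
    tol: float = 1e-8,
    max_iter: int = 200,
    variance_floor: float = VARIANCE_FLOOR,
) -> SingleFit:
    """Heteroscedastic iterative weighted least-squares superposition.

    Coordinate ascent on the Gaussian log-likelihood with a diagonal,
    per-atom-isotropic covariance: (i) per-atom variances are re-estimated
    from the aligned residuals (ML update, floored at ``variance_floor`` Å²),
    (ii) transforms and mean are updated under weights w_a = 1/σ̂²_a.  Both
    steps increase the likelihood, so ``objective_trace`` (the log-likelihood)
    is non-decreasing whenever the iteration converges.  The returned
    ``Sigma_hat`` is the full 3n×3n ML covariance of the final residuals.

    The iteration is not guaranteed to converge for every input (notoriously
    at very small ensemble sizes); in that case ``converged`` is False and the
    best fit found is returned.
    """
    Xs = np.stack([_coords(c) for c in members])
    m, n, _ = Xs.shape
    if m < 2:
        raise ValueError("need at least 2 members")
    M = Xs[0] - Xs[0].mean(axis=0)
    w = np.ones(n)
    var = np.ones(n)
    trace: list[float] = []
    converged = False
    prev = -np.inf
    ts = np.zeros((m, 3))
    Rs = np.repeat(np.eye(3)[None], m, axis=0)
    for it in range(1, max_iter + 1):
        # (ii) weighted transform + mean updates under current weights
        ts, Rs = optimal_transforms_batch(Xs, M, w)
        Y = apply_transforms_batch(Xs, ts, Rs)
        M = Y.mean(axis=0)  # per-atom weights are constant across members
        M, ts = _gauge_center(M, ts, Rs)
        Y = apply_transforms_batch(Xs, ts, Rs)
        # (i) ML variance update from residuals, floored
        resid2 = np.sum((Y - M) ** 2, axis=(0, 2))  # per atom, summed over m and xyz
        var = np.maximum(resid2 / (3 * m), variance_floor)
        w = 1.0 / var
        # heteroscedastic Gaussian log-likelihood at the ML variances
        ll = float(
            -0.5 * (3 * m) * np.sum(np.log(2 * np.pi * var))
            - 0.5 * np.sum(resid2 / var)
        )
        trace.append(ll)
        if it > 1 and ll - prev <= tol * max(abs(prev), 1.0):
            converged = True
            break
        prev = ll
    Sigma = sample_covariance(Y, M, divisor="ml")
    return SingleFit(
        M_hat=M,
        Sigma_hat=Sigma,
        transforms=[RigidTransform(t=ts[j], R=Rs[j]) for j in range(m)],
        n_iter=it,
        converged=converged,
        objective_trace=trace,
        objective="loglik",
        weights=w,
        metadata={
            "method": "iwls",
            "variance_floor": variance_floor,
            "full_covariance_note": (
                "Sigma_hat is a full 3n x 3n ML covariance from the final "
                "residuals; with m below 3n it is rank-deficient"
            ),
        },
    )


def weights_from_sigma(Sigma: np.ndarray, floor: float = VARIANCE_FLOOR) -> np.ndarray:
    """Per-atom weights 1 / max(tr(Σ_aa)/3, floor) from a 3n×3n covariance."""
    return atom_weights_from_covariance(Sigma, floor)
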