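r"""EM estimation of the two-level random-effects superposition model.

Model
-----
Each conformation ``X_ij`` (member j of ensemble i) is a rigidly displaced
copy of a latent structure

    Y_ij = (X_ij - 1_n t_ijᵀ) R_ij = M + Z_i + E_ij,

with ``vec(Z_iᵀ) ~ N(0, W)`` the ensemble-level (inter-ensemble) deviation
and ``vec(E_ijᵀ) ~ N(0, Σ)`` the conformation-level (intra-ensemble)
deviation; W and Σ are full 3n×3n anisotropic covariance matrices.

Fitting cycles through four steps (one generalized-EM cycle):

1. **E step** — the posterior of ``z_i`` is Gaussian with
   ``V_i = (W⁻¹ + m_i Σ⁻¹)⁻¹`` and mean
   ``b_i = V_i Σ⁻¹ Σ_j (y_ij − μ)`` (empirical Bayes: the current (W, Σ)
   act as the prior, shrinking small-ensemble means toward the population
   mean).  Computed via the W-inverse-free push-through form
   ``b_i = W (W + Σ/m_i)⁻¹ (ȳ_i − μ)``, which is exact for singular W.
2. **M step** — mixed-model updates:
   ``μ ← N⁻¹ Σ_ij (y_ij − b_i)``, ``W ← ν⁻¹ Σ_i (b_i b_iᵀ + V_i)``,
   ``Σ ← N⁻¹ Σ_ij (r_ij r_ijᵀ + V_i)`` with ``r_ij = y_ij − μ − b_i``.
3. **Transform step** — each conformation is re-superposed onto its ensemble
   target ``M̂ + ẑ_i``.  Two candidates per conformation: the closed-form
   Procrustes solution under scalar per-atom weights ``w_a = 3/tr(Σ̂_aa)``,
   and a damped Gauss–Newton step on the six rigid parameters in the full
   Σ⁻¹ metric.  A candidate is accepted only if it lowers the exact
   Σ⁻¹-metric residual given the current posterior mean — so every step
   increases the same likelihood minorant and the log-likelihood trace is
   monotone.
4. **Gauge step** — μ is recentred at the origin, the shift absorbed into
   the translations; the orientation is inherited from the initial pooled
   superposition frame.

The ridge ``C̄ = C + ridge·(tr C/3n)·I`` is folded into the *initial*
covariances: with ν and Σm_i below 3n — true for realistic X-ray datasets —
the moment-based starting values are rank-deficient and the ridge makes them
positive definite.  Subsequent iterates stay positive definite on their own
(the posterior covariance V_i enters both covariance updates additively), so
the EM runs and is evaluated at the raw parameters, which keeps the
log-likelihood trace exactly monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from ._linalg import (
    clip_eigenvalues,
    ridge_stabilize,
    symmetrize,
    unvec_coords,
    vec_coords,
)
from .superpose import (
    RigidTransform,
    apply_transforms_batch,
    ols_superpose,
    optimal_transforms_batch,
    weights_from_sigma,
)

__all__ = [
    "REMConfig",
    "REMFit",
    "rem_fit",
    "rem_loglik",
    "rem_loglik_from_set",
    "posterior_ensemble_means",
]


@dataclass
class REMConfig:
    tol: float = 1e-8
    max_iter: int = 5000
    ridge: float = 1e-6
    covariance_structure: str = "full"  # or "atom_block"
    init: str = "ols_pool"  # or "ts_warm"
    seed: int = 0
    anchor: str = "init_pool_frame"

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")
        if self.covariance_structure not in ("full", "atom_block"):
            raise ValueError("covariance_structure must be 'full' or 'atom_block'")
        if self.init not in ("ols_pool", "ts_warm"):
            raise ValueError("init must be 'ols_pool' or 'ts_warm'")


@dataclass
class REMFit:
    """Fitted random-effects superposition.

    ``Z_hat`` holds the posterior-mean ensemble deviations (empirical-Bayes
    shrunken), ``V_i`` their posterior covariances.  ``loglik_trace`` is the
    marginal log-likelihood after each EM cycle and is non-decreasing.
    """

    M_hat: np.ndarray
    W_hat: np.ndarray
    Sigma_hat: np.ndarray
    Z_hat: list[np.ndarray]
    V_i: list[np.ndarray]
    transforms: list[RigidTransform]
    loglik_trace: list[float]
    n_iter: int
    converged: bool
    ensemble_ids: list[str] = field(default_factory=list)
    member_ids: list[str] = field(default_factory=list)
    member_ensemble_index: list[int] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def _skew(v: np.ndarray) -> np.ndarray:
    """[v]× with [v]× ω = v × ω."""
    return np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])


def _block_diag_project(C: np.ndarray) -> np.ndarray:
    """Keep only the per-atom 3×3 diagonal blocks of a 3n×3n matrix."""
    n = C.shape[0] // 3
    out = np.zeros_like(C)
    for a in range(n):
        s = slice(3 * a, 3 * a + 3)
        out[s, s] = C[s, s]
    return out


def _posterior_moments(W_bar, Sigma_bar, sizes):
    """Per unique ensemble size m: V_m = W̄ (W̄ + Σ̄/m)⁻¹ (Σ̄/m) and the
    shrinkage matrix S_m = W̄ (W̄ + Σ̄/m)⁻¹ with b_i = S_m · (ȳ_i − μ)."""
    out = {}
    for m in sorted(set(sizes)):
        G = np.linalg.inv(W_bar + Sigma_bar / m)
        S = W_bar @ G
        V = symmetrize(S @ (Sigma_bar / m))
        out[m] = (S, V)
    return out


def rem_loglik(ys_by_ensemble, M, W, Sigma, ridge: float = 1e-6) -> float:
    """Marginal Gaussian log-likelihood of transformed coordinates.

    Within ensemble i the stacked vectors y_i1..y_im are jointly normal with
    mean 1⊗μ and covariance I_m⊗Σ̄ + J_m⊗W̄ (J the all-ones matrix).  The
    evaluation uses det(I⊗Σ + J⊗W) = det(Σ)^{m-1} det(Σ + mW) and a Woodbury
    reduction, so only 3n×3n solves appear.

    Parameters
    ----------
    ys_by_ensemble : list of (m_i, 3n) arrays
        Transformed coordinate vectors per ensemble, vec(Y_ijᵀ) rows.
    """
    mu = vec_coords(M)
    p = mu.size
    W_bar = ridge_stabilize(symmetrize(np.asarray(W, dtype=float)), ridge)
    S_bar = ridge_stabilize(symmetrize(np.asarray(Sigma, dtype=float)), ridge)
    sign, logdet_S = np.linalg.slogdet(S_bar)
    if sign <= 0:
        raise np.linalg.LinAlgError("intra-ensemble covariance singular after ridge")
    S_inv = np.linalg.inv(S_bar)
    ll = 0.0
    shrink_cache: dict[int, tuple[np.ndarray, float]] = {}
    for Yi in ys_by_ensemble:
        Yi = np.atleast_2d(np.asarray(Yi, dtype=float))
        m = Yi.shape[0]
        if m not in shrink_cache:
            sign2, logdet_mix = np.linalg.slogdet(S_bar + m * W_bar)
            if sign2 <= 0:
                raise np.linalg.LinAlgError("marginal covariance singular after ridge")
            # correction kernel Σ̄⁻¹ V_m Σ̄⁻¹ = Σ̄⁻¹ W̄ (W̄ + Σ̄/m)⁻¹ / m
            K = S_inv @ W_bar @ np.linalg.inv(W_bar + S_bar / m) / m
            shrink_cache[m] = (K, logdet_mix)
        K, logdet_mix = shrink_cache[m]
        U = Yi - mu
        q = float(np.einsum("jk,kl,jl->", U, S_inv, U))
        s = U.sum(axis=0)
        q -= float(s @ K @ s)
        ll += -0.5 * (m * p * np.log(2 * np.pi) + (m - 1) * logdet_S + logdet_mix + q)
    return ll


def rem_loglik_from_set(es, M, W, Sigma, transforms, ridge: float = 1e-6) -> float:
    """Convenience wrapper: apply ``transforms`` to an EnsembleSet and evaluate
    :func:`rem_loglik` on the resulting per-ensemble coordinate vectors."""
    ys_by_ensemble = []
    k = 0
    for _, members in es.ensembles:
        rows = []
        for c in members:
            rows.append(vec_coords(transforms[k].apply(c.coords)))
            k += 1
        ys_by_ensemble.append(np.stack(rows))
    return rem_loglik(ys_by_ensemble, M, W, Sigma, ridge=ridge)


def _init_from_pool(es):
    """Pooled OLS superposition -> initial μ, W₀ (between-mean scatter),
    Σ₀ (pooled within scatter), transforms."""
    fit = ols_superpose(es.all_conformations(), tol=1e-8, max_iter=100)
    Y = np.stack([tr.apply(c.coords) for tr, c in zip(fit.transforms, es.all_conformations())])
    ys = Y.reshape(Y.shape[0], -1)
    idx = np.asarray([i for i, _, _ in es.members()])
    mu = ys.mean(axis=0)
    nu = es.nu
    means = np.stack([ys[idx == i].mean(axis=0) for i in range(nu)])
    Dm = means - mu
    W0 = symmetrize(Dm.T @ Dm / nu)
    Dw = ys - means[idx]
    S0 = symmetrize(Dw.T @ Dw / ys.shape[0])
    if np.trace(S0) <= 0:  # degenerate: identical members everywhere
        S0 = S0 + 1e-6 * np.eye(S0.shape[0])
    return mu, W0, S0, fit.transforms


def rem_fit(es, config: REMConfig | None = None) -> REMFit:
    """Fit the random-effects superposition model by (generalized) EM.

    Requires at least two ensembles (otherwise inter-ensemble variance is
    unidentifiable) and Σ m_i ≥ ν + 1 (otherwise W and Σ are confounded).
    """
    config = config or REMConfig()
    nu = es.nu
    sizes = es.sizes
    N = sum(sizes)
    n = es.n
    p = 3 * n
    if nu < 2:
        raise ValueError("inter-ensemble variance unidentifiable: need at least 2 ensembles")
    if N < nu + 1:
        raise ValueError(
            "W and Sigma are confounded: need sum(m_i) >= nu + 1 "
            f"(got {N} conformations in {nu} ensembles)"
        )

    Xs = es.coords_stacked()  # (N, n, 3)
    idx = np.asarray([i for i, _, _ in es.members()])

    if config.init == "ts_warm":
        from .baselines import ts_fit

        warm = ts_fit(es, first_stage="iwls")
        mu = vec_coords(warm.M_hat)
        W = warm.W_hat.copy()
        Sigma = warm.Sigma_pooled.copy()
        if np.trace(Sigma) <= 0:
            Sigma = Sigma + 1e-6 * np.eye(p)
        ts = np.stack([tr.t for tr in warm.member_transforms])
        Rs = np.stack([tr.R for tr in warm.member_transforms])
    else:
        mu, W, Sigma, transforms = _init_from_pool(es)
        ts = np.stack([tr.t for tr in transforms])
        Rs = np.stack([tr.R for tr in transforms])

    if config.seed:
        # random restart: perturb the initial superposition (the fitted
        # optimum depends on the start; seed=0 keeps the deterministic
        # pooled start, other seeds explore different basins)
        rng = np.random.default_rng(config.seed)
        E = Rotation.from_rotvec(rng.normal(scale=0.3, size=(N, 3))).as_matrix()
        Rs = Rs @ E
        ts = ts + rng.normal(scale=1.0, size=(N, 3))

    b = np.zeros((nu, p))
    V_by_size: dict[int, np.ndarray] = {}
    trace: list[float] = []
    converged = False
    m_arr = np.asarray(sizes)

    # The ridge is folded into the *initial* covariances once; afterwards the
    # EM runs on the raw stored parameters.  The Laird–Ware updates keep every
    # iterate positive definite by induction (the posterior covariance V_i
    # enters both updates additively), so all solves stay defined and each
    # cycle is an exact generalized-EM step: the posterior from the E step is
    # held fixed through the M and transform steps, each of which increases
    # the same minorant of the marginal log-likelihood.
    # In degenerate problems (Σ m_i < 3n) the ML log-likelihood is unbounded
    # and Σ can collapse numerically; each collapse is caught and the ridge
    # re-applied (counted in metadata, never triggered when Σ m_i ≥ 3n).
    W = ridge_stabilize(W, config.ridge)
    Sigma = ridge_stabilize(Sigma, config.ridge)
    n_restabilized = 0
    ys = apply_transforms_batch(Xs, ts, Rs).reshape(N, -1)
    it = 0

    for it in range(1, config.max_iter + 1):
        try:
            ll, mu, W, Sigma, b, V_by_size, ts, Rs, ys = _em_cycle(
                Xs, idx, sizes, m_arr, N, nu, n, mu, W, Sigma, b, ts, Rs, config
            )
        except np.linalg.LinAlgError:
            n_restabilized += 1
            if n_restabilized > 50:
                raise FloatingPointError(
                    f"covariance collapse not recoverable at EM iteration {it}"
                )
            ridge = config.ridge if config.ridge > 0 else 1e-6
            W = ridge_stabilize(W, ridge)
            Sigma = ridge_stabilize(Sigma, ridge)
            continue
        trace.append(ll)
        if it > 1 and len(trace) > 1 and abs(trace[-1] - trace[-2]) <= config.tol * max(
            abs(trace[-2]), 1.0
        ):
            converged = True
            break
        if not np.isfinite(ll):
            raise FloatingPointError(f"non-finite log-likelihood at EM iteration {it}")

    # refresh the posterior at the final parameters so Z_hat/V_i are
    # consistent with the returned (M_hat, W_hat, Sigma_hat, transforms)
    moments = _posterior_moments(W, Sigma, sizes)
    ybar = np.stack([ys[idx == i].mean(axis=0) for i in range(nu)])
    for i in range(nu):
        S_m, _ = moments[sizes[i]]
        b[i] = S_m @ (ybar[i] - mu)
    V_by_size = {m: V for m, (_, V) in moments.items()}

    if config.covariance_structure == "atom_block":
        # block structure is a fitting restriction; for PCA the full matrices
        # are recomputed from the final posteriors and residuals
        W = symmetrize((b.T @ b + sum(V_by_size[m] for m in sizes)) / nu)
        Rres = ys - mu - b[idx]
        Sigma = symmetrize(
            (Rres.T @ Rres + sum(sizes[i] * V_by_size[sizes[i]] for i in range(nu))) / N
        )

    member_ids = [c.id for _, _, c in es.members()]
    return REMFit(
        M_hat=unvec_coords(mu, n),
        W_hat=W,
        Sigma_hat=Sigma,
        Z_hat=[unvec_coords(b[i], n) for i in range(nu)],
        V_i=[V_by_size[sizes[i]] for i in range(nu)],
        transforms=[RigidTransform(t=ts[j], R=Rs[j]) for j in range(N)],
        loglik_trace=trace,
        n_iter=it,
        converged=converged,
        ensemble_ids=es.ensemble_ids,
        member_ids=member_ids,
        member_ensemble_index=list(idx),
        metadata={
            "method": "rem",
            "ridge": config.ridge,
            "covariance_structure": config.covariance_structure,
            "init": config.init,
            "n_restabilized": n_restabilized,
            "note": "W_hat/Sigma_hat are ML estimates; rank-deficient when nu or sum(m_i) < 3n",
        },
    )


def _em_cycle(Xs, idx, sizes, m_arr, N, nu, n, mu, W, Sigma, b, ts, Rs, config):
    """One generalized-EM cycle; returns the updated state and log-likelihood."""
    # --- E step (empirical Bayes, at the current transforms/parameters) ---
    Y = apply_transforms_batch(Xs, ts, Rs)
    ys = Y.reshape(N, -1)
    moments = _posterior_moments(W, Sigma, sizes)
    ybar = np.stack([ys[idx == i].mean(axis=0) for i in range(nu)])
    for i in range(nu):
        S_m, _ = moments[sizes[i]]
        b[i] = S_m @ (ybar[i] - mu)
    V_by_size = {m: V for m, (_, V) in moments.items()}

    # --- M step (Laird–Ware updates) ---
    mu = (ys.sum(axis=0) - m_arr @ b) / N
    W = symmetrize((b.T @ b + sum(V_by_size[m] for m in sizes)) / nu)
    Rres = ys - mu - b[idx]
    Sigma = symmetrize(
        (Rres.T @ Rres + sum(sizes[i] * V_by_size[sizes[i]] for i in range(nu))) / N
    )
    if config.covariance_structure == "atom_block":
        W = _block_diag_project(W)
        Sigma = _block_diag_project(Sigma)
    # Σ must stay invertible; the floor is a no-op unless Σ m_i - ν < 3n
    # (degenerate regime where the ML of Σ collapses).  W is never floored:
    # its ML legitimately sits on the rank-deficient boundary when ν < 3n and
    # no step requires W⁻¹.
    Sigma = clip_eigenvalues(Sigma, config.ridge)

    # --- transform step (GEM-safeguarded, under the updated parameters) ---
    # Two candidate moves per conformation, both scored with the exact full
    # Σ⁻¹-metric quadratic so the minorant never decreases: (i) the scalar
    # per-atom-weight Procrustes solution (good global moves early on), and
    # (ii) a damped Gauss-Newton step on the six rigid parameters in the full
    # metric (captures the anisotropic gauge the scalar weights cannot see).
    S_inv_new = np.linalg.inv(Sigma)
    w_atom = weights_from_sigma(Sigma)
    targets = mu + b  # superposition target per ensemble: M̂ + ẑ_i
    for i in range(nu):
        sel = np.flatnonzero(idx == i)
        T = unvec_coords(targets[i], n)
        U_old = ys[sel] - targets[i]
        q_best = np.einsum("jk,kl,jl->j", U_old, S_inv_new, U_old)
        t_best = ts[sel].copy()
        R_best = Rs[sel].copy()

        def consider(cand_t, cand_R):
            nonlocal q_best, t_best, R_best
            Y_new = apply_transforms_batch(Xs[sel], cand_t, cand_R)
            U_new = Y_new.reshape(len(sel), -1) - targets[i]
            q_new = np.einsum("jk,kl,jl->j", U_new, S_inv_new, U_new)
            better = q_new < q_best - 1e-12 * np.abs(q_best)
            q_best[better] = q_new[better]
            t_best[better] = cand_t[better]
            R_best[better] = cand_R[better]

        consider(*optimal_transforms_batch(Xs[sel], T, w_atom))
        # Gauss-Newton in the full metric; Jacobian linearised at the target
        # (J exactness is irrelevant for monotonicity -- only the exact
        # q-comparison in consider() decides acceptance)
        J = np.zeros((3 * n, 6))
        J[0::3, 0] = J[1::3, 1] = J[2::3, 2] = -1.0
        for a in range(n):
            J[3 * a : 3 * a + 3, 3:6] = _skew(T[a])
        SJ = S_inv_new @ J
        H = J.T @ SJ
        U_cur = (apply_transforms_batch(Xs[sel], t_best, R_best).reshape(len(sel), -1)
                 - targets[i])
        g = U_cur @ SJ  # (m, 6)
        try:
            delta = -np.linalg.solve(H, g.T).T
        except np.linalg.LinAlgError:
            delta = None
        if delta is not None:
            for lam in (1.0, 0.25):
                dt_local = lam * delta[:, :3]
                omega = lam * delta[:, 3:]
                E = Rotation.from_rotvec(omega).as_matrix()
                cand_R = R_best @ E
                cand_t = t_best + np.einsum("jkl,jl->jk", R_best, dt_local)
                consider(cand_t, cand_R)
        ts[sel] = t_best
        Rs[sel] = R_best
    Y = apply_transforms_batch(Xs, ts, Rs)
    ys = Y.reshape(N, -1)

    # --- gauge: recentre μ, absorb the shift into translations ---
    Mmat = unvec_coords(mu, n)
    c = Mmat.mean(axis=0)
    if np.any(np.abs(c) > 0):
        mu = vec_coords(Mmat - c)
        ts = ts + np.einsum("k,jlk->jl", c, Rs)
        ys = ys - np.tile(c, n)

    ll = rem_loglik(
        [ys[idx == i] for i in range(nu)],
        unvec_coords(mu, n),
        W,
        Sigma,
        ridge=0.0,  # iterates are PD by construction; evaluate exactly
    )
    return ll, mu, W, Sigma, b, V_by_size, ts, Rs, ys


def posterior_ensemble_means(fit: REMFit) -> list[np.ndarray]:
    """Empirical-Bayes ensemble mean structures ``M̂ + Ẑ_i``.

    Each Ẑ_i is shrunken toward zero relative to the raw ensemble-mean
    deviation, the more so the smaller the ensemble — the source of the
    method's advantage at small m_i.
    """
    return [fit.M_hat + Z for Z in fit.Z_hat]
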