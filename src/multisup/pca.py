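"""Eigen-analysis of estimated covariance matrices and interpretation tools.

The eigenvectors of the inter-ensemble covariance Ŵ separate the ensembles
(e.g. enzymes of different active-site size); those of the intra-ensemble
covariance Σ̂ describe variability shared across ensembles after the
between-ensemble differences have been adjusted out (e.g. a common
open/close motion).  Scores are in Å, eigenvalues in Å².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from ._linalg import unvec_coords, vec_coords

__all__ = [
    "PCAModel",
    "eigendecompose",
    "project_structures",
    "per_residue_displacement",
    "reconstruct_extreme",
    "extreme_series",
    "rmsip",
    "mae_sqrt_diag",
    "pairwise_distance_metrics",
    "align_to_reference",
]


@dataclass
class PCAModel:
    eigenvalues: np.ndarray  # (K,) descending, Å²
    eigenvectors: np.ndarray  # (3n, K) orthonormal columns
    source: str = ""
    sign_rule: str = "largest_abs_positive"

    @property
    def n(self) -> int:
        return self.eigenvectors.shape[0] // 3


def eigendecompose(C: np.ndarray, K: int | None = None, source: str = "") -> PCAModel:
    """Top-K eigenpairs of a symmetric 3n×3n covariance.

    Eigenvalues within -1e-8·tr(C) of zero are clipped to 0.  Each
    eigenvector's largest-|component| entry is made positive (ties broken by
    lowest index), which fixes the sign indeterminacy deterministically.
    """
    C = np.asarray(C, dtype=float)
    if not np.allclose(C, C.T, atol=1e-8 * max(1.0, np.abs(C).max())):
        raise ValueError("covariance matrix is not symmetric")
    p = C.shape[0]
    K = p if K is None else int(K)
    if K > p:
        raise ValueError(f"K={K} exceeds matrix dimension {p}")
    vals, vecs = scipy.linalg.eigh(0.5 * (C + C.T))
    order = np.argsort(vals)[::-1][:K]
    vals = vals[order]
    vecs = vecs[:, order]
    tol = 1e-8 * max(np.trace(C), 0.0)
    vals = np.where((vals < 0) & (vals >= -tol), 0.0, vals)
    for k in range(vecs.shape[1]):
        j = int(np.argmax(np.abs(vecs[:, k])))
        if vecs[j, k] < 0:
            vecs[:, k] *= -1
    return PCAModel(eigenvalues=vals, eigenvectors=vecs, source=source)


def _aligned_vectors(es, fit) -> tuple[np.ndarray, list[str], list[str], np.ndarray]:
    """Apply the fit's transforms to the dataset; return (N,3n) vectors plus labels."""
    ys, ids, eids, idx = [], [], [], []
    for k, (i, eid, conf) in enumerate(es.members()):
        ys.append(vec_coords(fit_transform(fit, k).apply(conf.coords)))
        ids.append(conf.id)
        eids.append(eid)
        idx.append(i)
    return np.stack(ys), ids, eids, np.asarray(idx)


def fit_transform(fit, k: int):
    """Per-member transform list across fit flavours (REM/TS/SPE/Single)."""
    for attr in ("transforms", "member_transforms"):
        trs = getattr(fit, attr, None)
        if trs is not None:
            return trs[k]
    raise AttributeError("fit object exposes no transforms")


def project_structures(es, fit, model: PCAModel, mode: str = "total") -> pd.DataFrame:
    """PC scores of every conformation.

    ``mode='total'`` projects y_ij − μ̂ (appropriate for Δ̂- and Ŵ-derived
    models); ``mode='within'`` projects y_ij − μ̂ − ẑ_i, the intra-ensemble
    residual (appropriate for Σ̂ models).  Returns a table with one row per
    conformation and columns PC1..PCK (Å).
    """
    if model.eigenvectors.shape[0] != 3 * es.n:
        raise ValueError("PCA model and dataset disagree on atom count")
    ys, ids, eids, idx = _aligned_vectors(es, fit)
    mu = vec_coords(fit.M_hat)
    D = ys - mu
    if mode == "within":
        Z = getattr(fit, "Z_hat", None)
        if Z is None:
            raise ValueError("within-mode projection requires a fit with ensemble deviations")
        D = D - np.stack([vec_coords(Z[i]) for i in idx])
    elif mode != "total":
        raise ValueError("mode must be 'total' or 'within'")
    scores = D @ model.eigenvectors
    out = pd.DataFrame(
        scores, columns=[f"PC{k + 1}" for k in range(scores.shape[1])]
    )
    out.insert(0, "ensemble", eids)
    out.insert(0, "id", ids)
    return out


def per_residue_displacement(model: PCAModel, pc: int, scores) -> np.ndarray:
    """Average per-residue displacement along one PC, in Å.

    For atom a: d_a = sqrt(mean_j s_j²) · ‖(u_pc)_a‖, i.e. the RMS score over
    structures scaled by the eigenvector's weight on that atom.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score list")
    if not 1 <= pc <= model.eigenvectors.shape[1]:
        raise ValueError(f"pc must be in 1..{model.eigenvectors.shape[1]}")
    u = unvec_coords(model.eigenvectors[:, pc - 1])
    rms = float(np.sqrt(np.mean(scores**2)))
    return rms * np.linalg.norm(u, axis=1)


def reconstruct_extreme(M_hat: np.ndarray, model: PCAModel, pc: int, score: float) -> np.ndarray:
    """Structure at a given score along one PC: M̂ + score · u_pc (n×3)."""
    u = unvec_coords(model.eigenvectors[:, pc - 1])
    return np.asarray(M_hat, dtype=float) + float(score) * u


def extreme_series(M_hat, model, pc, score_min, score_max, n_frames: int = 11):
    """Linear interpolation between two extreme scores, for animation output."""
    return [
        reconstruct_extreme(M_hat, model, pc, s)
        for s in np.linspace(score_min, score_max, n_frames)
    ]


def rmsip(U: np.ndarray, V: np.ndarray) -> float:
    """Root mean squared inner product of two k-dimensional orthonormal bases.

    sqrt((1/k) Σ_i Σ_j (u_iᵀ v_j)²); 1 for identical subspaces, 0 for
    orthogonal ones.  Invariant to rotations within each subspace.
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if U.shape != V.shape:
        raise ValueError("subspaces must have the same shape")
    for B in (U, V):
        G = B.T @ B
        if not np.allclose(G, np.eye(B.shape[1]), atol=1e-6):
            raise ValueError("columns must be orthonormal (within 1e-6)")
    k = U.shape[1]
    return float(np.sqrt(np.sum((U.T @ V) ** 2) / k))


def mae_sqrt_diag(C_hat: np.ndarray, C_true: np.ndarray) -> float:
    """Mean absolute error of per-coordinate standard deviations, in Å."""
    C_hat = np.asarray(C_hat, dtype=float)
    C_true = np.asarray(C_true, dtype=float)
    if C_hat.shape != C_true.shape:
        raise ValueError("shape mismatch")
    out = []
    for C in (C_hat, C_true):
        d = np.diagonal(C).copy()
        tol = 1e-8 * max(np.trace(C), 1.0)
        if np.any(d < -tol):
            raise ValueError("negative diagonal beyond tolerance")
        out.append(np.sqrt(np.clip(d, 0.0, None)))
    return float(np.mean(np.abs(out[0] - out[1])))


def pairwise_distance_metrics(es, pairs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-conformation distances between atom/centroid selections, in Å.

    ``pairs`` is a list of (selection_a, selection_b, kind) with selections as
    lists of 0-based atom (column) indices; kind 'atom' requires singleton
    selections, 'centroid' averages each selection first.  Distances need no
    superposition (rigid-motion invariant).  Returns (per-conformation table,
    per-ensemble averages).
    """
    norm_pairs = []
    for k, (sa, sb, kind) in enumerate(pairs):
        sa = [int(i) for i in np.atleast_1d(sa)]
        sb = [int(i) for i in np.atleast_1d(sb)]
        if kind == "atom" and (len(sa) != 1 or len(sb) != 1):
            raise ValueError("kind='atom' requires singleton selections")
        if kind not in ("atom", "centroid"):
            raise ValueError(f"unknown selection kind {kind!r}")
        for sel in (sa, sb):
            for i in sel:
                if not 0 <= i < es.n:
                    raise ValueError(f"selection index {i} outside 0..{es.n - 1}")
        norm_pairs.append((sa, sb, f"dist{k + 1}"))
    rows = []
    for _, eid, conf in es.members():
        row = {"id": conf.id, "ensemble": eid}
        for sa, sb, name in norm_pairs:
            pa = conf.coords[sa].mean(axis=0)
            pb = conf.coords[sb].mean(axis=0)
            row[name] = float(np.linalg.norm(pa - pb))
        rows.append(row)
    per_conf = pd.DataFrame(rows)
    per_ens = per_conf.drop(columns="id").groupby("ensemble", sort=False).mean().reset_index()
    return per_conf, per_ens


def align_to_reference(M_hat: np.ndarray, M_ref: np.ndarray, covariances=()):
    """Gauge-fix a fit to a reference frame.

    Finds the rigid transform superposing ``M_hat`` onto ``M_ref`` (unit
    weights) and returns the transformed mean together with each covariance
    rotated into that frame.  Covariance eigenvalues are unchanged; use this
    before comparing diagonals or eigenvectors against a ground truth
    expressed in another frame.
    """
    from ._linalg import rotate_covariance
    from .superpose import optimal_transform

    tr = optimal_transform(M_hat, M_ref)
    M_aligned = tr.apply(M_hat)
    covs = [rotate_covariance(np.asarray(C, dtype=float), tr.R) for C in covariances]
    return M_aligned, covs, tr
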