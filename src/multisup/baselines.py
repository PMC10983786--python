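"""Two-stage (TS) and single-pooled-ensemble (SPE) baseline estimators.

TS treats the ensemble deviations as fixed effects: stage 1 superposes each
ensemble separately (IWLS or OLS), stage 2 superposes the stage-1 mean
structures by IWLS, giving M̂ and the inter-ensemble covariance Ŵ; the
intra-ensemble covariance is the pooled stage-1 covariance.  SPE ignores the
grouping entirely and IWLS-fits a single ensemble, estimating one covariance
Δ; for data that truly follow the two-level model, Δ ≈ W + Σ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._linalg import rotate_covariance, symmetrize
from .superpose import (
    RigidTransform,
    SingleFit,
    iwls_superpose,
    ols_superpose,
    sample_covariance,
)

__all__ = ["TSFit", "SPEFit", "ts_fit", "spe_fit"]


@dataclass
class TSFit:
    M_hat: np.ndarray
    W_hat: np.ndarray
    Sigma_pooled: np.ndarray
    stage1: list[SingleFit | None]
    stage2_transforms: list[RigidTransform]
    member_transforms: list[RigidTransform]
    Z_hat: list[np.ndarray]
    ensemble_ids: list[str] = field(default_factory=list)
    stage1_flags: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


@dataclass
class SPEFit:
    M_hat: np.ndarray
    Delta_hat: np.ndarray
    transforms: list[RigidTransform]
    fit: SingleFit | None = None
    metadata: dict = field(default_factory=dict)


def ts_fit(
    es,
    first_stage: str = "iwls",
    tol: float = 1e-8,
    max_iter: int = 200,
    pooling_weights: str = "dof",
    stage2_divisor: str = "ml",
) -> TSFit:
    """Two-stage fixed-effects fit.

    Stage 1 fits each ensemble with IWLS or OLS (``first_stage``); singleton
    ensembles contribute their lone structure as a mean and no covariance.
    Stage-1 covariances are rotated into the stage-2 frame before pooling,
    weighted by degrees of freedom m_i - 1 (``pooling_weights='dof'``) or by
    m_i (``'size'``).  Stage-1 non-convergence is flagged per ensemble, not
    fatal; if every stage fails the fit errors out.
    """
    if es.nu < 2:
        raise ValueError("two-stage fit needs at least 2 ensembles")
    if first_stage not in ("iwls", "ols"):
        raise ValueError("first_stage must be 'iwls' or 'ols'")
    superpose = iwls_superpose if first_stage == "iwls" else ols_superpose

    stage1: list[SingleFit | None] = []
    flags: list[str] = []
    means: list[np.ndarray] = []
    n_failed = 0
    for eid, members in es.ensembles:
        if len(members) == 1:
            x = members[0].coords
            means.append(x - x.mean(axis=0))
            stage1.append(None)
            flags.append("singleton: mean only, no stage-1 covariance")
            continue
        try:
            fit = superpose(members, tol=tol, max_iter=max_iter)
        except (ValueError, np.linalg.LinAlgError, FloatingPointError) as exc:
            stage1.append(None)
            flags.append(f"stage-1 failed: {exc}")
            means.append(members[0].coords - members[0].coords.mean(axis=0))
            n_failed += 1
            continue
        stage1.append(fit)
        flags.append("" if fit.converged else "stage-1 did not converge")
        means.append(fit.M_hat)
    if n_failed == es.nu:
        raise ValueError("all stage-1 fits failed")

    stage2 = iwls_superpose(means, tol=tol, max_iter=max_iter)
    aligned_means = [tr.apply(m) for tr, m in zip(stage2.transforms, means)]
    W_hat = sample_covariance(aligned_means, stage2.M_hat, divisor=stage2_divisor)

    # pool stage-1 covariances, rotated into the stage-2 frame
    num = np.zeros_like(W_hat)
    den = 0.0
    for fit, tr, (eid, members) in zip(stage1, stage2.transforms, es.ensembles):
        if fit is None:
            continue
        m = len(members)
        wgt = (m - 1) if pooling_weights == "dof" else m
        num += wgt * rotate_covariance(fit.Sigma_hat, tr.R)
        den += wgt
    Sigma_pooled = symmetrize(num / den) if den > 0 else np.zeros_like(W_hat)

    member_transforms: list[RigidTransform] = []
    for fit, tr, (eid, members) in zip(stage1, stage2.transforms, es.ensembles):
        for j, c in enumerate(members):
            if fit is None:
                t1 = RigidTransform(t=c.coords.mean(axis=0), R=np.eye(3))
            else:
                t1 = fit.transforms[j]
            member_transforms.append(t1.compose(tr))

    Z_hat = [am - stage2.M_hat for am in aligned_means]
    return TSFit(
        M_hat=stage2.M_hat,
        W_hat=W_hat,
        Sigma_pooled=Sigma_pooled,
        stage1=stage1,
        stage2_transforms=list(stage2.transforms),
        member_transforms=member_transforms,
        Z_hat=Z_hat,
        ensemble_ids=es.ensemble_ids,
        stage1_flags=flags,
        metadata={
            "method": f"ts-{first_stage}",
            "stage2_divisor": stage2_divisor,
            "pooling_weights": pooling_weights,
            "n_stage1_failed": n_failed,
        },
    )


def spe_fit(es, tol: float = 1e-8, max_iter: int = 200) -> SPEFit:
    """Single-pooled-ensemble fit: IWLS over all members, grouping ignored.

    Invariant to ensemble labelling by construction.  The estimated Δ̂ mixes
    inter- and intra-ensemble variability (Δ ≈ W + Σ under the two-level
    model).
    """
    members = es.all_conformations()
    if len(members) < 2:
        raise ValueError("need at least 2 conformations in total")
    fit = iwls_superpose(members, tol=tol, max_iter=max_iter)
    return SPEFit(
        M_hat=fit.M_hat,
        Delta_hat=fit.Sigma_hat,
        transforms=list(fit.transforms),
        fit=fit,
        metadata={"method": "spe"},
    )
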