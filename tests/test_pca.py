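"""Eigen-analysis, projections, displacement profiles, RMSIP, distances."""

import numpy as np
import pytest

from multisup.ensemble_io import Conformation, EnsembleSet
from multisup.pca import (
    eigendecompose,
    extreme_series,
    mae_sqrt_diag,
    pairwise_distance_metrics,
    per_residue_displacement,
    project_structures,
    reconstruct_extreme,
    rmsip,
)
from multisup._linalg import symmetrize
from conftest import random_rigid, toy_structure


class TestEigendecompose:
    def test_diagonal_matrix(self):
        C = np.diag([4.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        model = eigendecompose(C, K=3)
        assert np.allclose(model.eigenvalues, [4.0, 1.0, 0.0])
        assert abs(model.eigenvectors[0, 0]) == pytest.approx(1.0)
        assert abs(model.eigenvectors[1, 1]) == pytest.approx(1.0)

    def test_rank_one(self, rng):
        v = rng.standard_normal(9)
        model = eigendecompose(np.outer(v, v), K=1)
        assert model.eigenvalues[0] == pytest.approx(v @ v)
        u = model.eigenvectors[:, 0]
        assert abs(abs(u @ v) - np.linalg.norm(v)) < 1e-10

    def test_full_spectral_reconstruction(self, rng):
        A = rng.standard_normal((12, 12))
        C = symmetrize(A @ A.T)
        model = eigendecompose(C, K=12)
        rec = model.eigenvectors @ np.diag(model.eigenvalues) @ model.eigenvectors.T
        assert np.allclose(rec, C, atol=1e-8)

    def test_sign_rule_deterministic(self, rng):
        A = rng.standard_normal((9, 9))
        C = symmetrize(A @ A.T)
        m1 = eigendecompose(C, K=4)
        m2 = eigendecompose(C.copy(), K=4)
        assert np.array_equal(m1.eigenvectors, m2.eigenvectors)
        for k in range(4):
            u = m1.eigenvectors[:, k]
            assert u[np.argmax(np.abs(u))] > 0

    def test_nonsymmetric_rejected(self):
        C = np.arange(16.0).reshape(4, 4)
        with pytest.raises(ValueError, match="symmetric"):
            eigendecompose(C)


def _fit_stub(M, Z_list=None, transforms=None, N=None):
    from types import SimpleNamespace

    from multisup.superpose import RigidTransform

    if transforms is None:
        transforms = [RigidTransform.identity()] * N
    return SimpleNamespace(M_hat=M, Z_hat=Z_list, transforms=transforms)


class TestProjections:
    def _setup(self, rng, n=5):
        M = toy_structure(n, seed=2)
        C = symmetrize(rng.standard_normal((3 * n, 3 * n)))
        model = eigendecompose(C @ C.T, K=3)
        return M, model

    def test_mean_projects_to_zero(self, rng):
        M, model = self._setup(rng)
        es = EnsembleSet([("e", [Conformation(id="a", coords=M),
                                 Conformation(id="b", coords=M)])])
        scores = project_structures(es, _fit_stub(M, N=2), model, mode="total")
        assert np.allclose(scores[["PC1", "PC2", "PC3"]].to_numpy(), 0, atol=1e-10)

    def test_injected_mode_recovered_exactly(self, rng):
        M, model = self._setup(rng)
        c = 1.7
        u1 = model.eigenvectors[:, 0].reshape(-1, 3)
        es = EnsembleSet([("e", [Conformation(id="a", coords=M + c * u1),
                                 Conformation(id="b", coords=M)])])
        scores = project_structures(es, _fit_stub(M, N=2), model, mode="total")
        assert scores.loc[0, "PC1"] == pytest.approx(c, abs=1e-10)
        assert scores.loc[0, "PC2"] == pytest.approx(0.0, abs=1e-10)

    def test_within_mode_subtracts_ensemble_deviation(self, rng):
        M, model = self._setup(rng)
        Z = 0.9 * model.eigenvectors[:, 1].reshape(-1, 3)
        es = EnsembleSet([("e", [Conformation(id="a", coords=M + Z)])])
        total = project_structures(es, _fit_stub(M, [Z], N=1), model, mode="total")
        within = project_structures(es, _fit_stub(M, [Z], N=1), model, mode="within")
        assert total.loc[0, "PC2"] == pytest.approx(0.9, abs=1e-10)
        assert within.loc[0, "PC2"] == pytest.approx(0.0, abs=1e-10)

    def test_within_mode_requires_deviations(self, rng):
        M, model = self._setup(rng)
        es = EnsembleSet([("e", [Conformation(id="a", coords=M)])])
        with pytest.raises(ValueError, match="within"):
            project_structures(es, _fit_stub(M, None, N=1), model, mode="within")

    def test_within_scores_of_rem_fit_sum_to_zero_per_ensemble(self):
        """With balanced ensembles the posterior deviations absorb the
        ensemble means, so within-mode scores average out per ensemble."""
        from multisup.rem import REMConfig, rem_fit
        from conftest import small_ensemble_set

        es = small_ensemble_set(nu=3, m=6, n=8, noise=0.3, seed=12)
        fit = rem_fit(es, REMConfig(tol=1e-10, max_iter=400))
        model = eigendecompose(fit.Sigma_hat, K=2)
        scores = project_structures(es, fit, model, mode="within")
        sums = scores.groupby("ensemble")[["PC1", "PC2"]].mean()
        assert np.abs(sums.to_numpy()).max() < 1e-4


class TestDisplacement:
    def test_concentrated_eigenvector(self):
        u = np.zeros(18)
        u[15] = 1.0  # atom 5, x-axis
        model = eigendecompose(np.outer(u, u), K=1)
        d = per_residue_displacement(model, 1, [1.0, -1.0])
        assert d[5] == pytest.approx(1.0)
        assert np.allclose(np.delete(d, 5), 0)

    def test_uniform_eigenvector_constant_profile(self):
        n = 6
        u = np.ones(3 * n) / np.sqrt(3 * n)
        model = eigendecompose(np.outer(u, u), K=1)
        d = per_residue_displacement(model, 1, [-1.0, 1.0])
        assert np.allclose(d, np.linalg.norm(u[:3]))

    def test_hinge_truth_displaces_both_domains(self):
        """The superposed image of a hinge bend moves both domains (they
        counter-rotate after superposition), with quiet nodes where the chain
        crosses the axis of the compensating rotation."""
        from multisup.simulate import make_truth

        n = 24
        _, W, _ = make_truth(n, "hinge", scale=0.5, seed=3)
        model = eigendecompose(W, K=1)
        d = per_residue_displacement(model, 1, [1.0])
        half = n // 2
        assert d[:half].max() > 5 * d.min()
        assert d[half:].max() > 5 * d.min()

    def test_injected_local_mode_peaks_in_injected_range(self):
        """A mode concentrated on residues 10-20 produces a displacement
        profile peaking inside that range."""
        n = 30
        rng = np.random.default_rng(7)
        u = np.zeros((n, 3))
        idx = np.arange(10, 21)
        u[idx] = np.sin(np.pi * (idx - 10) / 10)[:, None] * rng.standard_normal(3)
        v = u.ravel() / np.linalg.norm(u)
        model = eigendecompose(np.outer(v, v), K=1)
        d = per_residue_displacement(model, 1, [1.0, -0.5, 0.8])
        assert 10 <= int(np.argmax(d)) <= 20
        assert d[idx].sum() > 0.99 * d.sum()

    def test_empty_scores_rejected(self):
        model = eigendecompose(np.eye(6), K=1)
        with pytest.raises(ValueError, match="empty"):
            per_residue_displacement(model, 1, [])


class TestExtremes:
    def test_zero_score_returns_mean(self, rng):
        M = toy_structure(4)
        model = eigendecompose(np.eye(12), K=2)
        assert np.allclose(reconstruct_extreme(M, model, 1, 0.0), M)

    def test_linearity_midpoint(self, rng):
        M = toy_structure(4)
        model = eigendecompose(symmetrize(np.diag(np.arange(1.0, 13.0))), K=2)
        hi = reconstruct_extreme(M, model, 1, 2.5)
        lo = reconstruct_extreme(M, model, 1, -2.5)
        assert np.allclose(0.5 * (hi + lo), M, atol=1e-12)

    def test_projection_round_trip(self, rng):
        M = toy_structure(5)
        A = rng.standard_normal((15, 15))
        model = eigendecompose(symmetrize(A @ A.T), K=3)
        s = 1.234
        S = reconstruct_extreme(M, model, 2, s)
        back = model.eigenvectors.T @ (S - M).ravel()
        assert back[1] == pytest.approx(s, abs=1e-10)
        assert back[0] == pytest.approx(0.0, abs=1e-10)

    def test_series_endpoints_and_length(self):
        M = toy_structure(4)
        model = eigendecompose(np.eye(12), K=1)
        frames = extreme_series(M, model, 1, -1.0, 1.0, n_frames=5)
        assert len(frames) == 5
        assert np.allclose(frames[2], M)


class TestRMSIP:
    def test_identical_subspaces(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((10, 2)))
        assert rmsip(Q, Q) == pytest.approx(1.0)

    def test_orthogonal_subspaces(self):
        U = np.eye(8)[:, :2]
        V = np.eye(8)[:, 4:6]
        assert rmsip(U, V) == pytest.approx(0.0)

    def test_sixty_degrees_single_vector(self):
        u = np.array([[1.0], [0.0], [0.0]])
        v = np.array([[np.cos(np.pi / 3)], [np.sin(np.pi / 3)], [0.0]])
        assert rmsip(u, v) == pytest.approx(0.5, abs=1e-12)

    def test_symmetric_and_rotation_invariant(self, rng):
        Q1, _ = np.linalg.qr(rng.standard_normal((12, 3)))
        Q2, _ = np.linalg.qr(rng.standard_normal((12, 3)))
        assert rmsip(Q1, Q2) == pytest.approx(rmsip(Q2, Q1), abs=1e-12)
        G, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        assert rmsip(Q1 @ G, Q2) == pytest.approx(rmsip(Q1, Q2), abs=1e-10)

    def test_nonorthonormal_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            rmsip(np.ones((6, 2)), np.ones((6, 2)))


class TestMAE:
    def test_zero_for_identical(self, rng):
        A = rng.standard_normal((6, 6))
        C = symmetrize(A @ A.T)
        assert mae_sqrt_diag(C, C) == 0.0

    def test_constant_gap(self):
        assert mae_sqrt_diag(4.0 * np.eye(9), np.eye(9)) == pytest.approx(1.0)

    def test_matches_loop_oracle(self, rng):
        A = rng.standard_normal((8, 8))
        B = rng.standard_normal((8, 8))
        C1, C2 = symmetrize(A @ A.T), symmetrize(B @ B.T)
        oracle = np.mean([abs(np.sqrt(C1[k, k]) - np.sqrt(C2[k, k])) for k in range(8)])
        assert mae_sqrt_diag(C1, C2) == pytest.approx(oracle, abs=1e-12)

    def test_negative_diagonal_rejected(self):
        C = np.eye(4)
        bad = C.copy()
        bad[0, 0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            mae_sqrt_diag(bad, C)


class TestDistances:
    def _set(self):
        coords = np.array([[0.0, 0, 0], [3, 4, 0], [2, 0, 0], [1, 4, 0]])
        return EnsembleSet([("e", [Conformation(id="c", coords=coords)])])

    def test_atom_pair(self):
        per_conf, per_ens = pairwise_distance_metrics(self._set(), [([0], [1], "atom")])
        assert per_conf.loc[0, "dist1"] == pytest.approx(5.0)
        assert per_ens.loc[0, "dist1"] == pytest.approx(5.0)

    def test_centroid_pair(self):
        per_conf, _ = pairwise_distance_metrics(self._set(), [([0, 2], [3], "centroid")])
        assert per_conf.loc[0, "dist1"] == pytest.approx(4.0)

    def test_rigid_motion_invariance(self, rng):
        es = self._set()
        tr = random_rigid(rng)
        moved = EnsembleSet([
            ("e", [Conformation(id="c", coords=tr.apply(es.all_conformations()[0].coords))])
        ])
        pairs = [([0], [1], "atom"), ([0, 2], [1, 3], "centroid")]
        a, _ = pairwise_distance_metrics(es, pairs)
        b, _ = pairwise_distance_metrics(moved, pairs)
        assert np.allclose(a[["dist1", "dist2"]], b[["dist1", "dist2"]], atol=1e-9)

    def test_per_ensemble_average(self):
        c1 = Conformation(id="a", coords=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]))
        c2 = Conformation(id="b", coords=np.array([[0.0, 0, 0], [3, 0, 0], [0, 1, 0]]))
        es = EnsembleSet([("e", [c1, c2])])
        _, per_ens = pairwise_distance_metrics(es, [([0], [1], "atom")])
        assert per_ens.loc[0, "dist1"] == pytest.approx(2.0)

    def test_bad_selection_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            pairwise_distance_metrics(self._set(), [([0], [99], "atom")])
        with pytest.raises(ValueError, match="singleton"):
            pairwise_distance_metrics(self._set(), [([0, 1], [2], "atom")])
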