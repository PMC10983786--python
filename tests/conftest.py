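"""Shared fixtures: hand-written PDB text, small ensembles, rigid motions."""

from __future__ import annotations

import numpy as np
import pytest

from multisup.ensemble_io import Conformation, EnsembleSet
from multisup.superpose import RigidTransform


def make_pdb_text(records, chain="A"):
    """Minimal PDB ATOM records, one Cα per (resnum, x, y, z[, altloc]) tuple."""
    lines = []
    for i, rec in enumerate(records, start=1):
        resnum, x, y, z = rec[:4]
        altloc = rec[4] if len(rec) > 4 else " "
        lines.append(
            f"ATOM  {i:5d}  CA {altloc}GLY {chain}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def tri_pdb(tmp_path):
    """3-residue chain A with Cα at (0,0,0), (1,0,0), (0,1,0)."""
    p = tmp_path / "tri.pdb"
    p.write_text(make_pdb_text([(1, 0.0, 0.0, 0.0), (2, 1.0, 0.0, 0.0), (3, 0.0, 1.0, 0.0)]))
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    q = rng.standard_normal(4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def random_rigid(rng, translation_scale=5.0) -> RigidTransform:
    return RigidTransform(
        t=translation_scale * rng.standard_normal(3), R=random_rotation(rng)
    )


def scramble(conf: Conformation, rng, translation_scale=5.0) -> Conformation:
    """Hide a conformation behind a random rigid motion (inverse of the model's
    transform, so that fitting can recover the original frame)."""
    tr = random_rigid(rng, translation_scale)
    return Conformation(id=conf.id, coords=conf.coords @ tr.R.T + tr.t)


def toy_structure(n=8, seed=0) -> np.ndarray:
    r = np.random.default_rng(seed)
    X = np.cumsum(r.normal(scale=1.5, size=(n, 3)), axis=0) + 3.8 * np.arange(n)[:, None] * np.array([1.0, 0, 0])
    return X - X.mean(axis=0)


def small_ensemble_set(nu=3, m=4, n=8, noise=0.3, seed=0, scrambled=True) -> EnsembleSet:
    """Cheap hierarchical dataset: shared mean, per-ensemble offset, iid noise."""
    r = np.random.default_rng(seed)
    M = toy_structure(n, seed)
    ensembles = []
    for i in range(nu):
        Z = r.normal(scale=noise, size=(n, 3))
        members = []
        for j in range(m):
            Y = M + Z + r.normal(scale=noise, size=(n, 3))
            conf = Conformation(id=f"e{i}s{j}", coords=Y)
            if scrambled:
                conf = scramble(conf, r)
            members.append(conf)
        ensembles.append((f"ens{i}", members))
    return EnsembleSet(ensembles)
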