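"""On-disk artifacts for fits: covariance containers, transform tables, traces.

A covariance is stored as ``<base>.npy`` (dense, float64) with a ``<base>.json``
sidecar recording the atom count, the vec(Aᵀ) index convention and provenance;
transforms as a TSV (id, ensemble, t1..t3, R row-major); the mean structure as
a single-conformation coordinate table plus a Cα-trace PDB.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble_io import Conformation, EnsembleSet, write_coordinate_table, write_superposed_pdb
from .superpose import RigidTransform

__all__ = [
    "save_covariance",
    "load_covariance",
    "save_covariance_text",
    "save_fit",
    "load_fit_dir",
]


def save_covariance(C: np.ndarray, base, *, n: int, source: str, method: str,
                    divisor: str = "ml") -> None:
    base = Path(base)
    np.save(base.with_suffix(".npy"), np.asarray(C, dtype=np.float64))
    meta = {
        "n_atoms": n,
        "dim": 3 * n,
        "index_convention": "vec(A^T): (atom a, axis k in xyz) -> 3a+k",
        "source": source,
        "method": method,
        "divisor": divisor,
        "units": "angstrom^2",
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def save_covariance_text(C: np.ndarray, path) -> None:
    """Plain-text dump of a covariance matrix (diff-able; sensible for small n)."""
    np.savetxt(path, np.asarray(C, dtype=float), fmt="%.10g", delimiter="\t")


def load_covariance(base) -> tuple[np.ndarray, dict]:
    base = Path(base)
    C = np.load(base.with_suffix(".npy"))
    meta = json.loads(base.with_suffix(".json").read_text())
    return C, meta


def _transforms_frame(ids, ensembles, transforms) -> pd.DataFrame:
    rows = []
    for cid, eid, tr in zip(ids, ensembles, transforms):
        row = {"id": cid, "ensemble": eid}
        row.update({f"t{k+1}": tr.t[k] for k in range(3)})
        row.update({f"r{a+1}{b+1}": tr.R[a, b] for a in range(3) for b in range(3)})
        rows.append(row)
    return pd.DataFrame(rows)


def save_fit(fit, es: EnsembleSet, outdir, method: str) -> None:
    """Write the artifact set for a REM/TS/SPE fit into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = es.n

    mean_conf = Conformation(id="mean", coords=fit.M_hat)
    mean_set = EnsembleSet([("mean", [mean_conf])])
    write_coordinate_table(mean_set, outdir / "mean.tsv")
    write_superposed_pdb([mean_conf], [RigidTransform.identity()], outdir / "mean.pdb")

    if method == "rem":
        save_covariance(fit.W_hat, outdir / "W", n=n, source="W", method=method)
        save_covariance(fit.Sigma_hat, outdir / "Sigma", n=n, source="Sigma", method=method)
        np.save(outdir / "Z.npy", np.stack(fit.Z_hat))
        pd.DataFrame(
            {"iteration": np.arange(1, len(fit.loglik_trace) + 1),
             "loglik": fit.loglik_trace}
        ).to_csv(outdir / "loglik.csv", index=False)
        transforms = fit.transforms
    elif method in ("ts-iwls", "ts-ols"):
        save_covariance(fit.W_hat, outdir / "W", n=n, source="W", method=method)
        save_covariance(fit.Sigma_pooled, outdir / "Sigma", n=n, source="Sigma", method=method)
        np.save(outdir / "Z.npy", np.stack(fit.Z_hat))
        transforms = fit.member_transforms
    elif method == "spe":
        save_covariance(fit.Delta_hat, outdir / "Delta", n=n, source="Delta", method=method)
        transforms = fit.transforms
    else:
        raise ValueError(f"unknown method {method!r}")

    ids = [c.id for _, _, c in es.members()]
    eids = [eid for _, eid, _ in es.members()]
    _transforms_frame(ids, eids, transforms).to_csv(
        outdir / "transforms.tsv", sep="\t", index=False
    )
    report = {
        "method": method,
        "n_atoms": n,
        "nu": es.nu,
        "sizes": es.sizes,
        "converged": bool(getattr(fit, "converged", True)),
        "n_iter": int(getattr(fit, "n_iter", 0)),
        "metadata": {k: v for k, v in getattr(fit, "metadata", {}).items()
                     if isinstance(v, (str, int, float, bool))},
    }
    if hasattr(fit, "stage1_flags"):
        report["stage1_flags"] = fit.stage1_flags
    (outdir / "report.json").write_text(json.dumps(report, indent=1))


def load_fit_dir(outdir) -> dict:
    """Load a fit directory back into a plain dict of arrays and tables."""
    outdir = Path(outdir)
    out: dict = {"report": json.loads((outdir / "report.json").read_text())}
    from .ensemble_io import read_coordinate_table

    mean_set = read_coordinate_table(outdir / "mean.tsv")
    out["M_hat"] = mean_set.ensembles[0][1][0].coords
    for tag in ("W", "Sigma", "Delta"):
        if (outdir / f"{tag}.npy").exists():
            out[tag], out[f"{tag}_meta"] = load_covariance(outdir / tag)
    if (outdir / "Z.npy").exists():
        out["Z"] = list(np.load(outdir / "Z.npy"))
    tdf = pd.read_csv(outdir / "transforms.tsv", sep="\t")
    out["transforms"] = [
        RigidTransform(
            t=np.array([row[f"t{k+1}"] for k in range(3)]),
            R=np.array([[row[f"r{a+1}{b+1}"] for b in range(3)] for a in range(3)]),
        )
        for _, row in tdf.iterrows()
    ]
    out["transform_ids"] = list(tdf["id"])
    out["transform_ensembles"] = list(tdf["ensemble"])
    if (outdir / "loglik.csv").exists():
        out["loglik_trace"] = pd.read_csv(outdir / "loglik.csv")["loglik"].tolist()
    return out
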