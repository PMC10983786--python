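"""Reading, filtering and writing multi-ensemble Cα coordinate sets.

A dataset is a set of *ensembles* (e.g. all X-ray chains of one enzyme),
each a list of :class:`Conformation` objects whose rows are indexed by the
columns of a shared residue alignment.  Building a dataset goes:

    read_pdb_calpha -> apply_alignment -> EnsembleSet -> complete_case_filter

Sequence alignment itself is consumed as a precomputed TSV map
(chain_key, source_resnum, column), not computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Conformation",
    "EnsembleSet",
    "AlignmentMap",
    "FilterReport",
    "read_pdb_calpha",
    "apply_alignment",
    "complete_case_filter",
    "write_superposed_pdb",
    "write_coordinate_table",
    "read_coordinate_table",
    "read_manifest",
    "build_dataset",
]


@dataclass
class Conformation:
    """Labelled n×3 Cα coordinate matrix with a presence mask.

    ``present_mask[a]`` is False where no coordinate exists (missing residue
    or unmapped alignment column); masked rows hold zeros and are ignored by
    every consumer until :func:`complete_case_filter` removes them.
    """

    id: str
    coords: np.ndarray
    present_mask: np.ndarray | None = None
    residue_ids: list[str] | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.present_mask is None:
            self.present_mask = np.ones(len(self.coords), dtype=bool)
        self.present_mask = np.asarray(self.present_mask, dtype=bool)
        if len(self.present_mask) != len(self.coords):
            raise ValueError("present_mask length must match coords")
        if not np.all(np.isfinite(self.coords[self.present_mask])):
            raise ValueError("non-finite coordinates at present positions")

    @property
    def n(self) -> int:
        return len(self.coords)

    @property
    def missing_fraction(self) -> float:
        return 1.0 - self.present_mask.mean()


@dataclass
class EnsembleSet:
    """Ordered ensembles of conformations sharing one alignment frame."""

    ensembles: list[tuple[str, list[Conformation]]]

    def __post_init__(self):
        ids = [eid for eid, _ in self.ensembles]
        if len(set(ids)) != len(ids):
            raise ValueError("ensemble ids must be unique")
        if not self.ensembles:
            raise ValueError("need at least one ensemble")
        ns = {c.n for _, members in self.ensembles for c in members}
        if len(ns) > 1:
            raise ValueError(f"conformations disagree on atom count: {sorted(ns)}")

    @property
    def n(self) -> int:
        return self.ensembles[0][1][0].n

    @property
    def nu(self) -> int:
        return len(self.ensembles)

    @property
    def sizes(self) -> list[int]:
        return [len(members) for _, members in self.ensembles]

    @property
    def ensemble_ids(self) -> list[str]:
        return [eid for eid, _ in self.ensembles]

    def members(self):
        """Yield (ensemble_index, ensemble_id, Conformation) in order."""
        for i, (eid, mem) in enumerate(self.ensembles):
            for c in mem:
                yield i, eid, c

    def all_conformations(self) -> list[Conformation]:
        return [c for _, _, c in self.members()]

    def coords_stacked(self) -> np.ndarray:
        return np.stack([c.coords for c in self.all_conformations()])


@dataclass
class AlignmentMap:
    """Residue-number -> alignment-column map, one row per mapped residue."""

    table: pd.DataFrame  # columns: chain_key, source_resnum, column

    REQUIRED = ("chain_key", "source_resnum", "column")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"alignment map missing column {col!r}")
        dup = self.table.duplicated(subset=["chain_key", "column"])
        if dup.any():
            bad = self.table[dup].iloc[0]
            raise ValueError(
                f"duplicate alignment column {bad['column']} for chain {bad['chain_key']!r}"
            )

    @property
    def n_columns(self) -> int:
        return int(self.table["column"].max()) + 1

    def for_chain(self, chain_key: str) -> pd.DataFrame:
        sub = self.table[self.table["chain_key"] == chain_key]
        if sub.empty:
            raise ValueError(f"alignment map has no entries for chain {chain_key!r}")
        return sub

    @classmethod
    def read_tsv(cls, path) -> "AlignmentMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"chain_key": str, "source_resnum": str}))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def identity(cls, chain_keys, residue_ids) -> "AlignmentMap":
        rows = [
            {"chain_key": ck, "source_resnum": str(r), "column": i}
            for ck in chain_keys
            for i, r in enumerate(residue_ids)
        ]
        return cls(pd.DataFrame(rows))


@dataclass
class FilterReport:
    n_conf_in: int = 0
    n_conf_dropped_missing: int = 0
    n_columns_in: int = 0
    n_columns_dropped: int = 0
    n_conf_dropped_excluded: int = 0
    n_ensembles_dropped_empty: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def read_pdb_calpha(path, chain: str, altloc_policy: str = "first") -> Conformation:
    """Extract one Cα coordinate per residue of ``chain`` from a PDB/mmCIF file.

    Residues without a Cα atom get a masked (absent) row.  ``altloc_policy``
    is ``"first"`` (first record in file order) or ``"highest_occupancy"``.
    Insertion codes are kept, so residues 52 and 52A are distinct.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    names = [ch.name for ch in model]
    target = None
    for ch in model:
        if ch.name == chain:
            target = ch
            break
    if target is None:
        raise ValueError(f"{path}: chain {chain!r} not found; available chains: {names}")
    coords, mask, resids = [], [], []
    for res in target:
        cas = [a for a in res if a.name == "CA" and a.element.name != "Ca"]
        if not cas:
            # skip waters/ligands entirely, mask missing amino-acid residues
            if gemmi.find_tabulated_residue(res.name) and gemmi.find_tabulated_residue(res.name).is_amino_acid():
                coords.append((0.0, 0.0, 0.0))
                mask.append(False)
                resids.append(f"{res.seqid.num}{res.seqid.icode}".strip())
            continue
        if len(cas) > 1:
            if altloc_policy == "highest_occupancy":
                atom = max(cas, key=lambda a: a.occ)
            elif altloc_policy == "first":
                atom = cas[0]
            else:
                raise ValueError(f"unknown altloc policy {altloc_policy!r}")
        else:
            atom = cas[0]
        coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
        mask.append(True)
        resids.append(f"{res.seqid.num}{res.seqid.icode}".strip())
    if not any(mask):
        raise ValueError(f"{path} chain {chain!r}: no C-alpha atoms")
    name = Path(path).stem
    return Conformation(
        id=f"{name}{chain}",
        coords=np.asarray(coords, dtype=float),
        present_mask=np.asarray(mask, dtype=bool),
        residue_ids=resids,
    )


def apply_alignment(conf: Conformation, amap: AlignmentMap, n_total: int,
                    chain_key: str | None = None) -> Conformation:
    """Re-index a conformation's rows to shared alignment columns.

    Rows whose residue number is not mapped, and columns with no mapped
    residue, come out masked absent: the output's present positions are a
    subset of the input's.
    """
    key = chain_key if chain_key is not None else conf.id
    sub = amap.for_chain(key)
    if conf.residue_ids is None:
        resids = [str(i) for i in range(conf.n)]
    else:
        resids = [str(r) for r in conf.residue_ids]
    lookup = {}
    for _, row in sub.iterrows():
        col = int(row["column"])
        if not 0 <= col < n_total:
            raise ValueError(f"alignment column {col} outside [0, {n_total})")
        lookup[str(row["source_resnum"])] = col
    coords = np.zeros((n_total, 3))
    mask = np.zeros(n_total, dtype=bool)
    for a, rid in enumerate(resids):
        col = lookup.get(rid)
        if col is not None and conf.present_mask[a]:
            coords[col] = conf.coords[a]
            mask[col] = True
    return Conformation(id=conf.id, coords=coords, present_mask=mask)


def complete_case_filter(
    es: EnsembleSet,
    max_missing_frac_conf: float = 0.5,
    drop_any_missing_residue: bool = True,
    exclude_ids=(),
) -> tuple[EnsembleSet, FilterReport]:
    """Reduce a masked dataset to complete cases.

    Steps, in order: (1) drop conformations whose missing fraction exceeds
    ``max_missing_frac_conf``; (2) drop alignment columns absent in any
    surviving conformation (when ``drop_any_missing_residue``); (3) drop
    conformations in ``exclude_ids`` (manual outlier removal).  Ensembles
    left empty are dropped.  Idempotent.
    """
    if not 0 <= max_missing_frac_conf <= 1:
        raise ValueError("max_missing_frac_conf must be in [0, 1]")
    exclude = set(exclude_ids)
    report = FilterReport(
        n_conf_in=sum(es.sizes),
        n_columns_in=es.n,
    )
    kept: list[tuple[str, list[Conformation]]] = []
    for eid, members in es.ensembles:
        surv = []
        for c in members:
            if c.missing_fraction > max_missing_frac_conf:
                report.n_conf_dropped_missing += 1
            else:
                surv.append(c)
        kept.append((eid, surv))

    survivors = [c for _, mem in kept for c in mem]
    if not survivors:
        raise ValueError("no complete cases")
    if drop_any_missing_residue:
        col_ok = np.logical_and.reduce([c.present_mask for c in survivors])
    else:
        col_ok = np.ones(es.n, dtype=bool)
    report.n_columns_dropped = int((~col_ok).sum())

    out: list[tuple[str, list[Conformation]]] = []
    for eid, members in kept:
        final = []
        for c in members:
            if c.id in exclude:
                report.n_conf_dropped_excluded += 1
                continue
            final.append(
                Conformation(
                    id=c.id,
                    coords=c.coords[col_ok],
                    present_mask=c.present_mask[col_ok],
                    residue_ids=[c.residue_ids[i] for i in np.flatnonzero(col_ok)]
                    if c.residue_ids is not None
                    else None,
                )
            )
        if final:
            out.append((eid, final))
        else:
            report.n_ensembles_dropped_empty += 1
    if not out:
        raise ValueError("no complete cases")
    result = EnsembleSet(out)
    if drop_any_missing_residue and not all(
        c.present_mask.all() for c in result.all_conformations()
    ):
        raise ValueError("no complete cases")  # excluded ids reopened a gap
    return result, report


def write_superposed_pdb(confs, transforms, path) -> None:
    """Write conformations as MODELs of one PDB file after applying their transforms."""
    if len(confs) != len(transforms):
        raise ValueError("confs and transforms must have the same length")
    st = gemmi.Structure()
    st.name = "multisup"
    for k, (conf, tr) in enumerate(zip(confs, transforms), start=1):
        coords = tr.apply(conf.coords) if tr is not None else conf.coords
        model = gemmi.Model(k)
        chain = gemmi.Chain("A")
        rids = conf.residue_ids or [str(i + 1) for i in range(conf.n)]
        for a in range(conf.n):
            if conf.present_mask is not None and not conf.present_mask[a]:
                continue
            res = gemmi.Residue()
            res.name = "ALA"
            num = "".join(ch for ch in str(rids[a]) if ch.isdigit() or ch == "-")
            res.seqid = gemmi.SeqId(int(num) if num else a + 1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*coords[a])
            atom.occ = 1.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_coordinate_table(es: EnsembleSet, path) -> None:
    """Plain-text dump: per conformation a '#n=.. id=.. ensemble=..' header then x y z rows."""
    with open(path, "w") as fh:
        for _, eid, conf in es.members():
            fh.write(f"#n={conf.n} id={conf.id} ensemble={eid}\n")
            for row in conf.coords:
                fh.write(f"{row[0]:.6f}\t{row[1]:.6f}\t{row[2]:.6f}\n")


def read_coordinate_table(path) -> EnsembleSet:
    ensembles: dict[str, list[Conformation]] = {}
    order: list[str] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        ln = lines[i]
        if not ln.startswith("#"):
            raise ValueError(f"{path}: expected header line, got {ln!r}")
        fields = dict(kv.split("=", 1) for kv in ln[1:].split())
        n = int(fields["n"])
        coords = np.array(
            [[float(v) for v in lines[i + 1 + a].split()] for a in range(n)]
        )
        conf = Conformation(id=fields["id"], coords=coords)
        eid = fields["ensemble"]
        if eid not in ensembles:
            ensembles[eid] = []
            order.append(eid)
        ensembles[eid].append(conf)
        i += 1 + n
    return EnsembleSet([(eid, ensembles[eid]) for eid in order])


def read_manifest(path) -> pd.DataFrame:
    """TSV with columns ensemble_id, conformation_id, path, chain."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"ensemble_id", "conformation_id", "path", "chain"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def build_dataset(
    manifest: pd.DataFrame,
    amap: AlignmentMap,
    max_missing_frac_conf: float = 0.5,
    exclude_ids=(),
    altloc_policy: str = "first",
    base_dir=None,
) -> tuple[EnsembleSet, FilterReport]:
    """Read every chain in the manifest, align, and complete-case filter."""
    n_total = amap.n_columns
    ensembles: dict[str, list[Conformation]] = {}
    order: list[str] = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        if not p.exists():
            raise FileNotFoundError(f"manifest references unreadable path: {p}")
        conf = read_pdb_calpha(p, row["chain"], altloc_policy=altloc_policy)
        conf.id = row["conformation_id"]
        aligned = apply_alignment(conf, amap, n_total, chain_key=row["conformation_id"])
        eid = row["ensemble_id"]
        if eid not in ensembles:
            ensembles[eid] = []
            order.append(eid)
        ensembles[eid].append(aligned)
    es = EnsembleSet([(eid, ensembles[eid]) for eid in order])
    return complete_case_filter(
        es, max_missing_frac_conf=max_missing_frac_conf, exclude_ids=exclude_ids
    )
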