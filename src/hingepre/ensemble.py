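"""Conformer ensembles and their on-disk representations.

The :class:`ConformerEnsemble` is the common currency of the geometric and
PRE stages: an ordered stack of coordinate frames (Å) over a fixed atom
table carrying residue ids, atom names and a coarse domain tag
(NTD / HINGE / CTD / OTHER).  Multi-model PDB files (MODEL/ENDMDL records)
are read and written through biotite; XYZ is a plain-text fallback for
toy systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

DOMAIN_TAGS = ("NTD", "HINGE", "CTD", "OTHER")


@dataclass
class ConformerEnsemble:
    """Ordered coordinate frames over a fixed atom table.

    Parameters
    ----------
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in Å.
    atom_meta : pandas.DataFrame
        One row per atom with columns ``residue_id`` (int, 1-based),
        ``atom_name`` (str) and ``domain`` (one of NTD/HINGE/CTD/OTHER).
    source : str
        Free-text provenance note.
    """

    coords: np.ndarray
    atom_meta: pd.DataFrame
    source: str = ""
    frame_labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if len(self.atom_meta) != self.coords.shape[1]:
            raise ValueError(
                f"atom_meta has {len(self.atom_meta)} rows but frames have "
                f"{self.coords.shape[1]} atoms"
            )
        required = {"residue_id", "atom_name", "domain"}
        missing = required - set(self.atom_meta.columns)
        if missing:
            raise ValueError(f"atom_meta missing columns: {sorted(missing)}")
        bad = set(self.atom_meta["domain"]) - set(DOMAIN_TAGS)
        if bad:
            raise ValueError(f"unknown domain tags: {sorted(bad)}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def atom_indices(self, domain: str | None = None,
                     residue_ids=None) -> np.ndarray:
        """Integer indices of atoms matching a domain tag and/or residue set."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if domain is not None:
            mask &= (self.atom_meta["domain"] == domain).to_numpy()
        if residue_ids is not None:
            mask &= self.atom_meta["residue_id"].isin(list(residue_ids)).to_numpy()
        return np.nonzero(mask)[0]

    def subset(self, indices) -> "ConformerEnsemble":
        indices = np.asarray(indices, dtype=int)
        return ConformerEnsemble(
            coords=self.coords[:, indices],
            atom_meta=self.atom_meta.iloc[indices].reset_index(drop=True),
            source=self.source,
            frame_labels=self.frame_labels,
        )


@dataclass(frozen=True)
class DomainPartition:
    """Residue-id sets defining the NTD, hinge region and CTD.

    The interdomain angle is the vertex angle at the hinge-region center of
    mass between the two domain centers of mass; the partition is always a
    configuration input because residue ranges are a modelling convention.
    """

    ntd_residues: frozenset
    hinge_residues: frozenset
    ctd_residues: frozenset

    def __post_init__(self):
        sets = {
            "ntd_residues": frozenset(self.ntd_residues),
            "hinge_residues": frozenset(self.hinge_residues),
            "ctd_residues": frozenset(self.ctd_residues),
        }
        for name, s in sets.items():
            object.__setattr__(self, name, s)
            if not s:
                raise ValueError(f"{name} must be non-empty")
        if (sets["ntd_residues"] & sets["hinge_residues"]
                or sets["ntd_residues"] & sets["ctd_residues"]
                or sets["hinge_residues"] & sets["ctd_residues"]):
            raise ValueError("partition residue sets must be pairwise disjoint")

    @classmethod
    def from_ranges(cls, ntd, hinge, ctd) -> "DomainPartition":
        """Build from lists of inclusive ``[start, stop]`` residue ranges."""
        def expand(ranges):
            out = set()
            for lo, hi in ranges:
                out.update(range(int(lo), int(hi) + 1))
            return frozenset(out)

        return cls(expand(ntd), expand(hinge), expand(ctd))

    @classmethod
    def from_yaml(cls, path) -> "DomainPartition":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        return cls.from_ranges(spec["ntd"], spec["hinge"], spec["ctd"])


def _to_atom_array_stack(ensemble: ConformerEnsemble) -> struc.AtomArrayStack:
    n_frames, n_atoms = ensemble.n_frames, ensemble.n_atoms
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = ensemble.coords.astype(np.float32)
    meta = ensemble.atom_meta
    stack.res_id = meta["residue_id"].to_numpy(dtype=int)
    stack.atom_name = meta["atom_name"].to_numpy(dtype="U6")
    stack.chain_id = np.full(n_atoms, "A", dtype="U4")
    # domain tag survives the round trip through the residue-name column
    stack.res_name = np.array(
        [{"NTD": "NTD", "HINGE": "HIN", "CTD": "CTD", "OTHER": "UNK"}[d]
         for d in meta["domain"]], dtype="U5")
    stack.element = np.full(n_atoms, "C", dtype="U2")
    stack.hetero = np.zeros(n_atoms, dtype=bool)
    stack.set_annotation("occupancy", np.ones(n_atoms, dtype=np.float32))
    stack.set_annotation("b_factor", np.zeros(n_atoms, dtype=np.float32))
    return stack


_RES_NAME_TO_DOMAIN = {"NTD": "NTD", "HIN": "HINGE", "CTD": "CTD"}


def _from_atom_array_stack(stack, source: str = "") -> ConformerEnsemble:
    if isinstance(stack, struc.AtomArray):
        coords = np.asarray(stack.coord, dtype=float)[None]
        template = stack
    else:
        coords = np.asarray(stack.coord, dtype=float)
        template = stack[0]
    meta = pd.DataFrame({
        "residue_id": np.asarray(template.res_id, dtype=int),
        "atom_name": [str(a) for a in template.atom_name],
        "domain": [_RES_NAME_TO_DOMAIN.get(str(r), "OTHER")
                   for r in template.res_name],
    })
    return ConformerEnsemble(coords=coords, atom_meta=meta, source=source)


def write_pdb(ensemble: ConformerEnsemble, path) -> None:
    """Write a multi-model PDB (MODEL/ENDMDL per frame)."""
    f = pdb.PDBFile()
    f.set_structure(_to_atom_array_stack(ensemble))
    f.write(str(path))


def read_pdb(path, ca_only: bool = False) -> ConformerEnsemble:
    """Read a (multi-model) PDB into an ensemble.

    Alternate locations resolve by the first altloc; models must share one
    atom table (biotite raises otherwise, which is re-reported with the
    offending file named).
    """
    f = pdb.PDBFile.read(str(path))
    try:
        stack = f.get_structure(model=None, altloc="first")
    except Exception as exc:  # inconsistent models etc.
        raise ValueError(f"cannot read {path} as a multi-model PDB: {exc}") from exc
    if ca_only:
        stack = stack[..., stack.atom_name == "CA"]
    return _from_atom_array_stack(stack, source=str(path))


def write_xyz(ensemble: ConformerEnsemble, path) -> None:
    """Plain multi-frame XYZ (element column carries the domain tag)."""
    with open(path, "w") as fh:
        for i in range(ensemble.n_frames):
            fh.write(f"{ensemble.n_atoms}\nframe {i}\n")
            for (x, y, z), dom in zip(ensemble.coords[i],
                                      ensemble.atom_meta["domain"]):
                fh.write(f"{dom:<6s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def read_xyz(path) -> ConformerEnsemble:
    frames, meta_rows = [], None
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos].strip())
        block = lines[pos + 2: pos + 2 + n]
        doms, xyz = [], []
        for line in block:
            parts = line.split()
            doms.append(parts[0] if parts[0] in DOMAIN_TAGS else "OTHER")
            xyz.append([float(v) for v in parts[1:4]])
        if meta_rows is None:
            meta_rows = doms
        frames.append(xyz)
        pos += 2 + n
    meta = pd.DataFrame({
        "residue_id": np.arange(1, len(meta_rows) + 1),
        "atom_name": ["CA"] * len(meta_rows),
        "domain": meta_rows,
    })
    return ConformerEnsemble(coords=np.array(frames), atom_meta=meta,
                             source=str(path))


def ensemble_to_csv_labels(ensemble: ConformerEnsemble, path) -> None:
    """Side-car CSV of per-frame state labels (frame, state)."""
    if ensemble.frame_labels is None:
        raise ValueError("ensemble carries no frame labels")
    pd.DataFrame({
        "frame": np.arange(ensemble.n_frames),
        "state": ensemble.frame_labels,
    }).to_csv(path, index=False)
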