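"""Reading and writing the package's on-disk artifacts.

Structures and ensembles are read through MDAnalysis, so anything it
understands works (PDB, multi-model PDB, GRO topologies, XTC/DCD
trajectories). Rotamer libraries live on disk as a multi-model PDB (one
MODEL per conformer) plus a YAML metadata block; an index YAML maps library
names to their metadata files. Förster radii for common dye pairs come
from a CSV table (donor, acceptor, R0 in nm).
"""
from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field

import MDAnalysis as mda
import numpy as np
import pandas as pd
import yaml
from MDAnalysis.coordinates.memory import MemoryReader

from .libgen import ProbeMeta, RotamerLibrary
from .placement import ProteinEnsemble

__all__ = [
    "LibraryIndex",
    "LibraryNotFoundError",
    "read_ensemble",
    "write_ensemble",
    "save_library",
    "load_library_file",
    "load_library",
    "read_r0_table",
    "lookup_r0",
]


class LibraryNotFoundError(KeyError):
    """Requested rotamer library is not in the index."""


_TWO_LETTER = {"CL", "BR", "NA", "MG", "ZN", "FE", "MN", "SE"}


def _guess_element(name: str) -> str:
    """Fallback element guess from an atom name (first alphabetic char,
    with common two-letter ions/halogens recognized)."""
    stripped = name.strip().upper()
    head = stripped.lstrip("0123456789")
    if head[:2] in _TWO_LETTER:
        return head[:2]
    for ch in head:
        if ch.isalpha():
            return ch
    raise ValueError(f"cannot guess element for atom name {name!r}")


def _universe_to_ensemble(u: mda.Universe) -> ProteinEnsemble:
    ag = u.atoms
    try:
        elements = [str(e) if str(e).strip() else _guess_element(n) for e, n in zip(ag.elements, ag.names)]
    except (mda.exceptions.NoDataError, AttributeError):
        elements = [_guess_element(n) for n in ag.names]
    try:
        charges = np.asarray(ag.charges, dtype=float)
    except (mda.exceptions.NoDataError, AttributeError):
        charges = np.zeros(len(ag))
    try:
        chains = [str(c) for c in ag.chainIDs]
    except (mda.exceptions.NoDataError, AttributeError):
        chains = [str(s) for s in ag.segids]
    atoms = pd.DataFrame(
        {
            "name": [str(n) for n in ag.names],
            "resid": np.asarray(ag.resids, dtype=int),
            "resname": [str(r) for r in ag.resnames],
            "chain": chains,
            "element": elements,
            "charge": charges,
        }
    )
    frames = np.stack([ts.positions.copy().astype(float) for ts in u.trajectory])
    return ProteinEnsemble(atoms=atoms, frames=frames)


def read_ensemble(topology: str, trajectory: str | None = None) -> ProteinEnsemble:
    """Load a structure or ensemble.

    A single-model PDB gives N = 1; a multi-model PDB one frame per MODEL;
    a separate trajectory file (XTC/DCD/...) is read against the topology.
    """
    if not os.path.exists(topology):
        raise FileNotFoundError(topology)
    if trajectory is not None and not os.path.exists(trajectory):
        raise FileNotFoundError(trajectory)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(topology) if trajectory is None else mda.Universe(topology, trajectory)
    return _universe_to_ensemble(u)


def _empty_universe(atoms: pd.DataFrame, frames: np.ndarray) -> mda.Universe:
    resid_key = atoms[["chain", "resid"]].apply(tuple, axis=1)
    # preserve first-appearance order of residues
    order = {}
    atom_resindex = np.empty(len(atoms), dtype=int)
    for i, key in enumerate(resid_key):
        atom_resindex[i] = order.setdefault(key, len(order))
    n_res = len(order)
    res_rows = atoms.drop_duplicates(subset=["chain", "resid"])
    u = mda.Universe.empty(
        n_atoms=len(atoms),
        n_residues=n_res,
        atom_resindex=atom_resindex,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", atoms["name"].tolist())
    u.add_TopologyAttr("elements", atoms["element"].tolist())
    u.add_TopologyAttr("resids", res_rows["resid"].to_numpy())
    u.add_TopologyAttr("resnames", res_rows["resname"].tolist())
    u.add_TopologyAttr("chainIDs", atoms["chain"].tolist())
    u.add_TopologyAttr("segids", ["SYS"])
    u.add_TopologyAttr("occupancies", np.ones(len(atoms)))
    u.add_TopologyAttr("tempfactors", np.zeros(len(atoms)))
    u.load_new(np.asarray(frames, dtype=np.float32), format=MemoryReader)
    return u


def write_ensemble(ensemble: ProteinEnsemble, path: str) -> None:
    """Write an ensemble as a (multi-model) PDB file."""
    u = _empty_universe(ensemble.atoms, ensemble.frames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def save_library(library: RotamerLibrary, directory: str, basename: str | None = None) -> str:
    """Write a library as ``<basename>.pdb`` + ``<basename>.yml``.

    Returns the path of the YAML metadata file.
    """
    os.makedirs(directory, exist_ok=True)
    basename = basename or re.sub(r"\s+", "_", library.name)
    pdb_path = os.path.join(directory, basename + ".pdb")
    yml_path = os.path.join(directory, basename + ".yml")
    atoms = pd.DataFrame(
        {
            "name": library.atom_names,
            "resid": 1,
            "resname": "DYE",
            "chain": "X",
            "element": library.elements,
            "charge": library.charges,
        }
    )
    write_ensemble(ProteinEnsemble(atoms=atoms, frames=library.coords), pdb_path)
    meta = {
        "name": library.name,
        "pdb": os.path.basename(pdb_path),
        "dipole_atoms": list(library.meta.dipole_atoms),
        "center_atom": library.meta.center_atom,
        "attachment_atoms": list(library.meta.attachment_atoms),
        "cutoff_class": library.cutoff_class,
        "weights": [float(w) for w in library.weights],
        "charges": [float(q) for q in library.charges],
    }
    with open(yml_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return yml_path


def load_library_file(yml_path: str) -> RotamerLibrary:
    """Load one library from its YAML metadata file (PDB path is relative
    to the YAML's directory)."""
    with open(yml_path) as fh:
        meta = yaml.safe_load(fh)
    pdb_path = os.path.join(os.path.dirname(os.path.abspath(yml_path)), meta["pdb"])
    if not os.path.exists(pdb_path):
        raise FileNotFoundError(f"conformer file {pdb_path} referenced by {yml_path} is missing")
    ens = read_ensemble(pdb_path)
    weights = np.asarray(meta["weights"], dtype=float)
    charges = np.asarray(meta.get("charges", np.zeros(len(ens.atoms))), dtype=float)
    return RotamerLibrary(
        name=meta["name"],
        coords=ens.frames,
        weights=weights / weights.sum(),
        atom_names=list(ens.atoms["name"]),
        elements=list(ens.atoms["element"]),
        charges=charges,
        meta=ProbeMeta(
            dipole_atoms=tuple(meta["dipole_atoms"]),
            center_atom=meta["center_atom"],
            attachment_atoms=tuple(meta["attachment_atoms"]),
        ),
        cutoff_class=meta.get("cutoff_class", "custom"),
    )


@dataclass
class LibraryIndex:
    """Name -> metadata-file mapping for the installed rotamer libraries."""

    entries: dict[str, str] = field(default_factory=dict)
    root: str = "."

    @classmethod
    def load(cls, path: str) -> "LibraryIndex":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(entries=dict(raw), root=os.path.dirname(os.path.abspath(path)))

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.entries, fh, sort_keys=True)

    def add(self, name: str, yml_relpath: str) -> None:
        self.entries[name] = yml_relpath

    def path_for(self, name: str) -> str:
        if name not in self.entries:
            available = ", ".join(sorted(self.entries)) or "(none)"
            raise LibraryNotFoundError(
                f"library {name!r} not found; available: {available}"
            )
        return os.path.join(self.root, self.entries[name])


def load_library(index: LibraryIndex, name: str) -> RotamerLibrary:
    """Load a library by name from an index."""
    return load_library_file(index.path_for(name))


def _norm_dye(name: str) -> str:
    return re.sub(r"\s+", " ", str(name).strip()).casefold()


def read_r0_table(path: str) -> pd.DataFrame:
    """Read a (donor, acceptor, R0/nm) CSV table."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"donor", "acceptor", "r0"}
    if not required.issubset(df.columns):
        raise ValueError(f"R0 table needs columns {sorted(required)}, got {list(df.columns)}")
    if (df["r0"] <= 0).any():
        raise ValueError("R0 values must be positive")
    return df


def lookup_r0(table: pd.DataFrame, donor: str, acceptor: str) -> float:
    """Tabulated Förster radius in nm for a dye pair (names are matched
    case- and whitespace-insensitively)."""
    d, a = _norm_dye(donor), _norm_dye(acceptor)
    mask = (table["donor"].map(_norm_dye) == d) & (table["acceptor"].map(_norm_dye) == a)
    hits = table.loc[mask, "r0"]
    if hits.empty:
        raise KeyError(
            f"no R0 entry for pair ({donor!r}, {acceptor!r}); "
            "add one to the table or pass a fixed R0 directly"
        )
    return float(hits.iloc[0])
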