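"""Readers/writers: PDB structures, tabular q-profiles, HDF5 train series."""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .geometry import QGrid, RadialProfile
from .scattering import AtomicModel, EFFECTIVE_ELECTRONS

log = logging.getLogger(__name__)

__all__ = [
    "read_structure",
    "write_structure",
    "read_profile",
    "write_profile",
    "save_train_series",
    "load_train_series",
]


def _infer_element(atom_name: str) -> str:
    """Element from a PDB atom name (first alphabetic character, H-number aware)."""
    name = atom_name.strip()
    for ch in name:
        if ch.isalpha():
            # two-letter elements we care about would be spelled in the element
            # column; atom-name inference targets organic single-letter cases
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def read_structure(path: str | Path) -> AtomicModel:
    """Read a PDB file into an :class:`AtomicModel`.

    Missing element columns fall back to atom-name inference (logged); a
    malformed ATOM/HETATM record raises with its line number.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1)
    except Exception as exc:
        # locate the first unparseable coordinate record for the error message
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except (ValueError, IndexError):
                    raise ValueError(f"{path}: malformed coordinate record at line {lineno}") from exc
        raise ValueError(f"{path}: cannot parse PDB file: {exc}") from exc
    elements = np.asarray(atoms.element, dtype=object)
    blank = [i for i, e in enumerate(elements) if not str(e).strip()]
    if blank:
        log.info("%s: inferring elements from atom names for %d atoms", path, len(blank))
        for i in blank:
            elements[i] = _infer_element(atoms.atom_name[i])
    return AtomicModel(coords=atoms.coord, elements=elements, id=path.stem)


def write_structure(model: AtomicModel, path: str | Path) -> None:
    """Write an :class:`AtomicModel` as a single-chain PDB (one atom per residue)."""
    n = len(model)
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(model.coords, dtype=np.float32)
    atoms.chain_id = np.full(n, "A")
    atoms.res_id = np.arange(1, n + 1)
    atoms.res_name = np.full(n, "GLY")
    atoms.atom_name = np.array([f"{str(e).upper()}A"[:4] for e in model.elements])
    atoms.element = np.array([str(e).upper() for e in model.elements])
    atoms.hetero = np.full(n, False)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def write_profile(profile: RadialProfile, path: str | Path, header: str = "") -> None:
    """Write a profile as two whitespace columns (q [1/A], intensity)."""
    lines = ["# trwaxs radial profile", "# q[1/A]  intensity"]
    if header:
        lines[1:1] = [f"# {line}" for line in header.splitlines()]
    body = "\n".join(f"{qi:.9e} {ii:.9e}" for qi, ii in zip(profile.q.values, profile.intensity))
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def read_profile(path: str | Path) -> RadialProfile:
    """Read a two-column (q, intensity) table with '#' comment headers."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (q, intensity)")
    q, intensity = data[:, 0], data[:, 1]
    edges = np.concatenate([[q[0] - (q[1] - q[0]) / 2] if len(q) > 1 else [q[0] * 0.5],
                            (q[:-1] + q[1:]) / 2 if len(q) > 1 else [],
                            [q[-1] + (q[-1] - q[-2]) / 2] if len(q) > 1 else [q[0] * 1.5]])
    return RadialProfile(q=QGrid(values=q, edges=edges), intensity=intensity)


def save_train_series(series, path: str | Path) -> None:
    """Write a TrainSeries to the HDF5 container.

    Layout: /trains/profiles, /trains/light_flag, /time_us, /q, /q_edges and an
    optional /truth group holding the synthetic ground-truth record.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("trains/profiles", data=series.profiles)
        f.create_dataset("trains/light_flag", data=series.light_flag)
        f.create_dataset("time_us", data=series.time_us)
        f.create_dataset("q", data=series.q.values)
        f.create_dataset("q_edges", data=series.q.edges)
        if series.truth is not None:
            g = f.create_group("truth")
            for key, val in series.truth.items():
                g.create_dataset(key, data=np.asarray(val))


def load_train_series(path: str | Path):
    """Read a TrainSeries from the HDF5 container written by :func:`save_train_series`."""
    from .synthetic import TrainSeries  # deferred: io <-> synthetic layering

    with h5py.File(path, "r") as f:
        truth = None
        if "truth" in f:
            truth = {k: np.asarray(f["truth"][k]) for k in f["truth"]}
        return TrainSeries(
            profiles=np.asarray(f["trains/profiles"]),
            light_flag=np.asarray(f["trains/light_flag"], dtype=bool),
            time_us=np.asarray(f["time_us"]),
            q=QGrid(values=np.asarray(f["q"]), edges=np.asarray(f["q_edges"])),
            truth=truth,
        )
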