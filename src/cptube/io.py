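"""Structure and trajectory I/O.

Models are written as multi-chain PDB files (one chain per ring, chain IDs
A, B, C, ... for up to 62 rings) and trajectories as multi-MODEL PDB files,
both through biotite.  Coordinates round-trip at PDB format precision
(0.001 angstrom).  Model metadata (ring size, spacing, registry) travels in a
JSON sidecar written next to the structure.

External trajectories in binary MD formats (DCD/XTC) can optionally be
loaded through MDAnalysis when it is importable; nothing in the pipeline
requires it.
"""

from __future__ import annotations

import json
import string
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .geometry import N_SITES, SITE_NAMES, NanotubeModel

_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits

#: Elements of the four backbone sites, aligned with SITE_NAMES.
_SITE_ELEMENTS = ("N", "H", "C", "O")


class StructureParseError(ValueError):
    """A structure file could not be interpreted as a nanotube model."""


def _model_to_atom_array(coords: np.ndarray) -> struc.AtomArray:
    """Flatten (rings, residues, sites, 3) coordinates into an AtomArray."""
    n_rings, n_res = coords.shape[:2]
    if n_rings > len(_CHAIN_IDS):
        raise ValueError(
            f"PDB chain IDs support at most {len(_CHAIN_IDS)} rings, "
            f"got {n_rings}")
    n_atoms = n_rings * n_res * N_SITES
    arr = struc.AtomArray(n_atoms)
    arr.coord = coords.reshape(n_atoms, 3)
    ring_idx = np.repeat(np.arange(n_rings), n_res * N_SITES)
    arr.chain_id = np.array([_CHAIN_IDS[i] for i in ring_idx])
    arr.res_id = np.tile(np.repeat(np.arange(1, n_res + 1), N_SITES), n_rings)
    arr.res_name = np.full(n_atoms, "CPR")
    arr.atom_name = np.tile(np.array(SITE_NAMES), n_rings * n_res)
    arr.element = np.tile(np.array(_SITE_ELEMENTS), n_rings * n_res)
    arr.hetero = np.zeros(n_atoms, dtype=bool)
    return arr


def write_structure(model: NanotubeModel, path: str | Path) -> None:
    """Write a model as a one-chain-per-ring PDB plus JSON metadata sidecar."""
    path = Path(path)
    pdb = PDBFile()
    pdb.set_structure(_model_to_atom_array(model.coords))
    pdb.write(str(path))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(model.metadata(), indent=2))


def write_trajectory(frames: np.ndarray, path: str | Path) -> None:
    """Write trajectory frames (F, rings, residues, 4, 3) as multi-MODEL PDB."""
    frames = np.asarray(frames, dtype=float)
    n_frames = frames.shape[0]
    template = _model_to_atom_array(frames[0])
    stack = struc.stack([template] * n_frames)
    stack.coord = frames.reshape(n_frames, -1, 3)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def _atoms_to_coords(arr: struc.AtomArray) -> np.ndarray:
    """Reshape a parsed AtomArray back to (rings, residues, 4, 3)."""
    chains = list(dict.fromkeys(arr.chain_id))  # preserve file order
    n_res_per_chain = {
        c: len(set(arr.res_id[arr.chain_id == c])) for c in chains}
    n_res = next(iter(n_res_per_chain.values()))
    if any(v != n_res for v in n_res_per_chain.values()):
        raise StructureParseError(
            f"rings differ in residue count: {n_res_per_chain}")
    expected = len(chains) * n_res * N_SITES
    if arr.array_length() != expected:
        raise StructureParseError(
            f"expected {expected} atoms ({len(chains)} rings x {n_res} "
            f"residues x {N_SITES} backbone sites), got {arr.array_length()}")
    coords = np.empty((len(chains), n_res, N_SITES, 3))
    for ci, chain in enumerate(chains):
        sel = arr[arr.chain_id == chain]
        res_ids = sorted(set(sel.res_id))
        for ri, rid in enumerate(res_ids):
            res = sel[sel.res_id == rid]
            for si, name in enumerate(SITE_NAMES):
                site = res[res.atom_name == name]
                if site.array_length() != 1:
                    raise StructureParseError(
                        f"chain {chain} residue {rid}: expected one atom "
                        f"named {name}, got {site.array_length()}")
                coords[ci, ri, si] = site.coord[0]
    return coords


def read_structure(path: str | Path) -> NanotubeModel:
    """Read a model written by :func:`write_structure`.

    Spacing is recomputed from the stored coordinates; metadata such as the
    registry rotation is restored from the JSON sidecar when present.

    Raises
    ------
    StructureParseError
        If the file holds no atoms or does not decompose into rings of
        equal residue count with the four backbone sites each.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1)
    except Exception as exc:  # biotite raises assorted parse errors
        raise StructureParseError(
            f"{path}: not a readable PDB structure ({exc})") from exc
    if arr.array_length() == 0:
        raise StructureParseError(f"{path}: file contains no atoms")
    coords = _atoms_to_coords(arr)

    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    n_unimers, n_res = coords.shape[:2]
    centroids = coords.reshape(n_unimers, -1, 3).mean(axis=1)
    if n_unimers > 1:
        spacing = float(np.mean(
            np.linalg.norm(np.diff(centroids, axis=0), axis=1)))
    else:
        spacing = float(meta.get("spacing", 0.0))
    # Face: which way the N->H vector points along the tube axis.
    face = np.sign(coords[:, :, 1, 2] - coords[:, :, 0, 2]).astype(int)
    return NanotubeModel(
        coords=coords, n_unimers=n_unimers, n_residues=n_res,
        spacing=spacing,
        antiparallel=bool(meta.get("antiparallel", True)),
        registry_rotation=meta.get("registry_rotation"),
        amide_face=face)


def read_trajectory(path: str | Path) -> np.ndarray:
    """Read a multi-MODEL PDB trajectory back to (F, rings, residues, 4, 3)."""
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure()
    except Exception as exc:
        raise StructureParseError(
            f"{path}: not a readable PDB trajectory ({exc})") from exc
    if stack.array_length() == 0:
        raise StructureParseError(f"{path}: file contains no atoms")
    first = stack[0]
    coords0 = _atoms_to_coords(first)
    shape = (stack.stack_depth(),) + coords0.shape
    return stack.coord.reshape(shape)


def load_external_trajectory(topology: str | Path,
                             trajectory: str | Path) -> np.ndarray:
    """Load frames from standard MD formats (DCD/XTC/...) via MDAnalysis.

    Returns raw frame coordinates of shape (n_frames, n_atoms, 3); mapping
    onto a nanotube topology is the caller's responsibility.  MDAnalysis is
    an optional dependency.
    """
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError(
            "reading external trajectory formats requires MDAnalysis") from exc
    u = mda.Universe(str(topology), str(trajectory))
    return np.array([u.atoms.positions.copy() for _ in u.trajectory])
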