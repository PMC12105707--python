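"""Idealized geometry of stacked cyclic D,L-peptide nanotubes.

A cyclic peptide of alternating D- and L-residues adopts a flat ring with its
backbone amide groups perpendicular to the ring plane.  Stacked rings then
hydrogen-bond like an antiparallel beta-sheet: each inter-ring interface of an
``n``-residue ring supports up to ``n`` backbone N-H...O=C bonds (8 for the
octapeptides modelled here), half donated by each ring.

This module builds explicit backbone-site coordinates (amide N, amide H,
carbonyl C, carbonyl O per residue -- sidechains carry no weight in any metric
downstream and are omitted) for a single ring and for a stack of ``n_unimers``
rings, such that an ideal stack realizes exactly ``n_residues`` hydrogen bonds
per interface under geometric detection.

Conventions: tube axis = +z, ring 0 centroid at the origin, right-handed
frame, coordinates in angstroms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Backbone site order along axis 2 of every coordinate array.
SITE_NAMES = ("N", "H", "C", "O")
N_SITES = len(SITE_NAMES)

NH_BOND = 1.0   # amide N-H bond length, angstrom
CO_BOND = 1.23  # carbonyl C=O bond length, angstrom

DEFAULT_N_RESIDUES = 8
DEFAULT_RADIUS = 4.0        # angstrom, ring radius at the backbone sites
DEFAULT_AMIDE_OFFSET = 0.6  # angstrom, axial N / C displacement off the plane
DEFAULT_SPACING = 4.85      # angstrom, mean inter-unimer spacing


class GeometryError(ValueError):
    """Invalid nanotube geometry parameters."""


@dataclass(frozen=True)
class RingGeometry:
    """One flat cyclic-peptide ring with explicit backbone amide sites.

    Attributes
    ----------
    n_residues : int
        Residue count; must be even (alternating D/L chirality).
    radius : float
        Ring radius in angstrom.
    amide_offset : float
        Axial displacement of amide N and carbonyl C off the ring plane.
    coords : np.ndarray, shape (n_residues, 4, 3)
        Coordinates of N, H, C, O per residue (site order ``SITE_NAMES``).
    amide_face : np.ndarray, shape (n_residues,)
        +1 where the N-H vector points along +z, -1 along -z.  Alternates
        strictly around the ring, so each face exposes ``n_residues/2``
        donors and as many acceptors.
    """

    n_residues: int
    radius: float
    amide_offset: float
    coords: np.ndarray
    amide_face: np.ndarray


@dataclass(frozen=True)
class NanotubeModel:
    """A stack of rings along +z with antiparallel beta-sheet registry.

    ``coords`` has shape ``(n_unimers, n_residues, 4, 3)``.  Rings 0 and
    ``n_unimers - 1`` are the capping unimers; interfaces 0 and
    ``n_unimers - 2`` are the cap interfaces, all others core.
    """

    coords: np.ndarray
    n_unimers: int
    n_residues: int
    spacing: float
    antiparallel: bool = True
    registry_rotation: float | None = None
    amide_face: np.ndarray | None = None

    @property
    def n_interfaces(self) -> int:
        return self.n_unimers - 1

    @property
    def cap_interfaces(self) -> frozenset[int]:
        if self.n_unimers < 2:
            return frozenset()
        return frozenset({0, self.n_unimers - 2})

    def centroids(self) -> np.ndarray:
        """Per-ring backbone-atom centroids, shape (n_unimers, 3)."""
        return self.coords.reshape(self.n_unimers, -1, 3).mean(axis=1)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "NanotubeModel":
        """Apply a rigid-body transform (rotation then translation)."""
        xyz = self.coords
        if rotation is not None:
            rotation = np.asarray(rotation, dtype=float)
            xyz = xyz @ rotation.T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        return replace(self, coords=xyz)

    def metadata(self) -> dict:
        """JSON-serializable model metadata (no coordinates)."""
        return {
            "n_unimers": int(self.n_unimers),
            "n_residues": int(self.n_residues),
            "spacing": float(self.spacing),
            "antiparallel": bool(self.antiparallel),
            "registry_rotation": None if self.registry_rotation is None
            else float(self.registry_rotation),
            "site_names": list(SITE_NAMES),
        }


def build_ring(n_residues: int = DEFAULT_N_RESIDUES,
               radius: float = DEFAULT_RADIUS,
               amide_offset: float = DEFAULT_AMIDE_OFFSET) -> RingGeometry:
    """Construct one flat cyclic D,L-peptide ring.

    Residue ``i`` sits at angle ``2*pi*i/n_residues`` on a circle of
    ``radius`` in the z = 0 plane.  Its amide N (with H further out along the
    same axis) is displaced by ``amide_offset`` along ``+z`` when
    ``amide_face[i] = +1`` and along ``-z`` otherwise; the carbonyl C and O
    are displaced oppositely.  The face alternates residue to residue, which
    is the geometric signature of alternating D/L chirality.

    Raises
    ------
    GeometryError
        If ``n_residues`` is odd (no alternating chirality pattern exists),
        below 4, or ``radius``/``amide_offset`` are not positive.
    """
    if n_residues % 2 != 0:
        raise GeometryError(
            f"n_residues must be even for an alternating D/L chirality "
            f"pattern, got {n_residues}")
    if n_residues < 4:
        raise GeometryError(f"n_residues must be >= 4, got {n_residues}")
    if radius <= 0:
        raise GeometryError(f"radius must be positive, got {radius}")
    if amide_offset <= 0:
        raise GeometryError(
            f"amide_offset must be positive, got {amide_offset}")

    idx = np.arange(n_residues)
    theta = 2.0 * np.pi * idx / n_residues
    face = np.where(idx % 2 == 0, 1, -1)

    x = radius * np.cos(theta)
    y = radius * np.sin(theta)
    coords = np.empty((n_residues, N_SITES, 3))
    coords[:, :, 0] = x[:, None]
    coords[:, :, 1] = y[:, None]
    coords[:, 0, 2] = face * amide_offset                # N
    coords[:, 1, 2] = face * (amide_offset + NH_BOND)    # H
    coords[:, 2, 2] = -face * amide_offset               # C
    coords[:, 3, 2] = -face * (amide_offset + CO_BOND)   # O
    return RingGeometry(n_residues=n_residues, radius=radius,
                        amide_offset=amide_offset, coords=coords,
                        amide_face=face)


def stack_rings(ring: RingGeometry,
                n_unimers: int = 8,
                spacing: float = DEFAULT_SPACING,
                antiparallel: bool = True,
                registry_rotation: float | None = None) -> NanotubeModel:
    """Stack copies of ``ring`` along +z into a nanotube model.

    In the antiparallel arrangement every odd-index ring is mirrored through
    its own plane (z -> -z locally) and rotated about the axis by
    ``registry_rotation`` degrees (default ``360/n_residues``), which places
    every donor column of one ring face directly over an acceptor column of
    the neighboring face.  The resulting hydrogen bonds are axial and nearly
    linear, as in antiparallel beta-sheet stacking, and each of the
    ``n_unimers - 1`` interfaces supports exactly ``n_residues`` bonds.

    Raises
    ------
    GeometryError
        If ``n_unimers < 1`` or ``spacing <= 0``.
    """
    if n_unimers < 1:
        raise GeometryError(f"n_unimers must be >= 1, got {n_unimers}")
    if spacing <= 0:
        raise GeometryError(f"spacing must be positive, got {spacing}")
    if registry_rotation is None:
        registry_rotation = 360.0 / ring.n_residues

    phi = np.deg2rad(registry_rotation)
    rot = np.array([[np.cos(phi), -np.sin(phi), 0.0],
                    [np.sin(phi), np.cos(phi), 0.0],
                    [0.0, 0.0, 1.0]])

    coords = np.empty((n_unimers, ring.n_residues, N_SITES, 3))
    faces = np.empty((n_unimers, ring.n_residues), dtype=int)
    for i in range(n_unimers):
        xyz = ring.coords.copy()
        face = ring.amide_face.copy()
        if antiparallel and i % 2 == 1:
            xyz[:, :, 2] *= -1.0          # mirror through the ring plane
            xyz = xyz @ rot.T             # registry rotation about the axis
            face = -face
        xyz[:, :, 2] += i * spacing
        coords[i] = xyz
        faces[i] = face
    return NanotubeModel(coords=coords, n_unimers=n_unimers,
                         n_residues=ring.n_residues, spacing=spacing,
                         antiparallel=antiparallel,
                         registry_rotation=registry_rotation,
                         amide_face=faces)


def build_nanotube(n_residues: int = DEFAULT_N_RESIDUES,
                   n_unimers: int = 8,
                   radius: float = DEFAULT_RADIUS,
                   amide_offset: float = DEFAULT_AMIDE_OFFSET,
                   spacing: float = DEFAULT_SPACING,
                   antiparallel: bool = True,
                   registry_rotation: float | None = None) -> NanotubeModel:
    """Convenience wrapper: ``stack_rings(build_ring(...), ...)``."""
    ring = build_ring(n_residues, radius, amide_offset)
    return stack_rings(ring, n_unimers, spacing, antiparallel,
                       registry_rotation)
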