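"""Geometric detection of backbone-backbone intermolecular hydrogen bonds.

A hydrogen bond is accepted when the donor nitrogen to acceptor oxygen
distance is at most ``d_max`` and the N-H...O angle (measured at the
hydrogen) is at least ``theta_min`` -- the usual geometric criterion of MD
analysis suites.  Only bonds between adjacent rings of the stack count as
nanotube backbone bonds; each donor hydrogen bonds to at most one acceptor
(closest acceptor wins, ties broken by the lower acceptor residue index so
detection is deterministic).

Every bond is assigned to the interface ``min(donor ring, acceptor ring)``
and classified ``cap`` (first or last interface -- bonds involving a capping
unimer) or ``core``.  For the ideal octamer this reproduces the 56 = 16 cap
+ 40 core bookkeeping across 7 interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synthetic import BondStateSeries, Trajectory

DEFAULT_D_MAX = 3.5       # angstrom, N...O
DEFAULT_THETA_MIN = 120.0  # degrees, N-H...O at the hydrogen


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric cutoff pair for hydrogen-bond detection."""

    d_max: float = DEFAULT_D_MAX
    theta_min: float = DEFAULT_THETA_MIN

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError(f"d_max must be positive, got {self.d_max}")
        if not 0.0 <= self.theta_min <= 180.0:
            raise ValueError(
                f"theta_min must be in [0, 180], got {self.theta_min}")


@dataclass(frozen=True, order=True)
class HBondRecord:
    """One detected bond, identified by donor and acceptor sites."""

    donor_ring: int
    donor_res: int
    acceptor_ring: int
    acceptor_res: int
    interface_class: str = "unclassified"

    @property
    def interface(self) -> int:
        """Interface index: the lower of the two ring indices."""
        return min(self.donor_ring, self.acceptor_ring)

    @property
    def bond_id(self) -> tuple[int, int, int, int]:
        return (self.donor_ring, self.donor_res,
                self.acceptor_ring, self.acceptor_res)


@dataclass(frozen=True)
class CountSeries:
    """Per-frame bond totals with the cap/core decomposition."""

    total: np.ndarray
    cap: np.ndarray
    core: np.ndarray
    frame_dt: float

    def __post_init__(self):
        if not np.array_equal(self.total, self.cap + self.core):
            raise ValueError("total must equal cap + core at every frame")
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.total)

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_dt


def interface_class(interface: int, n_unimers: int) -> str:
    """``cap`` for the first/last interface, ``core`` otherwise."""
    if not 0 <= interface < n_unimers - 1:
        raise ValueError(
            f"interface {interface} out of range for {n_unimers} unimers")
    return "cap" if interface in (0, n_unimers - 2) else "core"


def classify_interfaces(records, n_unimers: int):
    """Return records with ``interface_class`` assigned from their interface."""
    return [replace(r, interface_class=interface_class(r.interface, n_unimers))
            for r in records]


def detect_hbonds(frame: np.ndarray,
                  criteria: HBondCriteria = HBondCriteria(),
                  classify: bool = True) -> list[HBondRecord]:
    """Detect intermolecular backbone hydrogen bonds in one frame.

    Parameters
    ----------
    frame : np.ndarray, shape (n_unimers, n_residues, 4, 3)
        Backbone site coordinates (N, H, C, O site order).
    criteria : HBondCriteria
        Distance/angle cutoffs.
    classify : bool
        Attach cap/core interface classes (default).

    Returns
    -------
    list of HBondRecord, sorted by (donor ring, donor residue).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 4 or frame.shape[2] != 4 or frame.shape[3] != 3:
        raise ValueError(
            f"frame must have shape (rings, residues, 4, 3), "
            f"got {frame.shape}")
    n_rings, n_res = frame.shape[:2]
    if n_rings < 2:
        return []

    ring_idx = np.repeat(np.arange(n_rings), n_res)
    res_idx = np.tile(np.arange(n_res), n_rings)
    n_pos = frame[:, :, 0, :].reshape(-1, 3)
    h_pos = frame[:, :, 1, :].reshape(-1, 3)
    o_pos = frame[:, :, 3, :].reshape(-1, 3)

    # Candidate pairs: donors on one ring, acceptors on an adjacent ring.
    adjacent = np.abs(ring_idx[:, None] - ring_idx[None, :]) == 1
    diff_no = n_pos[:, None, :] - o_pos[None, :, :]
    dist_no = np.linalg.norm(diff_no, axis=-1)

    hn = n_pos - h_pos                              # H -> N
    ho = o_pos[None, :, :] - h_pos[:, None, :]      # H -> O
    norm_hn = np.linalg.norm(hn, axis=-1)
    norm_ho = np.linalg.norm(ho, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_theta = np.einsum("ik,ijk->ij", hn, ho) \
            / (norm_hn[:, None] * norm_ho)
    cos_theta = np.clip(cos_theta, -1.0, 1.0)
    theta = np.degrees(np.arccos(cos_theta))

    ok = adjacent & (dist_no <= criteria.d_max) & (theta >= criteria.theta_min)

    records = []
    for d in range(n_rings * n_res):
        cands = np.nonzero(ok[d])[0]
        if cands.size == 0:
            continue
        # Closest acceptor; equal distances resolved by lower residue index.
        order = np.lexsort((res_idx[cands], dist_no[d, cands]))
        a = cands[order[0]]
        records.append(HBondRecord(
            donor_ring=int(ring_idx[d]), donor_res=int(res_idx[d]),
            acceptor_ring=int(ring_idx[a]), acceptor_res=int(res_idx[a])))
    if classify:
        records = classify_interfaces(records, n_rings)
    return sorted(records)


def count_by_class(records) -> dict[str, int]:
    """Totals of a record list: ``{"total": ..., "cap": ..., "core": ...}``."""
    cap = sum(1 for r in records if r.interface_class == "cap")
    core = sum(1 for r in records if r.interface_class == "core")
    return {"total": len(records), "cap": cap, "core": core}


def hbond_timeseries(traj: Trajectory,
                     criteria: HBondCriteria = HBondCriteria()
                     ) -> tuple[CountSeries, BondStateSeries]:
    """Per-frame bond counts and a per-bond presence matrix for a trajectory.

    The presence matrix is keyed by (donor ring, donor residue, acceptor
    ring, acceptor residue) over the union of bonds seen in any frame, so
    break events are attributable to specific bonds downstream.
    """
    if traj.n_frames < 1:
        raise ValueError("trajectory has no frames")

    per_frame: list[list[HBondRecord]] = [
        detect_hbonds(traj.frames[t], criteria) for t in range(traj.n_frames)]

    total = np.array([len(recs) for recs in per_frame])
    cap = np.array([sum(1 for r in recs if r.interface_class == "cap")
                    for recs in per_frame])
    series = CountSeries(total=total, cap=cap, core=total - cap,
                         frame_dt=traj.frame_dt)

    bond_ids = sorted({r.bond_id for recs in per_frame for r in recs})
    index = {b: i for i, b in enumerate(bond_ids)}
    presence = np.zeros((len(bond_ids), traj.n_frames), dtype=bool)
    labels = np.empty(len(bond_ids), dtype=object)
    for t, recs in enumerate(per_frame):
        for r in recs:
            presence[index[r.bond_id], t] = True
            labels[index[r.bond_id]] = r.interface_class
    states = BondStateSeries(presence=presence,
                             labels=labels.astype(str),
                             frame_dt=traj.frame_dt,
                             bond_ids=tuple(bond_ids))
    return series, states
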