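"""Nanotube stability statistics.

The central statistic is the broken-hydrogen-bond rate, BHB (ns^-1): the
number of present -> absent transitions of backbone hydrogen bonds per
nanosecond of trajectory, reported in total and decomposed into bonds at the
cap (terminal) interfaces versus the core.  A higher BHB rate means a more
dynamic, less stable stack; capping unimers, bonded through a single
interface, are expected to dominate it.

Also here: mean inter-unimer spacing (adjacent ring centroid distances),
detection of dissociation events as persistent step drops in the bond-count
series, and TEM-style tube-length summaries with the length <-> unimer-count
conversion via the axial stacking period.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import median_filter

from .synthetic import BondStateSeries, Trajectory
from .hbonds import CountSeries


class InsufficientDataError(ValueError):
    """Too few frames / observations to compute the statistic."""


@dataclass(frozen=True)
class StabilityReport:
    """Per-system stability summary.

    Rates in events/ns, counts in bonds, spacing in angstrom, time in ns.
    ``bhb_total == bhb_cap + bhb_core`` by construction.
    """

    bhb_total: float
    bhb_cap: float
    bhb_core: float
    mean_count_total: float
    mean_count_cap: float
    mean_count_core: float
    simulated_time: float
    flicker_window: int = 0
    bhb_cap_per_bond: float = 0.0
    bhb_core_per_bond: float = 0.0
    mean_spacing: float | None = None
    dissociation_events: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class LengthSummary:
    """Summary of per-tube lengths measured from micrographs."""

    n_tubes: int
    mean_nm: float
    sd_nm: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray

    def to_dict(self) -> dict:
        return {"n_tubes": self.n_tubes, "mean_nm": self.mean_nm,
                "sd_nm": self.sd_nm,
                "hist_counts": self.hist_counts.tolist(),
                "hist_edges": self.hist_edges.tolist()}


def _break_events(presence: np.ndarray, flicker_window: int) -> int:
    """Count present->absent transitions that persist >= flicker_window frames.

    With window 0 every transition counts once.  An absence run truncated by
    the end of the series shorter than the window cannot be confirmed as
    persistent and is not counted.
    """
    n_events = 0
    for row in presence:
        trans = np.nonzero(row[:-1] & ~row[1:])[0]
        if flicker_window <= 1:
            n_events += trans.size
            continue
        for t in trans:
            run = row[t + 1:t + 1 + flicker_window]
            if run.size >= flicker_window and not run.any():
                n_events += 1
    return n_events


def broken_bonds_per_ns(bond_states: BondStateSeries,
                        flicker_window: int = 0) -> StabilityReport:
    """Broken-hydrogen-bond rates (total / cap / core) from a presence matrix.

    A break event is a bond present at frame ``t`` and absent at ``t+1``
    whose absence persists for at least ``flicker_window`` frames; window 0
    counts raw transitions.  The rate divides events by the covered time
    ``(n_frames - 1) * frame_dt``.  Per-bond-normalized cap/core rates are
    reported alongside the raw ones, since the cap and core populations
    differ in size (16 vs 40 bonds in an octamer).
    """
    if bond_states.n_frames < 2:
        raise InsufficientDataError(
            "break rates need at least 2 frames")
    if flicker_window < 0:
        raise ValueError(f"flicker_window must be >= 0, got {flicker_window}")

    time_ns = (bond_states.n_frames - 1) * bond_states.frame_dt
    cap_mask = bond_states.labels == "cap"
    events_cap = _break_events(bond_states.presence[cap_mask], flicker_window)
    events_core = _break_events(bond_states.presence[~cap_mask],
                                flicker_window)
    n_cap = int(cap_mask.sum())
    n_core = bond_states.n_bonds - n_cap

    mean_cap = float(bond_states.presence[cap_mask].sum(axis=0).mean()) \
        if n_cap else 0.0
    mean_core = float(bond_states.presence[~cap_mask].sum(axis=0).mean()) \
        if n_core else 0.0

    bhb_cap = events_cap / time_ns
    bhb_core = events_core / time_ns
    return StabilityReport(
        bhb_total=bhb_cap + bhb_core, bhb_cap=bhb_cap, bhb_core=bhb_core,
        mean_count_total=mean_cap + mean_core,
        mean_count_cap=mean_cap, mean_count_core=mean_core,
        simulated_time=time_ns, flicker_window=flicker_window,
        bhb_cap_per_bond=bhb_cap / n_cap if n_cap else 0.0,
        bhb_core_per_bond=bhb_core / n_core if n_core else 0.0)


def mean_interunimer_distance(traj: Trajectory) -> float:
    """Mean adjacent-ring centroid distance over all frames and interfaces.

    Centroids are taken over the backbone sites only (the model carries no
    others).  For the ideal stack this equals the stacking period.
    """
    if traj.n_frames < 1:
        raise InsufficientDataError("no frames")
    if traj.n_unimers < 2:
        raise ValueError("spacing needs at least 2 rings")
    centroids = traj.frames.reshape(
        traj.n_frames, traj.n_unimers, -1, 3).mean(axis=2)
    dists = np.linalg.norm(np.diff(centroids, axis=1), axis=-1)
    return float(dists.mean())


def detect_dissociation_events(series: CountSeries,
                               drop_threshold: float = 6.0,
                               persistence: int = 50,
                               median_window: int = 11) -> list[tuple]:
    """Find persistent step drops in the total bond-count series.

    The series is median-filtered (window ``median_window`` frames) to
    suppress single-frame flicker; an event is flagged at frame ``t`` when
    the filtered count sits at least ``drop_threshold`` below the median of
    the filtered counts since the last event and stays that low for at least
    ``persistence`` frames.  The magnitude is the baseline minus the median
    of the ``persistence`` post-event frames -- for a full cap unbinding of
    an octamer this is ~8 bonds.

    Returns a list of ``(frame, magnitude)`` tuples; empty when no event.
    """
    if series.n_frames < persistence + 1:
        raise InsufficientDataError(
            f"series of {series.n_frames} frames cannot support "
            f"persistence={persistence}")
    filt = median_filter(series.total.astype(float), size=median_window,
                         mode="nearest")
    events = []
    seg_start = 0
    t = 1
    n = len(filt)
    while t < n - persistence + 1:
        base = float(np.median(filt[seg_start:t]))
        window = filt[t:t + persistence]
        if base - filt[t] >= drop_threshold and \
                np.all(window <= base - drop_threshold):
            magnitude = base - float(np.median(window))
            events.append((int(t), float(magnitude)))
            seg_start = t
            t += persistence
        else:
            t += 1
    return events


def summarize_lengths(lengths_nm, bins: int = 10) -> LengthSummary:
    """Mean / sd / histogram of per-tube lengths (nm), as measured from TEM."""
    lengths = np.asarray(lengths_nm, dtype=float)
    if lengths.size == 0:
        raise InsufficientDataError("no lengths given")
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    counts, edges = np.histogram(lengths, bins=bins)
    sd = float(lengths.std(ddof=1)) if lengths.size > 1 else 0.0
    return LengthSummary(n_tubes=int(lengths.size),
                         mean_nm=float(lengths.mean()), sd_nm=sd,
                         hist_counts=counts, hist_edges=edges)


def length_to_unimer_count(length_nm: float,
                           spacing_nm: float = 0.485) -> int:
    """Unimers in a tube of the given length at the axial stacking period.

    Default period 0.485 nm is the 4.85 angstrom inter-unimer spacing.
    A tube is at least one unimer.
    """
    if length_nm <= 0:
        raise ValueError(f"length must be positive, got {length_nm}")
    if spacing_nm <= 0:
        raise ValueError(f"spacing must be positive, got {spacing_nm}")
    return max(1, round(length_nm / spacing_nm))
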